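"""miRNA -> host-gene mapping: build from genomic coordinates, read/write the
tabular exchange format, filter by edge attributes, and bind edges to the rows
of an expression matrix.

An edge links one pre-miRNA locus to one overlapping protein-coding
transcript and carries the three categorical attributes the predictors use:
where the overlap falls (intron / exon / 3'UTR / 5'UTR), whether the miRNA
sits on the coding (sense) or opposite strand, and whether the annotation is
experimentally supported or predicted.  Coordinates are 1-based inclusive
(Ensembl convention); converters for 0-based half-open (BED) intervals are
provided at the boundary.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .preprocess import ExpressionMatrix

logger = logging.getLogger("mirhost")

StrandRel = Literal["sense", "antisense"]
Overlap = Literal["intron", "exon", "utr3", "utr5"]
Evidence = Literal["experimental", "predicted"]

# classification priority when a locus spans annotation boundaries
OVERLAP_PRIORITY: tuple[Overlap, ...] = ("utr3", "utr5", "exon", "intron")

_OVERLAP_ALIASES = {
    "intron": "intron",
    "intronic": "intron",
    "exon": "exon",
    "exonic": "exon",
    "utr3": "utr3",
    "3utr": "utr3",
    "3'utr": "utr3",
    "three_prime_utr": "utr3",
    "utr5": "utr5",
    "5utr": "utr5",
    "5'utr": "utr5",
    "five_prime_utr": "utr5",
}

MAPPING_COLUMNS = [
    "mirbase_id", "strand", "overlap", "evidence", "ensembl_gene_id",
    "ensembl_transcript_id", "probesets", "chromosome", "start", "end",
    "mir", "mir_star",
]


def normalize_overlap(token: str) -> Overlap:
    key = token.strip().lower()
    if key not in _OVERLAP_ALIASES:
        raise ValueError(f"unknown overlap class token: {token!r}")
    return _OVERLAP_ALIASES[key]  # type: ignore[return-value]


def classify_evidence(label: str) -> Evidence:
    """Binarize a free-text annotation-source label: anything automatic or
    predicted counts as 'predicted', everything else as 'experimental'."""
    low = label.lower()
    return "predicted" if ("automatic" in low or "predicted" in low) else "experimental"


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MappingEdge:
    mirbase_id: str
    mature_ids: tuple[str, ...]
    strand_rel: StrandRel
    overlap: Overlap
    evidence: Evidence
    gene_id: str
    transcript_id: str
    probeset_ids: tuple[str, ...]
    chromosome: str
    start: int
    end: int
    evidence_label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"edge {self.mirbase_id}: start {self.start} > end {self.end}"
            )
        if not self.mature_ids:
            raise ValueError(f"edge {self.mirbase_id}: no mature ids")


@dataclass
class MappingTable:
    edges: list[MappingEdge]
    by_mirbase: dict[str, list[MappingEdge]] = field(default_factory=dict)
    by_mature: dict[str, list[MappingEdge]] = field(default_factory=dict)
    by_probeset: dict[str, list[MappingEdge]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self.by_mirbase = defaultdict(list)
        self.by_mature = defaultdict(list)
        self.by_probeset = defaultdict(list)
        for e in self.edges:
            self.by_mirbase[e.mirbase_id].append(e)
            for m in e.mature_ids:
                self.by_mature[m].append(e)
            for p in e.probeset_ids:
                self.by_probeset[p].append(e)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def mature_ids(self) -> list[str]:
        return sorted(self.by_mature)


@dataclass
class MappedHosts:
    """Per mature miRNA, the (row index, edge) pairs of its host probesets
    present in a bound expression matrix, in edge order."""

    hosts: dict[str, list[tuple[int, MappingEdge]]]
    matrix_row_ids: list[str]

    def __getitem__(self, mature_id: str) -> list[tuple[int, MappingEdge]]:
        return self.hosts.get(mature_id, [])

    def mirnas_with_hosts(self) -> list[str]:
        return [m for m, h in self.hosts.items() if h]


# ---------------------------------------------------------------------------
# I/O (Table-1-style CSV)
# ---------------------------------------------------------------------------

def read_mapping(path: str | Path) -> MappingTable:
    """Read a mapping table CSV.  Columns: mirbase_id, strand (+/-/sense/
    antisense), overlap, evidence (free text), ensembl_gene_id,
    ensembl_transcript_id, probesets (';'-separated), chromosome, start, end,
    mir, mir_star."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MAPPING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mapping file missing columns: {missing}")
    edges = []
    for _, row in df.iterrows():
        strand_tok = row["strand"].strip().lower()
        strand: StrandRel = (
            "sense" if strand_tok in ("+", "sense") else "antisense"
            if strand_tok in ("-", "antisense") else _bad_strand(strand_tok)
        )
        mature = tuple(m for m in (row["mir"].strip(), row["mir_star"].strip()) if m)
        probesets = tuple(p for p in row["probesets"].split(";") if p)
        edges.append(
            MappingEdge(
                mirbase_id=row["mirbase_id"].strip(),
                mature_ids=mature,
                strand_rel=strand,
                overlap=normalize_overlap(row["overlap"]),
                evidence=classify_evidence(row["evidence"]),
                evidence_label=row["evidence"],
                gene_id=row["ensembl_gene_id"],
                transcript_id=row["ensembl_transcript_id"],
                probeset_ids=probesets,
                chromosome=row["chromosome"],
                start=int(row["start"]),
                end=int(row["end"]),
            )
        )
    return MappingTable(edges)


def _bad_strand(tok: str) -> StrandRel:
    raise ValueError(f"unknown strand token: {tok!r}")


def write_mapping(table: MappingTable, path: str | Path) -> None:
    rows = []
    for e in table.edges:
        rows.append(
            {
                "mirbase_id": e.mirbase_id,
                "strand": "+" if e.strand_rel == "sense" else "-",
                "overlap": e.overlap,
                "evidence": e.evidence_label or e.evidence,
                "ensembl_gene_id": e.gene_id,
                "ensembl_transcript_id": e.transcript_id,
                "probesets": ";".join(e.probeset_ids),
                "chromosome": e.chromosome,
                "start": e.start,
                "end": e.end,
                "mir": e.mature_ids[0],
                "mir_star": e.mature_ids[1] if len(e.mature_ids) > 1 else "",
            }
        )
    pd.DataFrame(rows, columns=MAPPING_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Building from coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MirnaLocus:
    mirbase_id: str
    mature_ids: tuple[str, ...]
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class TranscriptModel:
    gene_id: str
    transcript_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()
    probeset_ids: tuple[str, ...] = ()
    evidence_label: str = "curated_transcript"


def _intersects(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def build_mapping(
    mirna_loci: Iterable[MirnaLocus],
    gene_models: Iterable[TranscriptModel],
) -> MappingTable:
    """Intersect pre-miRNA loci with transcript models and emit one edge per
    overlapping (locus, transcript) pair.

    The overlap class is chosen with priority utr3 > utr5 > exon > intron
    when a locus spans annotation boundaries; a locus inside the transcript
    span that touches no exon/UTR interval is intronic.  strand_rel is sense
    iff the two strands are equal.
    """
    models = sorted(
        gene_models, key=lambda t: (t.chromosome, t.start, t.end, t.transcript_id)
    )
    known_chroms = {t.chromosome for t in models}
    edges: list[MappingEdge] = []
    n_skipped = 0
    for locus in mirna_loci:
        iv = (locus.start, locus.end)
        if locus.chromosome not in known_chroms:
            n_skipped += 1
            continue
        for t in models:
            if t.chromosome != locus.chromosome:
                continue
            if not _intersects(iv, (t.start, t.end)):
                continue
            hit: dict[str, bool] = {
                "utr3": any(_intersects(iv, u) for u in t.utr3),
                "utr5": any(_intersects(iv, u) for u in t.utr5),
                "exon": any(_intersects(iv, e) for e in t.exons),
            }
            overlap: Overlap = next(
                (c for c in OVERLAP_PRIORITY if hit.get(c)), "intron"
            )
            edges.append(
                MappingEdge(
                    mirbase_id=locus.mirbase_id,
                    mature_ids=locus.mature_ids,
                    strand_rel="sense" if locus.strand == t.strand else "antisense",
                    overlap=overlap,
                    evidence=classify_evidence(t.evidence_label),
                    evidence_label=t.evidence_label,
                    gene_id=t.gene_id,
                    transcript_id=t.transcript_id,
                    probeset_ids=t.probeset_ids,
                    chromosome=locus.chromosome,
                    start=locus.start,
                    end=locus.end,
                )
            )
    if n_skipped:
        logger.info("build_mapping: %d loci on chromosomes absent from models", n_skipped)
    return MappingTable(edges)


# ---------------------------------------------------------------------------
# Application and filtering
# ---------------------------------------------------------------------------

def map_expression_rows(table: MappingTable, matrix: ExpressionMatrix) -> MappedHosts:
    """Realize the mapping for one mRNA matrix: per mature miRNA, the host
    rows whose probeset appears among the matrix row ids, in edge order."""
    if matrix.role != "mrna":
        raise ValueError("map_expression_rows expects an mRNA matrix")
    row_index = {rid: i for i, rid in enumerate(matrix.row_ids)}
    hosts: dict[str, list[tuple[int, MappingEdge]]] = {}
    n_missing = 0
    for mature in table.mature_ids:
        entries: list[tuple[int, MappingEdge]] = []
        for edge in table.by_mature[mature]:
            for p in edge.probeset_ids:
                if p in row_index:
                    entries.append((row_index[p], edge))
                else:
                    n_missing += 1
        hosts[mature] = entries
    if n_missing:
        logger.info("map_expression_rows: %d probesets absent from matrix", n_missing)
    return MappedHosts(hosts, matrix.row_ids)


def filter_edges(
    table: MappingTable,
    strand_rel: StrandRel | None = None,
    overlap: Overlap | Sequence[Overlap] | None = None,
    evidence: Evidence | None = None,
) -> MappingTable:
    """Keep edges satisfying all given predicates; at least one predicate is
    required.  Indices are rebuilt."""
    if strand_rel is None and overlap is None and evidence is None:
        raise ValueError("filter_edges requires at least one predicate")
    overlaps = None
    if overlap is not None:
        overlaps = {overlap} if isinstance(overlap, str) else set(overlap)
    kept = [
        e
        for e in table.edges
        if (strand_rel is None or e.strand_rel == strand_rel)
        and (overlaps is None or e.overlap in overlaps)
        and (evidence is None or e.evidence == evidence)
    ]
    if not kept:
        logger.warning("filter_edges: no edges satisfy the predicates")
    return MappingTable(kept)


def edge_statistics(table: MappingTable) -> pd.DataFrame:
    """Counts and integer-rounded percentages per overlap class and per
    strand orientation."""
    if not table.edges:
        raise ValueError("edge_statistics requires a non-empty table")
    rows = []
    n = len(table.edges)
    for cls in OVERLAP_PRIORITY:
        k = sum(1 for e in table.edges if e.overlap == cls)
        rows.append({"dimension": "overlap", "level": cls, "count": k,
                     "percent": round(100 * k / n)})
    for s in ("sense", "antisense"):
        k = sum(1 for e in table.edges if e.strand_rel == s)
        rows.append({"dimension": "strand", "level": s, "count": k,
                     "percent": round(100 * k / n)})
    return pd.DataFrame(rows)


def edge_statistics_from_counts(counts: dict[str, int]) -> pd.DataFrame:
    """Same report computed from pre-tabulated class counts (levels may mix
    overlap classes and strand orientations; percentages are taken within
    each dimension)."""
    overlap_total = sum(v for k, v in counts.items() if k in OVERLAP_PRIORITY)
    strand_total = sum(v for k, v in counts.items() if k in ("sense", "antisense"))
    rows = []
    for k, v in counts.items():
        if k in OVERLAP_PRIORITY:
            dim, total = "overlap", overlap_total
        elif k in ("sense", "antisense"):
            dim, total = "strand", strand_total
        else:
            raise ValueError(f"unknown class level: {k!r}")
        rows.append({"dimension": dim, "level": k, "count": v,
                     "percent": round(100 * v / total)})
    return pd.DataFrame(rows)
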
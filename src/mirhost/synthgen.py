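"""Synthetic data with planted, scoreable structure.

Every stage of the pipeline is testable without external downloads: mapping
tables with realistic attribute mixes, paired miRNA-mRNA matrices in which
miRNA rows are linear in their hosts and target rows are anti-correlated
with their miRNA at a controlled population correlation, RNA sequences with
planted complementary binding sites, and gene-set collections with one
planted enriched term.  All generators are pure functions of their
parameters and seed.

Expression values live on the log2 scale with Gaussian noise, emulating
RMA-style microarray indexes; default attribute mixes follow the observed
genomic mapping (~92% intronic overlaps, ~83% on the coding strand).  The
default geometry (30 samples, 20 miRNAs, 500 genes) keeps a full pipeline
run in the seconds range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .energy_walk import RnaSequence, random_rna
from .mirmap import MappingEdge, MappingTable
from .preprocess import DesignTable, ExpressionMatrix

DEFAULT_CLASS_PROPORTIONS = {
    "overlap": {"intron": 0.92, "exon": 0.05, "utr5": 0.02, "utr3": 0.01},
    "strand": {"sense": 0.83, "antisense": 0.17},
    "evidence": {"experimental": 0.5, "predicted": 0.5},
}


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset, complete enough to score any
    downstream prediction."""

    hosts: dict[str, list[str]] = field(default_factory=dict)        # mirna -> host probesets
    coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)  # mirna -> (a, b)
    differential: dict[str, float] = field(default_factory=dict)     # mirna -> planted log2 effect
    targets: dict[str, list[str]] = field(default_factory=dict)      # mirna -> target probesets
    target_strength: float = 0.0                                     # planted population |r|
    repression: float = 0.0                                          # d in target = c - d*miRNA
    decoys: list[str] = field(default_factory=list)
    edge_classes: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_sites: dict[str, tuple[str, int]] = field(default_factory=dict)  # utr -> (mirna, 1-based pos)
    enriched_term: str = ""
    enriched_overlap: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "hosts": self.hosts,
            "coefficients": {k: list(v) for k, v in self.coefficients.items()},
            "differential": self.differential,
            "targets": self.targets,
            "target_strength": self.target_strength,
            "repression": self.repression,
            "decoys": self.decoys,
            "edge_classes": self.edge_classes,
            "planted_sites": {k: list(v) for k, v in self.planted_sites.items()},
            "enriched_term": self.enriched_term,
            "enriched_overlap": self.enriched_overlap,
        }


# ---------------------------------------------------------------------------
# Mapping tables
# ---------------------------------------------------------------------------

def make_mapping(
    n_mirna: int,
    n_genes: int,
    hosts_per_mirna: int = 3,
    class_proportions: dict | None = None,
    seed: int = 0,
) -> tuple[MappingTable, SyntheticTruth]:
    """A schema-valid mapping table with edge attributes drawn at the
    requested proportions and the per-miRNA host assignment recorded."""
    if hosts_per_mirna < 1:
        raise ValueError("hosts_per_mirna must be >= 1")
    if n_genes < hosts_per_mirna:
        raise ValueError("n_genes must be >= hosts_per_mirna")
    props = class_proportions or DEFAULT_CLASS_PROPORTIONS
    rng = np.random.default_rng(seed)
    genes = [f"gene{g:04d}" for g in range(n_genes)]
    edges: list[MappingEdge] = []
    truth = SyntheticTruth()
    counts: dict[str, dict[str, int]] = {
        dim: {lvl: 0 for lvl in levels} for dim, levels in props.items()
    }

    def draw(dim: str) -> str:
        levels = list(props[dim])
        p = np.array([props[dim][lv] for lv in levels], dtype=float)
        choice = str(rng.choice(levels, p=p / p.sum()))
        counts[dim][choice] += 1
        return choice

    for j in range(n_mirna):
        mid = f"syn-mir-{j:03d}"
        host_idx = rng.choice(n_genes, size=hosts_per_mirna, replace=False)
        truth.hosts[mid] = []
        for g in sorted(host_idx):
            gene = genes[g]
            probeset = f"ps_{gene}"
            overlap = draw("overlap")
            strand = draw("strand")
            evidence = draw("evidence")
            start = int(g) * 10_000 + 1_000
            edges.append(
                MappingEdge(
                    mirbase_id=mid,
                    mature_ids=(mid, f"{mid}*"),
                    strand_rel=strand,  # type: ignore[arg-type]
                    overlap=overlap,  # type: ignore[arg-type]
                    evidence=evidence,  # type: ignore[arg-type]
                    evidence_label=(
                        "curated_transcript" if evidence == "experimental"
                        else "automatic_transcript"
                    ),
                    gene_id=gene,
                    transcript_id=f"tx_{gene}",
                    probeset_ids=(probeset,),
                    chromosome="chr1",
                    start=start,
                    end=start + 80,
                )
            )
            truth.hosts[mid].append(probeset)
    truth.edge_classes = counts
    return MappingTable(edges), truth


# ---------------------------------------------------------------------------
# Paired expression matrices
# ---------------------------------------------------------------------------

def make_paired_dataset(
    n_samples: int = 30,
    n_mirna: int = 20,
    n_genes: int = 500,
    effect: float = 1.0,
    noise_sd: float = 0.1,
    target_strength: float = 0.95,
    seed: int = 0,
    hosts_per_mirna: int = 3,
    targets_per_mirna: int = 3,
    diff_fraction: float = 0.5,
    repression: float = 1.0,
    decoy_edges_per_mirna: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, MappingTable, DesignTable, SyntheticTruth]:
    """Paired mRNA and miRNA matrices with planted structure.

    Two balanced groups.  Host rows: baseline + per-miRNA group effect +
    Gaussian noise; miRNA rows: a_j + b_j * mean(hosts_j) + noise; target
    rows: c - repression * miRNA + noise scaled so the planted population
    anti-correlation equals ``target_strength``; remaining rows are
    independent decoys.  With ``noise_sd=0`` the dataset is fully
    deterministic and planted target correlations are exactly -1.

    ``decoy_edges_per_mirna`` adds spurious mapping edges from each miRNA to
    decoy genes, emulating the many-to-many mapping ambiguity that the
    fold-change/p-value weighting of the scaling predictor is meant to
    suppress.
    """
    if n_samples < 6 or n_samples % 2:
        raise ValueError("n_samples must be an even number >= 6")
    need = n_mirna * (hosts_per_mirna + targets_per_mirna)
    if n_genes < need + decoy_edges_per_mirna:
        raise ValueError(f"n_genes must be >= {need + decoy_edges_per_mirna}")
    if not (0 < target_strength <= 1):
        raise ValueError("target_strength must be in (0, 1]")
    rng = np.random.default_rng(seed)
    samples = [f"s{k:03d}" for k in range(n_samples)]
    group = np.array([-0.5] * (n_samples // 2) + [0.5] * (n_samples // 2))
    design = DesignTable(
        pd.Series(np.where(group < 0, "ctrl", "case"), index=samples)
    )

    gene_ids = [f"ps_{g:04d}" for g in range(n_genes)]
    truth = SyntheticTruth(target_strength=target_strength, repression=repression)
    n_diff = int(round(diff_fraction * n_mirna))
    diff_signs = np.concatenate(
        [rng.choice([-1.0, 1.0], size=n_diff), np.zeros(n_mirna - n_diff)]
    )
    rng.shuffle(diff_signs)

    mrna = np.zeros((n_genes, n_samples))
    mirna = np.zeros((n_mirna, n_samples))
    mirna_ids = [f"syn-mir-{j:03d}" for j in range(n_mirna)]
    edges: list[MappingEdge] = []
    cursor = 0
    for j, mid in enumerate(mirna_ids):
        delta = diff_signs[j] * effect
        if diff_signs[j] != 0:
            truth.differential[mid] = float(delta)
        host_rows = list(range(cursor, cursor + hosts_per_mirna))
        cursor += hosts_per_mirna
        truth.hosts[mid] = [gene_ids[r] for r in host_rows]
        for r in host_rows:
            baseline = rng.uniform(6, 10)
            mrna[r] = baseline + delta * group + rng.normal(0, noise_sd, n_samples)
            start = r * 10_000 + 1_000
            edges.append(
                MappingEdge(
                    mirbase_id=mid, mature_ids=(mid,),
                    strand_rel="sense", overlap="intron",
                    evidence="experimental", evidence_label="curated_transcript",
                    gene_id=gene_ids[r], transcript_id=f"tx_{gene_ids[r]}",
                    probeset_ids=(gene_ids[r],), chromosome="chr1",
                    start=start, end=start + 80,
                )
            )
        a_j = rng.uniform(0, 2)
        b_j = rng.uniform(0.8, 1.2)
        truth.coefficients[mid] = (float(a_j), float(b_j))
        host_mean = mrna[host_rows].mean(axis=0)
        mirna[j] = a_j + b_j * host_mean + rng.normal(0, noise_sd, n_samples)

        # population sd of the miRNA row, used to hit the requested
        # target anti-correlation
        var_m = b_j ** 2 * (delta ** 2 / 4 + noise_sd ** 2 / hosts_per_mirna) + noise_sd ** 2
        if noise_sd == 0:
            sd_t = 0.0
        else:
            sd_t = repression * np.sqrt(var_m) * np.sqrt(
                1 / target_strength ** 2 - 1
            )
        target_rows = list(range(cursor, cursor + targets_per_mirna))
        cursor += targets_per_mirna
        truth.targets[mid] = [gene_ids[r] for r in target_rows]
        for r in target_rows:
            c = rng.uniform(12, 16)
            mrna[r] = c - repression * mirna[j] + rng.normal(0, sd_t, n_samples)

    for r in range(cursor, n_genes):
        truth.decoys.append(gene_ids[r])
        mrna[r] = rng.uniform(6, 10) + rng.normal(0, max(noise_sd, 1e-12), n_samples)

    if decoy_edges_per_mirna:
        decoy_rows = list(range(cursor, n_genes))
        for mid in mirna_ids:
            picks = rng.choice(len(decoy_rows), size=decoy_edges_per_mirna,
                               replace=False)
            for r in (decoy_rows[i] for i in picks):
                start = r * 10_000 + 1_000
                edges.append(
                    MappingEdge(
                        mirbase_id=mid, mature_ids=(mid,),
                        strand_rel="sense", overlap="intron",
                        evidence="experimental",
                        evidence_label="curated_transcript",
                        gene_id=gene_ids[r], transcript_id=f"tx_{gene_ids[r]}",
                        probeset_ids=(gene_ids[r],), chromosome="chr1",
                        start=start, end=start + 80,
                    )
                )

    mrna_matrix = ExpressionMatrix(
        pd.DataFrame(mrna, index=gene_ids, columns=samples), role="mrna"
    )
    mirna_matrix = ExpressionMatrix(
        pd.DataFrame(mirna, index=mirna_ids, columns=samples), role="mirna"
    )
    return mrna_matrix, mirna_matrix, MappingTable(edges), design, truth


# ---------------------------------------------------------------------------
# Sequences with planted binding sites
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def make_mirna_sequences(n: int, length: int = 22, seed: int = 0) -> list[RnaSequence]:
    rng = np.random.default_rng(seed)
    return [
        RnaSequence(f"syn-mir-{j:03d}", random_rna(length, rng), kind="mature_mirna")
        for j in range(n)
    ]


def make_sequences(
    n_targets: int,
    length_range: tuple[int, int],
    mirna_set: Sequence[RnaSequence],
    planted_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[tuple[RnaSequence, RnaSequence]], SyntheticTruth]:
    """(miRNA, 3'UTR) pairs; a ``planted_fraction`` of the UTRs carry the
    exact reverse complement of their miRNA at a recorded 1-based position,
    the rest are uniform random."""
    if length_range[0] < 100:
        raise ValueError("UTR lengths must be >= 100 nt to pass the scan filter")
    if not mirna_set:
        raise ValueError("mirna_set must be non-empty")
    rng = np.random.default_rng(seed)
    n_planted = int(round(planted_fraction * n_targets))
    pairs: list[tuple[RnaSequence, RnaSequence]] = []
    truth = SyntheticTruth()
    for i in range(n_targets):
        mir = mirna_set[int(rng.integers(len(mirna_set)))]
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = list(random_rna(L, rng))
        utr_id = f"utr_{i:04d}"
        if i < n_planted:
            site = reverse_complement(mir.sequence)
            pos0 = int(rng.integers(0, L - len(site) + 1))
            seq[pos0 : pos0 + len(site)] = site
            truth.planted_sites[utr_id] = (mir.id, pos0 + 1)
        pairs.append((mir, RnaSequence(utr_id, "".join(seq), kind="utr3")))
    return pairs, truth


# ---------------------------------------------------------------------------
# Gene sets with a planted enriched term
# ---------------------------------------------------------------------------

def make_genesets(
    n_terms: int,
    term_size_range: tuple[int, int],
    universe: Sequence[str],
    query: Sequence[str],
    seed: int = 0,
    planted_term: str = "planted_term",
    query_fraction: float = 0.5,
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Random gene sets plus one planted term built to overlap the
    designated query (a ``query_fraction`` of the query's genes, padded with
    random universe members up to the term-size range)."""
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("universe must be non-empty")
    if term_size_range[1] > len(universe):
        raise ValueError("term size exceeds the universe")
    rng = np.random.default_rng(seed)
    terms: dict[str, tuple[str, frozenset]] = {}
    for t in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        terms[f"term_{t:03d}"] = (
            f"random set {t}", frozenset(universe[i] for i in members)
        )
    overlap = [q for q in query if q in set(universe)]
    k = max(1, int(round(query_fraction * len(overlap))))
    chosen = [overlap[i] for i in rng.choice(len(overlap), size=k, replace=False)]
    size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
    fillers = [g for g in universe if g not in set(chosen)]
    pad = max(0, size - len(chosen))
    extra = [fillers[i] for i in rng.choice(len(fillers), size=min(pad, len(fillers)),
                                            replace=False)]
    terms[planted_term] = ("planted enriched term", frozenset(chosen + extra))
    truth = SyntheticTruth(enriched_term=planted_term, enriched_overlap=sorted(chosen))
    return GeneSetCollection(label="synthetic", terms=terms), truth
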
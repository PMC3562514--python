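"""Binding-free-energy validation of predicted miRNA targets.

Each candidate 3'UTR is scanned with a 25 nt window advancing in 5 nt steps;
every window is joined to the mature miRNA through an 8-base artificial
linker of unpairable 'X' bases and the minimum free energy of the joined
molecule is computed.  The window with the lowest energy marks the putative
binding site, and the distribution of per-pair minima is compared (Welch two
sample t-test) between matched pairs and two randomized controls: permuted
gene labels, and substituted 3'UTR sequences.

The default energy backend is a nearest-neighbour hybridization dynamic
program: Watson-Crick and GU wobble pairs with Turner-style stacking terms,
affine bulge/internal-loop penalties, duplex initiation and terminal AU/GU
penalties.  It forbids intra-strand pairs, which makes the unpairable linker
trivially respected.  The GU stacking terms are approximate.  An adapter for
an external folding engine (RNAduplex) is provided for cross-checks.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats as sps

logger = logging.getLogger("mirhost")

RNA_ALPHABET = set("ACGU")
PAIRABLE = {"AU", "UA", "CG", "GC", "GU", "UG"}
WOBBLE_OR_AU = {"AU", "UA", "GU", "UG"}

DUPLEX_INIT = 4.09      # kcal/mol, duplex initiation
TERMINAL_AU = 0.45      # per helix end closed by AU or GU
MAX_LOOP = 4            # max unpaired bases per strand between two pairs

# Watson-Crick nearest-neighbour stacks, dG37 kcal/mol (Xia et al. values);
# key = (left pair, right pair), pair written top-strand base + bottom-strand
# base of the 5'XY3'/3'X'Y'5' stack.
_WC_STACKS = {
    ("AU", "AU"): -0.93, ("UA", "UA"): -0.93,
    ("AU", "UA"): -1.10, ("UA", "AU"): -1.33,
    ("CG", "UA"): -2.08, ("AU", "GC"): -2.08,
    ("CG", "AU"): -2.11, ("UA", "GC"): -2.11,
    ("GC", "UA"): -2.24, ("AU", "CG"): -2.24,
    ("GC", "AU"): -2.35, ("UA", "CG"): -2.35,
    ("CG", "GC"): -2.36, ("GC", "CG"): -3.42,
    ("GC", "GC"): -3.26, ("CG", "CG"): -3.26,
}
_GU_SINGLE = -1.0       # one wobble pair in the stack (approximate)
_GU_DOUBLE = -0.5       # both pairs wobble (approximate)

_BULGE = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4, 7: 4.6, 8: 4.7}
_INTERNAL = {2: 1.5, 3: 2.0, 4: 2.5, 5: 3.0, 6: 3.5, 7: 4.0, 8: 4.5}


def _stack_energy(p1: str, p2: str) -> float:
    val = _WC_STACKS.get((p1, p2))
    if val is not None:
        return val
    n_gu = (p1 in ("GU", "UG")) + (p2 in ("GU", "UG"))
    return _GU_DOUBLE if n_gu == 2 else _GU_SINGLE


def _loop_energy(gi: int, gj: int) -> float:
    """Cost of moving from one pair to the next with gi-1 / gj-1 unpaired
    bases on the two strands."""
    ui, uj = gi - 1, gj - 1
    if ui == 0 and uj == 0:
        raise ValueError("adjacent pairs are a stack, not a loop")
    if ui == 0 or uj == 0:
        return _BULGE[min(ui + uj, max(_BULGE))]
    return _INTERNAL[min(ui + uj, max(_INTERNAL))]


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RnaSequence:
    id: str
    sequence: str
    kind: Literal["mature_mirna", "utr3"] = "utr3"

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid RNA characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, kind: Literal["mature_mirna", "utr3"]) -> list[RnaSequence]:
    """Read FASTA; record ids are the first whitespace-delimited token."""
    return [
        RnaSequence(rec.id, str(rec.seq), kind=kind)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_gene_transcript_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (gene_id, transcript_id) -> gene to transcript lists."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "transcript"],
                     dtype=str)
    out: dict[str, list[str]] = {}
    for g, t in zip(df["gene"], df["transcript"]):
        out.setdefault(g, []).append(t)
    return out


def select_longest_utr(
    isoforms_by_gene: Mapping[str, Sequence[RnaSequence]],
    min_length: int = 100,
) -> dict[str, RnaSequence]:
    """Pick the longest 3'UTR isoform per gene (ties broken by the
    lexicographically smallest transcript id) and drop genes whose longest
    isoform is under ``min_length`` nt."""
    selected: dict[str, RnaSequence] = {}
    n_dropped = 0
    for gene, isoforms in isoforms_by_gene.items():
        if not isoforms:
            raise ValueError(f"gene {gene!r} has no isoforms")
        best = min(isoforms, key=lambda s: (-len(s), s.id))
        if len(best) < min_length:
            n_dropped += 1
            continue
        selected[gene] = best
    if n_dropped:
        logger.info("select_longest_utr: %d genes dropped (<%d nt)", n_dropped, min_length)
    return selected


# ---------------------------------------------------------------------------
# Duplex energy backends
# ---------------------------------------------------------------------------

@lru_cache(maxsize=65536)
def _hybrid_mfe(top: str, bottom_rev: str) -> float:
    """Minimum hybridization free energy of two strands (top 5'->3' against
    the reversed second strand), intra-strand pairing forbidden."""
    n, m = len(top), len(bottom_rev)
    can = [
        [top[i] + bottom_rev[j] in PAIRABLE for j in range(m)] for i in range(n)
    ]
    pair = [[top[i] + bottom_rev[j] for j in range(m)] for i in range(n)]
    INF = float("inf")
    # E[i][j] = best energy of a duplex whose rightmost pair is (i, j),
    # including initiation and the left-end terminal penalty.
    E = [[INF] * m for _ in range(n)]
    best = 0.0
    for i in range(n):
        for j in range(m):
            if not can[i][j]:
                continue
            e = DUPLEX_INIT + (TERMINAL_AU if pair[i][j] in WOBBLE_OR_AU else 0.0)
            for gi in range(1, MAX_LOOP + 2):
                if i - gi < 0:
                    break
                row = E[i - gi]
                for gj in range(1, MAX_LOOP + 2):
                    if j - gj < 0:
                        break
                    prev = row[j - gj]
                    if prev == INF:
                        continue
                    if gi == 1 and gj == 1:
                        cost = _stack_energy(pair[i - 1][j - 1], pair[i][j])
                    else:
                        cost = _loop_energy(gi, gj)
                    if prev + cost < e:
                        e = prev + cost
            E[i][j] = e
            closed = e + (TERMINAL_AU if pair[i][j] in WOBBLE_OR_AU else 0.0)
            if closed < best:
                best = closed
    return best


def _internal_backend(window: str, mirna: str) -> float:
    return _hybrid_mfe(window, mirna[::-1])


def _rnaduplex_backend(window: str, mirna: str) -> float:
    exe = shutil.which("RNAduplex")
    if exe is None:
        raise RuntimeError(
            "RNAduplex not found on PATH; configure backend='internal' "
            "or provide a callable backend"
        )
    proc = subprocess.run(
        [exe, "--noconv"], input=f"{window}\n{mirna}\n", text=True,
        capture_output=True, check=True,
    )
    line = proc.stdout.strip().splitlines()[-1]
    energy = float(line[line.rfind("(") + 1 : line.rfind(")")])
    return min(0.0, energy)


Backend = Literal["internal", "rnaduplex"] | Callable[[str, str], float]


def duplex_energy(
    window_seq: str | RnaSequence,
    mirna_seq: str | RnaSequence,
    backend: Backend = "internal",
    linker: str = "XXXXXXXX",
) -> float:
    """Minimum free energy (kcal/mol) of the joined molecule
    [window + linker + miRNA], <= 0 by contract (the open structure has
    energy 0).

    The linker bases are unpairable placeholders; because both backends are
    intermolecular-only, any placeholder identity yields the same value.
    """
    w = window_seq.sequence if isinstance(window_seq, RnaSequence) else window_seq
    m = mirna_seq.sequence if isinstance(mirna_seq, RnaSequence) else mirna_seq
    w = w.upper().replace("T", "U")
    m = m.upper().replace("T", "U")
    if len(w) > 25:
        raise ValueError("window length must be <= 25 nt")
    if not set(w) <= RNA_ALPHABET or not set(m) <= RNA_ALPHABET:
        raise ValueError("sequences must be RNA over {A,C,G,U}")
    if not linker:
        raise ValueError("linker must be non-empty")
    if callable(backend):
        return min(0.0, float(backend(w, m)))
    if backend == "internal":
        return min(0.0, _internal_backend(w, m))
    if backend == "rnaduplex":
        return _rnaduplex_backend(w, m)
    raise ValueError(f"unknown backend {backend!r}")


# ---------------------------------------------------------------------------
# The energy walk
# ---------------------------------------------------------------------------

@dataclass
class EnergyWalkResult:
    mirna_id: str
    target_id: str
    min_energy: float  # kcal/mol
    window_start: int  # 1-based position of the optimal window
    n_windows: int


def n_windows(utr_length: int, window: int = 25, step: int = 5) -> int:
    """floor((L - window) / step) + 1; trailing partial windows are dropped."""
    if utr_length < window:
        raise ValueError("UTR shorter than the scan window")
    return (utr_length - window) // step + 1


def energy_walk(
    mirna: RnaSequence,
    utr: RnaSequence,
    window: int = 25,
    step: int = 5,
    backend: Backend = "internal",
) -> EnergyWalkResult:
    """Slide a ``window`` nt window along the 3'UTR in ``step`` nt steps and
    return the minimum duplex energy and its (1-based) window start; the
    first window attaining the minimum wins ties."""
    L = len(utr)
    count = n_windows(L, window, step)
    best_e, best_start = np.inf, 1
    for k in range(count):
        start0 = k * step
        e = duplex_energy(utr.sequence[start0 : start0 + window], mirna,
                          backend=backend)
        if e < best_e:
            best_e, best_start = e, start0 + 1
    return EnergyWalkResult(
        mirna_id=mirna.id, target_id=utr.id,
        min_energy=float(best_e), window_start=best_start, n_windows=count,
    )


def walk_pairs(
    pairs: Sequence[tuple[RnaSequence, RnaSequence]],
    window: int = 25,
    step: int = 5,
    backend: Backend = "internal",
) -> pd.DataFrame:
    """Run the energy walk over (miRNA, 3'UTR) pairs; returns a tidy frame
    with one row per pair."""
    recs = [energy_walk(m, u, window=window, step=step, backend=backend)
            for m, u in pairs]
    return pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in recs],
            "target_id": [r.target_id for r in recs],
            "min_energy": [r.min_energy for r in recs],
            "window_start": [r.window_start for r in recs],
            "n_windows": [r.n_windows for r in recs],
        }
    )


# ---------------------------------------------------------------------------
# Randomized controls
# ---------------------------------------------------------------------------

def randomize_labels(
    pairs: Sequence[tuple[RnaSequence, RnaSequence]], seed: int
) -> list[tuple[RnaSequence, RnaSequence]]:
    """Permute the gene (3'UTR) assignments while keeping the miRNA list and
    the multiset of target sequences fixed."""
    if len(pairs) < 2:
        raise ValueError("need >= 2 pairs to permute")
    rng = np.random.default_rng(seed)
    targets = [u for _, u in pairs]
    perm = rng.permutation(len(targets))
    return [(m, targets[perm[i]]) for i, (m, _) in enumerate(pairs)]


def random_rna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def randomize_sequences(
    pairs: Sequence[tuple[RnaSequence, RnaSequence]],
    pool: Sequence[RnaSequence],
    seed: int,
) -> list[tuple[RnaSequence, RnaSequence]]:
    """Substitute every target with a uniformly drawn pool 3'UTR (without
    replacement while the pool lasts; uniform-random synthetic sequences of
    matching length once exhausted)."""
    if not pool:
        raise ValueError("substitution pool must be non-empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    out = []
    for i, (m, u) in enumerate(pairs):
        if i < len(pool):
            out.append((m, pool[order[i]]))
        else:
            out.append(
                (m, RnaSequence(f"synthetic_{i}", random_rna(len(u), rng), kind="utr3"))
            )
    return out


# ---------------------------------------------------------------------------
# Distribution comparison
# ---------------------------------------------------------------------------

@dataclass
class EnergyComparison:
    group_x: str
    group_y: str
    mean_x: float
    mean_y: float
    t: float
    df: float
    pval: float


def welch_ttest(
    x: Sequence[float], y: Sequence[float],
    label_x: str = "x", label_y: str = "y",
) -> EnergyComparison:
    """Welch two sample t-test: t = (mean_x - mean_y)/sqrt(sx^2/nx + sy^2/ny)
    with Welch-Satterthwaite degrees of freedom and a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both samples")
    sx, sy = vx / len(x), vy / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx ** 2 / (len(x) - 1) + sy ** 2 / (len(y) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return EnergyComparison(label_x, label_y, float(x.mean()), float(y.mean()),
                            float(t), float(df), float(min(p, 1.0)))


def compare_energy_distributions(
    groups: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """All pairwise Welch comparisons between named groups of per-pair
    minimum energies (e.g. matched vs label-permuted vs sequence-substituted)."""
    names = list(groups)
    rows = []
    for i, gx in enumerate(names):
        for gy in names[i + 1 :]:
            c = welch_ttest(groups[gx], groups[gy], gx, gy)
            rows.append(
                {"group_x": gx, "group_y": gy, "mean_x": c.mean_x,
                 "mean_y": c.mean_y, "t": c.t, "df": c.df, "pval": c.pval}
            )
    return pd.DataFrame(rows)


def write_walk_results(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
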
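"""Expression-matrix I/O, per-feature differential statistics, and the
permutation-derived significance cutoff.

Matrices are log2 expression indexes (features x samples), the scale produced
by RMA-style pre-processing.  Fold change is the signed log2 difference of
group means.  The significance cutoff is auto-generated: the row test is
re-run on label-shuffled data and the smallest p-value seen under the null
becomes the threshold for the real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("mirhost")

Role = Literal["mrna", "mirna", "pseudo"]
RowTest = Literal["welch", "student", "anova"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A log2 feature x sample expression matrix with a declared role."""

    data: pd.DataFrame  # rows = features, columns = samples
    role: Role = "mrna"

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValueError("expression matrix needs >= 2 sample columns")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def col_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_rows(self, row_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(row_ids)], role=self.role)


@dataclass
class DesignTable:
    """Sample-to-group assignments.

    A single grouping vector drives t-tests; several factor columns are
    collapsed into one crossed factor for one-way ANOVA.
    """

    assignments: pd.Series  # index = sample ids, values = group labels

    def __post_init__(self) -> None:
        self.assignments = self.assignments.astype(str)
        if self.assignments.index.has_duplicates:
            raise ValueError("duplicate sample ids in design table")
        counts = self.assignments.value_counts()
        if len(counts) < 2:
            raise ValueError("design table needs >= 2 distinct groups")
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"each group needs >= 2 samples; too small: {small.index.tolist()}"
            )

    @classmethod
    def from_factors(cls, factors: pd.DataFrame) -> "DesignTable":
        if factors.shape[1] == 1:
            return cls(factors.iloc[:, 0])
        crossed = factors.astype(str).agg(".".join, axis=1)
        return cls(crossed)

    @property
    def groups(self) -> list[str]:
        # first-appearance order: the group listed first (typically the
        # control) is the fold-change baseline
        return list(dict.fromkeys(self.assignments))

    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.assignments.index]

    def covers(self, col_ids: Sequence[str]) -> bool:
        return set(col_ids) <= set(self.sample_ids())


@dataclass
class DiffStats:
    """Per-feature fold change, p-value and group means, row-aligned with the
    matrix that was tested."""

    table: pd.DataFrame  # index = feature ids; columns: fc, pval, + mean_<group>
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pv = self.table["pval"].to_numpy()
        if ((pv < 0) | (pv > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        if not np.isfinite(self.table["fc"].to_numpy()).all():
            raise ValueError("fold changes must be finite")

    @property
    def fc(self) -> pd.Series:
        return self.table["fc"]

    @property
    def pval(self) -> pd.Series:
        return self.table["pval"]

    def subset(self, row_ids: Sequence[str]) -> "DiffStats":
        return DiffStats(self.table.loc[list(row_ids)], groups=self.groups)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, role: Role = "mrna") -> ExpressionMatrix:
    """Read a delimited features x samples matrix (first column = feature id,
    header row = sample ids).  TSV by default, CSV for ``.csv`` files."""
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if raw.isna().any().any():
        r, c = next(zip(*np.where(raw.isna().to_numpy())))
        raise ValueError(
            f"{path}: ragged or missing cell at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}"
        )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = next(zip(*np.where(numeric.isna().to_numpy())))
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at row "
            f"{raw.index[r]!r}, column {raw.columns[c]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric.astype(float), role=role)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.data.to_csv(path, sep=_sep_for(path), index_label="feature_id")


def read_design(path: str | Path) -> DesignTable:
    """Two-column TSV (sample_id, group), or multi-column for crossed factors."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return DesignTable.from_factors(df)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Cross-array quantile normalization: each column is replaced by the
    across-column mean of the values of equal rank, so every column ends up
    with the identical multiset of values.  Idempotent."""
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    x = matrix.values
    order = np.argsort(x, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(x.shape[0])
    for j in range(x.shape[1]):
        ranks[order[:, j], j] = rows
    rank_means = np.sort(x, axis=0).mean(axis=1)
    out = rank_means[ranks]
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        role=matrix.role,
    )


# ---------------------------------------------------------------------------
# Row-wise differential statistics
# ---------------------------------------------------------------------------

def _group_arrays(
    matrix: ExpressionMatrix, design: DesignTable
) -> tuple[list[str], list[np.ndarray]]:
    if not design.covers(matrix.col_ids):
        missing = sorted(set(matrix.col_ids) - set(design.sample_ids()))
        raise ValueError(f"design table does not cover samples: {missing}")
    groups = design.groups
    cols = {g: [s for s in matrix.col_ids if design.assignments[s] == g] for g in groups}
    for g, cs in cols.items():
        if len(cs) < 2:
            raise ValueError(f"group {g!r} has <2 samples among matrix columns")
    x = matrix.data
    return groups, [x[cols[g]].to_numpy(dtype=float) for g in groups]


def row_stats(
    matrix: ExpressionMatrix,
    design: DesignTable,
    test: RowTest = "welch",
) -> DiffStats:
    """Per-row two-group t-test (Welch default, Student optional) or one-way
    ANOVA, with signed log2 fold change.

    fc = mean(group2) - mean(group1) with groups in sorted label order; for
    >2-group ANOVA, fc is the spread of the extreme pair of group means.
    Rows with zero variance everywhere and equal means get pval 1 / fc 0
    (degenerate rule, logged); zero variance with unequal means gets pval 0.
    """
    groups, arrays = _group_arrays(matrix, design)
    if test in ("welch", "student") and len(groups) != 2:
        raise ValueError(f"{test} t-test requires exactly 2 groups, got {len(groups)}")
    means = np.column_stack([a.mean(axis=1) for a in arrays])

    if test in ("welch", "student"):
        a, b = arrays
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sps.ttest_ind(b, a, axis=1, equal_var=(test == "student"))
        pval = np.asarray(res.pvalue, dtype=float)
        fc = means[:, 1] - means[:, 0]
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sps.f_oneway(*arrays, axis=1)
        pval = np.asarray(res.pvalue, dtype=float)
        if len(groups) == 2:
            fc = means[:, 1] - means[:, 0]
        else:
            fc = means.max(axis=1) - means.min(axis=1)

    # degenerate rows: no within-group variance anywhere
    allvar = np.column_stack([a.var(axis=1) for a in arrays]).sum(axis=1)
    degenerate = allvar == 0
    equal_means = np.isclose(means.max(axis=1), means.min(axis=1))
    bad = np.isnan(pval)
    pval = np.where(degenerate & equal_means, 1.0, pval)
    fc = np.where(degenerate & equal_means, 0.0, fc)
    pval = np.where(degenerate & ~equal_means, 0.0, pval)
    pval = np.nan_to_num(pval, nan=1.0)
    n_deg = int((degenerate | bad).sum())
    if n_deg:
        logger.info("row_stats: %d degenerate rows handled by fixed rule", n_deg)

    table = pd.DataFrame({"fc": fc, "pval": pval}, index=matrix.data.index)
    for j, g in enumerate(groups):
        table[f"mean_{g}"] = means[:, j]
    return DiffStats(table, groups=groups)


def permutation_cutoff(
    matrix: ExpressionMatrix,
    design: DesignTable,
    n_perm: int = 1,
    seed: int | None = None,
    test: RowTest = "welch",
) -> float:
    """Auto-generated p-value threshold: shuffle the sample-to-group labels
    (group sizes preserved), rerun the row test, and return the smallest
    p-value observed across all permutations and rows."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("permutation_cutoff requires an explicit seed")
    rng = np.random.default_rng(seed)
    labels = design.assignments.loc[list(matrix.col_ids)].to_numpy()
    cutoff = 1.0
    for _ in range(n_perm):
        for _attempt in range(100):
            shuffled = rng.permutation(labels)
            if len(np.unique(shuffled)) >= 2:
                break
        perm_design = DesignTable(pd.Series(shuffled, index=matrix.col_ids))
        stats = row_stats(matrix, perm_design, test=test)
        cutoff = min(cutoff, float(stats.pval.min()))
    return cutoff


def filter_significant(
    matrix: ExpressionMatrix, stats: DiffStats, cutoff: float
) -> tuple[ExpressionMatrix, DiffStats]:
    """Keep rows with pval < cutoff, preserving row order; empty survivor
    sets are returned (with a warning) rather than raised."""
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    keep = stats.table.index[stats.pval.to_numpy() < cutoff]
    keep = [i for i in matrix.data.index if i in set(keep)]
    if not keep:
        logger.warning("filter_significant: no rows below cutoff %.4g", cutoff)
        return _empty_like(matrix, stats)
    sub = ExpressionMatrix(matrix.data.loc[keep], role=matrix.role)
    return sub, stats.subset(keep)


def _empty_like(matrix: ExpressionMatrix, stats: DiffStats):
    em = ExpressionMatrix.__new__(ExpressionMatrix)
    em.data = matrix.data.iloc[0:0]
    em.role = matrix.role
    return em, DiffStats(stats.table.iloc[0:0], groups=stats.groups)
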
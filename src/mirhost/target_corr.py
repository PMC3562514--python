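"""miRNA-mRNA correlation matrix and anti-correlation target filtering.

Every row of the (pseudo-)miRNA matrix is correlated against every row of
the mRNA matrix; strongly negative entries nominate repression targets.  The
filter (``get_ht``) keeps entries at or below a negative cutoff, -0.8 by
default.  Interactions are then aggregated from (probeset, mature miRNA)
pairs to (gene, miRNA) records with a support count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mirmap import MappingTable
from .preprocess import ExpressionMatrix

logger = logging.getLogger("mirhost")

CorrMethod = Literal["pearson", "spearman", "kendall"]


@dataclass
class CorrelationMatrix:
    data: pd.DataFrame  # rows = miRNA ids, cols = mRNA feature ids
    method: CorrMethod

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_coefficients(self) -> int:
        return self.data.shape[0] * self.data.shape[1]


def correlation_matrix_cardinality(n_mirna_rows: int, n_mrna_rows: int) -> int:
    """Number of coefficients captured when every miRNA row is correlated
    against every mRNA row (the matrix-shape contract)."""
    return n_mirna_rows * n_mrna_rows


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((ac ** 2).sum(axis=1))
    bsd = np.sqrt((bc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(asd, bsd)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)  # NaN passes through clip unchanged


def correlate(
    mirna_like: ExpressionMatrix,
    mrna: ExpressionMatrix,
    method: CorrMethod = "pearson",
    chunk_rows: int = 2048,
) -> CorrelationMatrix:
    """Dense correlation matrix between all miRNA rows and all mRNA rows.

    Pearson product-moment, Spearman (average ranks on ties) or Kendall
    tau-b.  Zero-variance rows yield missing (NaN) entries, which never pass
    the anti-correlation filter.  mRNA rows are processed in chunks of
    ``chunk_rows`` so memory stays proportional to the output.
    """
    if mirna_like.col_ids != mrna.col_ids:
        raise ValueError("matrices must share identical sample columns")
    a = mirna_like.values
    b = mrna.values
    if method in ("pearson", "spearman"):
        if method == "spearman":
            a = sps.rankdata(a, axis=1)
            b = sps.rankdata(b, axis=1)
        blocks = [
            _rowwise_pearson(a, b[i : i + chunk_rows])
            for i in range(0, b.shape[0], chunk_rows)
        ]
        vals = np.hstack(blocks) if blocks else np.empty((a.shape[0], 0))
    elif method == "kendall":
        vals = np.empty((a.shape[0], b.shape[0]))
        for i in range(a.shape[0]):
            for j in range(b.shape[0]):
                if np.ptp(a[i]) == 0 or np.ptp(b[j]) == 0:
                    vals[i, j] = np.nan
                else:
                    vals[i, j] = sps.kendalltau(a[i], b[j]).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        logger.info("correlate: %d undefined entries (zero-variance rows)", n_missing)
    data = pd.DataFrame(vals, index=mirna_like.data.index, columns=mrna.data.index)
    return CorrelationMatrix(data, method=method)


def get_ht(corr: CorrelationMatrix, cutoff: float = -0.8) -> pd.DataFrame:
    """Extract all (miRNA, target) entries with correlation <= cutoff,
    sorted ascending (strongest anti-correlation first).

    The cutoff must be negative: it encodes strong reversed correlation.
    Missing entries never qualify.
    """
    if cutoff >= 0:
        raise ValueError("anti-correlation cutoff must be negative")
    vals = corr.values
    with np.errstate(invalid="ignore"):
        rows, cols = np.where(vals <= cutoff)
    out = pd.DataFrame(
        {
            "mirna_id": corr.data.index[rows],
            "target_id": corr.data.columns[cols],
            "correlation": vals[rows, cols],
        }
    )
    return out.sort_values("correlation", kind="stable").reset_index(drop=True)


@dataclass
class InteractionRecord:
    mirna_id: str
    gene_id: str
    target_ids: tuple[str, ...]
    correlation: float  # strongest (most negative) supporting value
    support: int
    direction: str  # repression_gained | repression_lifted | inconsistent


def direction_of_regulation(mirna_fc: float, gene_fc: float) -> str:
    """miRNA up & gene down -> repression_gained; miRNA down & gene up ->
    repression_lifted; concordant signs are kept but labeled inconsistent."""
    if mirna_fc > 0 and gene_fc < 0:
        return "repression_gained"
    if mirna_fc < 0 and gene_fc > 0:
        return "repression_lifted"
    return "inconsistent"


def translate_probes(
    probes: pd.Series, annotation: pd.DataFrame | None
) -> pd.DataFrame:
    """Map probeset ids to (gene_id, symbol, name) via a user-supplied
    annotation table indexed by probeset; unannotated probes keep their raw
    id and are flagged."""
    out = pd.DataFrame(index=probes.index)
    if annotation is None:
        out["gene_id"] = probes.values
        out["symbol"] = probes.values
        out["gene_name"] = ""
        out["annotated"] = False
        return out
    ann = annotation.reindex(probes.values)
    out["gene_id"] = np.where(
        ann["gene_id"].notna(), ann["gene_id"], probes.values
    )
    out["symbol"] = np.where(
        ann.get("symbol", pd.Series(index=ann.index, dtype=object)).notna(),
        ann.get("symbol"), probes.values,
    )
    out["gene_name"] = ann.get("gene_name", pd.Series(index=ann.index, dtype=object)).fillna("").values
    out["annotated"] = ann["gene_id"].notna().values
    return out


def summarize_interactions(
    interactions: pd.DataFrame,
    mapping: MappingTable | None = None,
    annotation: pd.DataFrame | None = None,
    mirna_fc: pd.Series | None = None,
    gene_fc: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """The three summary lists of the interaction report.

    1. ``genes_by_mirna`` — influenced genes grouped under each miRNA;
    2. ``mirnas_by_gene`` — miRNAs grouped under each influenced gene;
    3. ``interactions``  — all (miRNA, gene) records with a significance
       score (support = number of anti-correlated (probeset, mature-form)
       entries backing the pair) and, when fold changes are supplied, the
       direction of regulation.
    """
    work = interactions.copy()
    trans = translate_probes(work["target_id"], annotation)
    work = pd.concat([work, trans], axis=1)
    n_unann = int((~work["annotated"]).sum()) if annotation is not None else 0
    if n_unann:
        logger.warning("summarize_interactions: %d unannotated probes kept raw", n_unann)

    grouped = (
        work.groupby(["mirna_id", "gene_id"], sort=True)
        .agg(
            correlation=("correlation", "min"),
            support=("correlation", "size"),
            target_ids=("target_id", lambda s: ";".join(sorted(set(s)))),
            symbol=("symbol", "first"),
            gene_name=("gene_name", "first"),
        )
        .reset_index()
    )
    if mirna_fc is not None and gene_fc is not None:
        probe_fc = work.groupby(["mirna_id", "gene_id"])["target_id"].first()
        grouped["direction"] = [
            direction_of_regulation(
                float(mirna_fc.get(m, 0.0)),
                float(gene_fc.get(probe_fc.loc[(m, g)], 0.0)),
            )
            for m, g in zip(grouped["mirna_id"], grouped["gene_id"])
        ]
    grouped = grouped.sort_values(
        ["mirna_id", "correlation"], kind="stable"
    ).reset_index(drop=True)

    genes_by_mirna = grouped.sort_values(
        ["mirna_id", "correlation"], kind="stable"
    ).reset_index(drop=True)
    mirnas_by_gene = grouped.sort_values(
        ["gene_id", "correlation"], kind="stable"
    ).reset_index(drop=True)
    all_interactions = grouped.sort_values(
        ["support", "correlation"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return {
        "genes_by_mirna": genes_by_mirna,
        "mirnas_by_gene": mirnas_by_gene,
        "interactions": all_interactions,
    }
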
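"""The two miRNA pseudo-expression predictors.

Predictor I (scaling function) averages host-gene expression weighted by
w_i = |FC_i| * (1 - pval_i) * k_sense * k_overlap * k_evidence, where the k
coefficients encode the nature of the miRNA/host overlap (intronic loci are
promoted because splicing frees them for Drosha processing, while UTR and
exonic loci travel with the mature mRNA).

Predictor II (linear model) regresses measured miRNA expression on host
transcript expression and differential-expression covariates with a
per-miRNA identity factor.  The factorial interaction with that factor is
fitted as independent per-miRNA least-squares blocks (mathematically the
same model), each transcript predicts separately, and the per-miRNA
prediction is the median across its transcripts.

Both predictors feed the same significance call (row test + permutation
cutoff on the pseudo-expression matrix) and the consensus is the union.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .mirmap import MappedHosts, MappingEdge
from .preprocess import (
    DesignTable,
    DiffStats,
    ExpressionMatrix,
    RowTest,
    permutation_cutoff,
    row_stats,
)

logger = logging.getLogger("mirhost")

Variant = Literal["eq8", "eq9", "eq10"]

_OVERLAP_RANK = {"intron": 0, "exon": 1, "utr3": 2, "utr5": 3}


# ---------------------------------------------------------------------------
# Scaling function (Predictor I)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingCoefficients:
    """Edge-attribute coefficients of the scaling function."""

    k_sense: dict = field(
        default_factory=lambda: {"sense": 1.2, "antisense": 0.8}
    )
    k_overlap: dict = field(
        default_factory=lambda: {"intron": 2.0, "exon": 0.8, "utr3": 0.8, "utr5": 0.8}
    )
    k_evidence: dict = field(
        default_factory=lambda: {"experimental": 1.2, "predicted": 0.8}
    )

    def __post_init__(self) -> None:
        for d in (self.k_sense, self.k_overlap, self.k_evidence):
            if any(v <= 0 for v in d.values()):
                raise ValueError("scaling coefficients must be > 0")

    def edge_factor(self, edge: MappingEdge) -> float:
        return (
            self.k_sense[edge.strand_rel]
            * self.k_overlap[edge.overlap]
            * self.k_evidence[edge.evidence]
        )


def collapse_duplicate_hosts(
    entries: list[tuple[int, MappingEdge]]
) -> list[tuple[int, MappingEdge]]:
    """Collapse duplicate (row, probeset) entries for one miRNA to a single
    edge, preferring experimental evidence, then intronic overlap, then the
    lowest start coordinate."""
    best: dict[int, tuple[int, MappingEdge]] = {}
    order: list[int] = []
    for row, edge in entries:
        key = (
            0 if edge.evidence == "experimental" else 1,
            _OVERLAP_RANK.get(edge.overlap, 9),
            edge.start,
        )
        if row not in best:
            best[row] = (key, edge)  # type: ignore[assignment]
            order.append(row)
        elif key < best[row][0]:  # type: ignore[index]
            best[row] = (key, edge)  # type: ignore[assignment]
    return [(row, best[row][1]) for row in order]  # type: ignore[index]


def compute_weights(
    mapped_hosts: MappedHosts,
    stats: DiffStats,
    coeffs: ScalingCoefficients | None = None,
) -> dict[str, np.ndarray]:
    """Weight vector per mature miRNA: w_i = |FC_i|*(1-pval_i)*k_sense*
    k_overlap*k_evidence over its (collapsed) mapped host rows."""
    coeffs = coeffs or ScalingCoefficients()
    weights: dict[str, np.ndarray] = {}
    for mature, entries in mapped_hosts.hosts.items():
        entries = collapse_duplicate_hosts(entries)
        w = np.empty(len(entries))
        for k, (row, edge) in enumerate(entries):
            rid = mapped_hosts.matrix_row_ids[row]
            if rid not in stats.table.index:
                raise KeyError(f"no differential stats for probeset {rid!r}")
            fc = abs(float(stats.fc.loc[rid]))
            pv = float(stats.pval.loc[rid])
            w[k] = fc * (1.0 - pv) * coeffs.edge_factor(edge)
        weights[mature] = w
    return weights


@dataclass
class PseudoExpressionMatrix(ExpressionMatrix):
    predictor: Literal["scaling", "linear"] = "scaling"
    provenance: dict = field(default_factory=dict)  # mature id -> host row ids

    def __init__(self, data, predictor, provenance=None):
        super().__init__(data, role="pseudo")
        self.predictor = predictor
        self.provenance = provenance or {}


def scaling_predict(
    sig_matrix: ExpressionMatrix,
    stats: DiffStats,
    mapped_hosts: MappedHosts,
    coeffs: ScalingCoefficients | None = None,
    normalized: bool = False,
) -> PseudoExpressionMatrix:
    """Build the pseudo-expression matrix: per miRNA and sample, the mean of
    host expression times weight.

    The literal unweighted mean of elementwise products is the default; it
    can overestimate fold changes of highly expressed hosts, so a
    sum-of-weights-normalized variant is available via ``normalized=True``.
    miRNAs without any mapped host row are omitted.
    """
    if sig_matrix.role != "mrna":
        raise ValueError("scaling_predict expects an mRNA matrix")
    coeffs = coeffs or ScalingCoefficients()
    weights = compute_weights(mapped_hosts, stats, coeffs)
    x = sig_matrix.values
    rows, ids, provenance = [], [], {}
    for mature in sorted(mapped_hosts.hosts):
        entries = collapse_duplicate_hosts(mapped_hosts.hosts[mature])
        if not entries:
            continue
        w = weights[mature]
        e = x[[row for row, _ in entries], :]
        if np.all(w == 0):
            logger.warning("scaling_predict: all-zero weights for %s", mature)
            pseudo = np.zeros(x.shape[1])
        elif normalized:
            pseudo = (e * w[:, None]).sum(axis=0) / w.sum()
        else:
            pseudo = (e * w[:, None]).mean(axis=0)
        rows.append(pseudo)
        ids.append(mature)
        provenance[mature] = [sig_matrix.row_ids[row] for row, _ in entries]
    data = pd.DataFrame(np.array(rows), index=ids, columns=sig_matrix.col_ids)
    return PseudoExpressionMatrix(data, predictor="scaling", provenance=provenance)


# ---------------------------------------------------------------------------
# Linear model (Predictor II)
# ---------------------------------------------------------------------------

def build_design_rows(
    mirna_matrix: ExpressionMatrix | None,
    mrna_matrix: ExpressionMatrix,
    stats: DiffStats,
    mapped_hosts: MappedHosts,
    variant: Variant = "eq9",
) -> pd.DataFrame:
    """One long-format row per (miRNA, host transcript entry, sample).

    Columns: mirna_id, probeset, sample_id, e (host expression), fc_abs,
    omp (1 - pval), overlap, strand, evidence, and response (measured miRNA
    expression; NaN when ``mirna_matrix`` is None, i.e. prediction mode).
    """
    if variant not in ("eq8", "eq9", "eq10"):
        raise ValueError(f"unknown variant {variant!r}")
    if mirna_matrix is not None and mirna_matrix.col_ids != mrna_matrix.col_ids:
        raise ValueError("paired matrices must share identical sample columns")
    samples = mrna_matrix.col_ids
    x = mrna_matrix.values
    recs = []
    for mature in sorted(mapped_hosts.hosts):
        entries = collapse_duplicate_hosts(mapped_hosts.hosts[mature])
        if not entries:
            continue
        if mirna_matrix is not None:
            if mature not in mirna_matrix.data.index:
                continue
            resp = mirna_matrix.data.loc[mature].to_numpy(dtype=float)
        else:
            resp = np.full(len(samples), np.nan)
        for row, edge in entries:
            rid = mrna_matrix.row_ids[row]
            if rid not in stats.table.index:
                raise KeyError(f"no differential stats for probeset {rid!r}")
            fc = abs(float(stats.fc.loc[rid]))
            omp = 1.0 - float(stats.pval.loc[rid])
            for s_idx, s in enumerate(samples):
                recs.append(
                    (mature, rid, s, x[row, s_idx], fc, omp,
                     edge.overlap, edge.strand_rel, edge.evidence, resp[s_idx])
                )
    return pd.DataFrame(
        recs,
        columns=["mirna_id", "probeset", "sample_id", "e", "fc_abs", "omp",
                 "overlap", "strand", "evidence", "response"],
    )


def _variant_groups(variant: Variant, rows: pd.DataFrame, levels: dict | None):
    """Factor groups of the factorial expansion for one miRNA block.

    Continuous groups contribute one column; categorical groups contribute
    dummy columns (first level dropped).  The full design is all products of
    one column per group over every subset of groups, plus an intercept —
    the per-miRNA slice of the formula convention where ``*`` means main
    effects plus every interaction.
    """
    groups: list[tuple[str, list[tuple[str, np.ndarray]]]] = [
        ("e", [("e", rows["e"].to_numpy(float))])
    ]
    if variant in ("eq8", "eq9"):
        groups.append(("fc_abs", [("fc_abs", rows["fc_abs"].to_numpy(float))]))
        groups.append(("omp", [("omp", rows["omp"].to_numpy(float))]))
    if variant == "eq8":
        for cat in ("overlap", "strand", "evidence"):
            lv = (levels or {}).get(cat) or sorted(rows[cat].unique())
            cols = [
                (f"{cat}[{v}]", (rows[cat] == v).to_numpy(float)) for v in lv[1:]
            ]
            if cols:
                groups.append((cat, cols))
    return groups


def _factorial_design(
    groups: list[tuple[str, list[tuple[str, np.ndarray]]]], n: int
) -> tuple[np.ndarray, list[str]]:
    names = ["Intercept"]
    cols = [np.ones(n)]
    for r in range(1, len(groups) + 1):
        for subset in itertools.combinations(groups, r):
            for combo in itertools.product(*(g[1] for g in subset)):
                names.append(":".join(c[0] for c in combo))
                prod = np.ones(n)
                for c in combo:
                    prod = prod * c[1]
                cols.append(prod)
    return np.column_stack(cols), names


def _fit_block(X: np.ndarray, y: np.ndarray, names: list[str]):
    """OLS with QR-pivot elimination of aliased columns; returns coefficient,
    standard-error maps and the kept column names."""
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if len(diag) else 0)
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    Xk = X[:, keep]
    beta, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta
    dof = Xk.shape[0] - Xk.shape[1]
    if dof > 0:
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.pinv(Xk.T @ Xk)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    else:
        se = np.full(len(beta), np.nan)
    kept_names = [names[i] for i in keep]
    if rank < X.shape[1]:
        dropped = [names[i] for i in range(X.shape[1]) if i not in set(keep)]
        logger.debug("aliased columns dropped: %s", dropped)
    return dict(zip(kept_names, beta)), dict(zip(kept_names, se)), kept_names


@dataclass
class LinearModelFit:
    formula_variant: Variant
    mir_levels: list[str]
    coefficients: dict[str, dict[str, float]]  # mirna -> column -> beta
    std_errors: dict[str, dict[str, float]]
    factor_levels: dict[str, dict[str, list[str]]]  # mirna -> cat -> levels
    train_frac: float
    seed: int | None
    prefilter: str
    test_r: float


def fit_linear_model(
    rows: pd.DataFrame,
    variant: Variant = "eq9",
    train_frac: float = 2 / 3,
    seed: int | None = None,
    prefilter: str = "sense_intron",
) -> LinearModelFit:
    """Least-squares fit of the factorial covariate expansion with the
    miRNA-identity factor, as independent per-miRNA regressions.

    Rows are shuffled and split into a training set (``train_frac``, default
    2/3) and a held-out test set; the reported ``test_r`` is the Pearson
    correlation between median-aggregated predictions and observations on
    the test set.  miRNAs with <2 training rows are excluded (warned).
    """
    rows = rows.dropna(subset=["response"]).reset_index(drop=True)
    if not len(rows):
        raise ValueError("no training rows with a response")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(rows))
    n_train = max(1, int(round(train_frac * len(rows))))
    train = rows.iloc[perm[:n_train]]
    test = rows.iloc[perm[n_train:]]

    coefficients, std_errors, factor_levels, mir_levels = {}, {}, {}, []
    for mature, block in train.groupby("mirna_id", sort=True):
        if len(block) < 2:
            logger.warning("fit_linear_model: %s has <2 training rows; excluded", mature)
            continue
        levels = {
            cat: sorted(block[cat].unique()) for cat in ("overlap", "strand", "evidence")
        }
        groups = _variant_groups(variant, block, levels)
        X, names = _factorial_design(groups, len(block))
        beta, se, _ = _fit_block(X, block["response"].to_numpy(float), names)
        coefficients[mature] = {k: float(v) for k, v in beta.items()}
        std_errors[mature] = {k: float(v) for k, v in se.items()}
        factor_levels[mature] = levels
        mir_levels.append(str(mature))

    fit = LinearModelFit(
        formula_variant=variant,
        mir_levels=mir_levels,
        coefficients=coefficients,
        std_errors=std_errors,
        factor_levels=factor_levels,
        train_frac=train_frac,
        seed=seed,
        prefilter=prefilter,
        test_r=float("nan"),
    )
    if len(test):
        pred = _predict_rows(fit, test)
        merged = test.assign(pred=pred).groupby(
            ["mirna_id", "sample_id"], sort=False
        ).agg(pred=("pred", "median"), obs=("response", "first")).dropna()
        if len(merged) >= 2 and merged["pred"].std() > 0 and merged["obs"].std() > 0:
            fit.test_r = float(np.corrcoef(merged["pred"], merged["obs"])[0, 1])
    return fit


def _predict_rows(fit: LinearModelFit, rows: pd.DataFrame) -> np.ndarray:
    out = np.full(len(rows), np.nan)
    pos = {i: k for k, i in enumerate(rows.index)}
    for mature, block in rows.groupby("mirna_id", sort=False):
        if mature not in fit.coefficients:
            continue
        groups = _variant_groups(
            fit.formula_variant, block, fit.factor_levels.get(mature)
        )
        X, names = _factorial_design(groups, len(block))
        coef = fit.coefficients[mature]
        beta = np.array([coef.get(n, 0.0) for n in names])
        yhat = X @ beta
        for i, v in zip(block.index, yhat):
            out[pos[i]] = v
    return out


def lm_predict(
    fit: LinearModelFit,
    mrna_matrix: ExpressionMatrix,
    stats: DiffStats,
    mapped_hosts: MappedHosts,
) -> PseudoExpressionMatrix:
    """Predict the pseudo-expression matrix: per (miRNA, transcript, sample)
    predictions from the fitted per-miRNA coefficients, aggregated by the
    median across transcripts.  miRNAs absent from ``fit.mir_levels`` are
    omitted with a warning."""
    rows = build_design_rows(None, mrna_matrix, stats, mapped_hosts,
                             variant=fit.formula_variant)
    known = set(fit.mir_levels)
    skipped = sorted(set(rows["mirna_id"]) - known)
    if skipped:
        logger.warning("lm_predict: %d miRNAs not in the fitted model: %s",
                       len(skipped), skipped[:5])
    rows = rows[rows["mirna_id"].isin(known)].reset_index(drop=True)
    if not len(rows):
        raise ValueError("no predictable miRNAs: fit and mapping are disjoint")
    rows["pred"] = _predict_rows(fit, rows)
    agg = rows.groupby(["mirna_id", "sample_id"], sort=False)["pred"].median()
    data = agg.unstack("sample_id")[mrna_matrix.col_ids].sort_index()
    provenance = {
        m: sorted(set(g["probeset"])) for m, g in rows.groupby("mirna_id")
    }
    return PseudoExpressionMatrix(data, predictor="linear", provenance=provenance)


# ---------------------------------------------------------------------------
# Significance calls and consensus
# ---------------------------------------------------------------------------

@dataclass
class PredictorCalls:
    predictor: str
    cutoff: float
    stats: DiffStats
    directions: dict[str, str]  # mature id -> 'up' | 'down'

    @property
    def mirnas(self) -> set[str]:
        return set(self.directions)


def significant_mirnas(
    pseudo: PseudoExpressionMatrix,
    design: DesignTable,
    n_perm: int = 1,
    seed: int | None = None,
    test: RowTest = "welch",
) -> PredictorCalls:
    """Apply the row test plus the permutation-derived cutoff to a pseudo
    matrix; direction comes from the sign of the pseudo fold change."""
    if pseudo.shape[0] < 1:
        raise ValueError("pseudo matrix has no rows")
    stats = row_stats(pseudo, design, test=test)
    cutoff = permutation_cutoff(pseudo, design, n_perm=n_perm, seed=seed, test=test)
    sig = stats.table[stats.pval.to_numpy() < cutoff]
    directions = {
        str(i): ("up" if fc > 0 else "down") for i, fc in sig["fc"].items()
    }
    return PredictorCalls(pseudo.predictor, cutoff, stats, directions)


@dataclass
class ConsensusResult:
    provenance: dict[str, str]  # mature id -> 'scaling' | 'linear' | 'both'
    directions: dict[str, str]
    terminate: bool

    @property
    def mirnas(self) -> set[str]:
        return set(self.provenance)


def consensus(
    calls_scaling: PredictorCalls | None,
    calls_linear: PredictorCalls | None,
) -> ConsensusResult:
    """Union of the two predictors' significant sets with per-miRNA
    provenance flags; an empty union raises the pipeline's terminate flag."""
    s = calls_scaling.mirnas if calls_scaling else set()
    l = calls_linear.mirnas if calls_linear else set()
    provenance: dict[str, str] = {}
    directions: dict[str, str] = {}
    for m in sorted(s | l):
        provenance[m] = "both" if (m in s and m in l) else ("scaling" if m in s else "linear")
        src = calls_scaling if m in s else calls_linear
        directions[m] = src.directions[m]  # type: ignore[union-attr]
    return ConsensusResult(provenance, directions, terminate=not provenance)
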
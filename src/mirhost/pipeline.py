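"""End-to-end orchestration: pre-processing -> predictors -> significance ->
consensus -> anti-correlation targets -> summaries -> enrichment -> reports.

The run is configured from a flat YAML/JSON file or keyword overrides,
executes deterministically for a fixed seed, and writes a machine-readable
manifest plus CSV tables and a static HTML index.  When both predictors
return no significant miRNA the run terminates with a distinct condition
(exit code 3 at the CLI) rather than crashing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import GeneSetCollection, hypergeom_enrich, read_gmt
from .mirmap import MappingTable, filter_edges, map_expression_rows, read_mapping
from .predictors import (
    ConsensusResult,
    LinearModelFit,
    PredictorCalls,
    PseudoExpressionMatrix,
    ScalingCoefficients,
    build_design_rows,
    consensus,
    fit_linear_model,
    lm_predict,
    scaling_predict,
    significant_mirnas,
)
from .preprocess import (
    DesignTable,
    DiffStats,
    ExpressionMatrix,
    filter_significant,
    permutation_cutoff,
    read_design,
    read_expression,
    row_stats,
)
from .target_corr import correlate, get_ht, summarize_interactions

logger = logging.getLogger("mirhost")


class PipelineValidationError(ValueError):
    """Invalid configuration or inputs (CLI exit code 2)."""


class PipelineTerminated(RuntimeError):
    """Both predictors returned no significant miRNA (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    expression: str = ""
    design: str = ""
    mapping: str = ""
    genesets: list[str] = field(default_factory=list)
    annotation: str = ""
    mirna_training: str = ""          # paired miRNA matrix; enables the linear predictor
    predictor: str = "both"           # scaling | linear | both
    linear_variant: str = "eq9"
    linear_prefilter: bool = True     # sense-strand intronic edges only
    correlation_method: str = "pearson"
    cutoff: float = -0.8
    row_test: str = "welch"
    n_perm: int = 1
    seed: int | None = None
    out: str = "mirhost_out"

    def validate(self) -> None:
        if self.cutoff >= 0:
            raise PipelineValidationError("anti-correlation cutoff must be negative")
        if self.predictor not in ("scaling", "linear", "both"):
            raise PipelineValidationError(f"unknown predictor {self.predictor!r}")
        if self.seed is None:
            raise PipelineValidationError("seed is mandatory (stochastic stages enabled)")
        if self.predictor == "linear" and not self.mirna_training:
            raise PipelineValidationError(
                "the linear predictor needs a paired miRNA training matrix"
            )
        for p in [self.expression, self.design, self.mapping, *self.genesets]:
            if p and not Path(p).exists():
                raise PipelineValidationError(f"input path does not exist: {p}")


def load_config(path: str | Path, **overrides: Any) -> PipelineConfig:
    """Read a flat YAML or JSON config file; keyword overrides win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise PipelineValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    stats: DiffStats
    cutoff_pvalue: float
    sig_matrix: ExpressionMatrix
    calls_scaling: PredictorCalls | None
    calls_linear: PredictorCalls | None
    linear_fit: LinearModelFit | None
    consensus: ConsensusResult
    pseudo: PseudoExpressionMatrix
    interactions: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    enrichment: dict[str, pd.DataFrame]
    manifest: dict


def _consensus_pseudo(
    cons: ConsensusResult,
    pseudo_scaling: PseudoExpressionMatrix | None,
    pseudo_linear: PseudoExpressionMatrix | None,
) -> PseudoExpressionMatrix:
    """One pseudo row per consensus miRNA, taken from the predictor that
    called it (scaling preferred for 'both')."""
    rows, ids = [], []
    for m in sorted(cons.mirnas):
        src = pseudo_scaling if cons.provenance[m] in ("scaling", "both") else pseudo_linear
        assert src is not None
        rows.append(src.data.loc[m])
        ids.append(m)
    base = pseudo_scaling if pseudo_scaling is not None else pseudo_linear
    assert base is not None
    data = pd.DataFrame(rows, index=ids, columns=base.data.columns)
    return PseudoExpressionMatrix(data, predictor=base.predictor)


def run_pipeline(
    config: PipelineConfig,
    objects: dict[str, Any] | None = None,
) -> PipelineResult:
    """Execute the full flow.  ``objects`` may carry pre-built in-memory
    inputs (keys: expression, design, mapping, mirna_training, genesets,
    annotation) which take precedence over the configured paths."""
    config.validate()
    objects = objects or {}
    def _get(key, loader):
        return objects[key] if key in objects else loader()

    expr: ExpressionMatrix = _get(
        "expression", lambda: read_expression(config.expression, role="mrna")
    )
    design: DesignTable = _get("design", lambda: read_design(config.design))
    mapping: MappingTable = _get("mapping", lambda: read_mapping(config.mapping))
    genesets: list[GeneSetCollection] = _get(
        "genesets",
        lambda: [read_gmt(p, label=Path(p).stem) for p in config.genesets],
    )
    annotation = objects.get("annotation")
    if annotation is None and config.annotation:
        annotation = pd.read_csv(config.annotation, sep="\t", index_col=0, dtype=str)

    # --- pre-processing -----------------------------------------------------
    stats = row_stats(expr, design, test=config.row_test)  # type: ignore[arg-type]
    cutoff_p = permutation_cutoff(
        expr, design, n_perm=config.n_perm, seed=config.seed,
        test=config.row_test,  # type: ignore[arg-type]
    )
    sig_matrix, sig_stats = filter_significant(expr, stats, max(cutoff_p, 1e-300))
    counts = {"features": expr.shape[0], "significant_features": sig_matrix.shape[0]}
    if sig_matrix.shape[0] == 0:
        raise PipelineTerminated("no significant features below the permutation cutoff")

    # --- predictors ----------------------------------------------------------
    calls_scaling = calls_linear = None
    pseudo_scaling = pseudo_linear = None
    linear_fit = None
    if config.predictor in ("scaling", "both"):
        mapped_sig = map_expression_rows(mapping, sig_matrix)
        if mapped_sig.mirnas_with_hosts():
            pseudo_scaling = scaling_predict(
                sig_matrix, sig_stats, mapped_sig, ScalingCoefficients()
            )
            calls_scaling = significant_mirnas(
                pseudo_scaling, design, n_perm=config.n_perm, seed=config.seed,
                test=config.row_test,  # type: ignore[arg-type]
            )
    if config.predictor in ("linear", "both") and (
        config.mirna_training or "mirna_training" in objects
    ):
        mirna_train: ExpressionMatrix = _get(
            "mirna_training",
            lambda: read_expression(config.mirna_training, role="mirna"),
        )
        lm_mapping = (
            filter_edges(mapping, strand_rel="sense", overlap="intron")
            if config.linear_prefilter else mapping
        )
        if len(lm_mapping):
            mapped_full = map_expression_rows(lm_mapping, expr)
            rows = build_design_rows(
                mirna_train, expr, stats, mapped_full,
                variant=config.linear_variant,  # type: ignore[arg-type]
            )
            if len(rows):
                linear_fit = fit_linear_model(
                    rows, variant=config.linear_variant,  # type: ignore[arg-type]
                    seed=config.seed,
                )
                mapped_sig_lm = map_expression_rows(lm_mapping, sig_matrix)
                if mapped_sig_lm.mirnas_with_hosts():
                    pseudo_linear = lm_predict(
                        linear_fit, sig_matrix, sig_stats, mapped_sig_lm
                    )
                    calls_linear = significant_mirnas(
                        pseudo_linear, design, n_perm=config.n_perm,
                        seed=config.seed, test=config.row_test,  # type: ignore[arg-type]
                    )

    cons = consensus(calls_scaling, calls_linear)
    counts["consensus_mirnas"] = len(cons.mirnas)
    if cons.terminate:
        raise PipelineTerminated("both predictors returned no significant miRNA")

    # --- correlation & targets ----------------------------------------------
    pseudo = _consensus_pseudo(cons, pseudo_scaling, pseudo_linear)
    corr = correlate(pseudo, sig_matrix, method=config.correlation_method)  # type: ignore[arg-type]
    interactions = get_ht(corr, cutoff=config.cutoff)
    counts["correlation_cells"] = corr.n_coefficients
    counts["interactions"] = len(interactions)

    mirna_fc = pd.Series(
        {m: (calls_scaling.stats.fc.get(m) if cons.provenance[m] in ("scaling", "both")
             else calls_linear.stats.fc.get(m))  # type: ignore[union-attr]
         for m in cons.mirnas}, dtype=float,
    )
    summaries = summarize_interactions(
        interactions, mapping=mapping, annotation=annotation,
        mirna_fc=mirna_fc, gene_fc=stats.fc,
    )

    # --- enrichment -----------------------------------------------------------
    def translate(ids: pd.Index | list[str]) -> list[str]:
        if annotation is None:
            return [str(i) for i in ids]
        return [
            str(annotation["gene_id"].get(i, i)) if i in annotation.index else str(i)
            for i in ids
        ]

    universe = sorted(set(translate(expr.data.index)))
    query = sorted(set(summaries["interactions"]["gene_id"].astype(str)))
    enrich: dict[str, pd.DataFrame] = {}
    for coll in genesets:
        if query:
            enrich[coll.label] = hypergeom_enrich(query, coll, universe)
    counts["enriched_collections"] = len(enrich)

    manifest = {
        "package": "mirhost",
        "version": __version__,
        "seed": config.seed,
        "row_test": config.row_test,
        "permutation_cutoff": cutoff_p,
        "anticorrelation_cutoff": config.cutoff,
        "predictor": config.predictor,
        "counts": counts,
        "consensus_provenance": cons.provenance,
    }
    result = PipelineResult(
        config=config, stats=stats, cutoff_pvalue=cutoff_p, sig_matrix=sig_matrix,
        calls_scaling=calls_scaling, calls_linear=calls_linear,
        linear_fit=linear_fit, consensus=cons, pseudo=pseudo,
        interactions=interactions, summaries=summaries, enrichment=enrich,
        manifest=manifest,
    )
    render_reports(result, Path(config.out))
    return result


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _qc_tables(result: PipelineResult) -> dict[str, pd.DataFrame]:
    stats = result.stats
    hist, edges = np.histogram(stats.pval.to_numpy(), bins=20, range=(0, 1))
    pval_hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}
    )
    volcano = pd.DataFrame(
        {
            "feature_id": stats.table.index,
            "fc": stats.fc.to_numpy(),
            "neg_log10_pval": -np.log10(np.clip(stats.pval.to_numpy(), 1e-300, None)),
        }
    )
    x = result.sig_matrix.values.T if result.sig_matrix.shape[0] >= 2 else None
    if x is not None:
        xc = x - x.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        k = min(2, u.shape[1])
        pca = pd.DataFrame(
            u[:, :k] * s[:k],
            index=result.sig_matrix.col_ids,
            columns=[f"PC{i+1}" for i in range(k)],
        ).rename_axis("sample_id").reset_index()
    else:
        pca = pd.DataFrame(columns=["sample_id", "PC1", "PC2"])
    return {"qc_pvalue_histogram": pval_hist, "qc_volcano": volcano, "qc_pca": pca}


_HTML_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>mirhost report</title></head>
<body>
<h1>miRNA-mRNA interaction report</h1>
<p>{n_mirna} consensus miRNAs; {n_inter} anti-correlated interactions
(cutoff {cutoff}); permutation p-value cutoff {pcut:.3g}; seed {seed}.</p>
<h2>Tables</h2>
<ul>
{links}
</ul>
</body></html>
"""


def render_reports(result: PipelineResult, outdir: Path) -> list[Path]:
    """Write the three interaction lists, enrichment tables, QC data tables,
    the run manifest and a static HTML index; returns the written paths."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PipelineValidationError(f"cannot create output dir {outdir}: {exc}")
    written: list[Path] = []
    tables: dict[str, pd.DataFrame] = dict(result.summaries)
    for label, df in result.enrichment.items():
        tables[f"enrichment_{label}"] = df
    tables.update(_qc_tables(result))
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    written.append(manifest_path)

    links = "\n".join(f'<li><a href="{p.name}">{p.name}</a></li>' for p in written)
    html = _HTML_PAGE.format(
        n_mirna=len(result.consensus.mirnas),
        n_inter=len(result.interactions),
        cutoff=result.config.cutoff,
        pcut=result.cutoff_pvalue,
        seed=result.config.seed,
        links=links,
    )
    index = outdir / "index.html"
    index.write_text(html)
    written.append(index)
    return written
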
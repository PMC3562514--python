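"""Scaling-function and linear-model predictors, significance calls and the
consensus union."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg as sla

from mirhost import (
    DesignTable,
    DiffStats,
    ExpressionMatrix,
    MappingEdge,
    MappingTable,
    ScalingCoefficients,
    build_design_rows,
    compute_weights,
    consensus,
    correlate,
    fit_linear_model,
    lm_predict,
    make_paired_dataset,
    map_expression_rows,
    row_stats,
    scaling_predict,
    significant_mirnas,
)
from mirhost.predictors import LinearModelFit, PredictorCalls, _factorial_design, _variant_groups

UNIT_COEFFS = ScalingCoefficients(
    k_sense={"sense": 1.0, "antisense": 1.0},
    k_overlap={"intron": 1.0, "exon": 1.0, "utr3": 1.0, "utr5": 1.0},
    k_evidence={"experimental": 1.0, "predicted": 1.0},
)


def _edge(probeset, strand="sense", overlap="intron", evidence="experimental"):
    return MappingEdge(
        mirbase_id="mir-1", mature_ids=("mir-1",), strand_rel=strand,
        overlap=overlap, evidence=evidence, gene_id="G", transcript_id="T",
        probeset_ids=(probeset,), chromosome="chr1", start=1, end=100,
    )


def _matrix(values, row_ids, col_ids=None):
    col_ids = col_ids or [f"s{i}" for i in range(np.shape(values)[1])]
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, float), index=row_ids, columns=col_ids),
        role="mrna",
    )


def _stats(row_ids, fc, pval):
    return DiffStats(pd.DataFrame({"fc": fc, "pval": pval}, index=row_ids))


def _hosts(matrix, edges_by_row):
    mapped = map_expression_rows(
        MappingTable([e for _, e in edges_by_row]), matrix
    )
    return mapped


class TestComputeWeights:
    @pytest.mark.parametrize(
        "fc,pval,strand,overlap,evidence,expected",
        [
            (1.0, 0.0, "sense", "intron", "experimental", 1 * 1 * 1.2 * 2 * 1.2),
            (3.0, 1.0, "sense", "intron", "experimental", 0.0),
            (2.0, 0.5, "antisense", "exon", "predicted", 2 * 0.5 * 0.8 * 0.8 * 0.8),
            (-1.0, 0.0, "sense", "intron", "experimental", 2.88),  # |FC| is used
        ],
    )
    def test_weight_formula(self, fc, pval, strand, overlap, evidence, expected):
        m = _matrix([[1, 2]], ["ps1"], ["s0", "s1"])
        mapped = map_expression_rows(
            MappingTable([_edge("ps1", strand, overlap, evidence)]), m
        )
        w = compute_weights(mapped, _stats(["ps1"], [fc], [pval]))
        assert w["mir-1"][0] == pytest.approx(expected)

    def test_missing_stats_row_named(self):
        m = _matrix([[1, 2]], ["ps1"], ["s0", "s1"])
        mapped = map_expression_rows(MappingTable([_edge("ps1")]), m)
        with pytest.raises(KeyError, match="ps1"):
            compute_weights(mapped, _stats(["other"], [1.0], [0.0]))


class TestScalingPredict:
    def test_single_host_unit_weight_identity(self):
        m = _matrix([[4.0, 5.0, 6.0]], ["ps1"])
        mapped = map_expression_rows(MappingTable([_edge("ps1")]), m)
        pseudo = scaling_predict(m, _stats(["ps1"], [1.0], [0.0]), mapped,
                                 coeffs=UNIT_COEFFS)
        assert np.allclose(pseudo.data.loc["mir-1"], m.values[0])

    def test_two_host_weighted_mean(self):
        # hosts e=(4,6), weights (1, 0.5) -> mean(4*1, 6*0.5) = 3.5
        m = _matrix([[4.0, 4.0], [6.0, 6.0]], ["ps1", "ps2"])
        edges = MappingTable([_edge("ps1"), _edge("ps2")])
        mapped = map_expression_rows(edges, m)
        pseudo = scaling_predict(
            m, _stats(["ps1", "ps2"], [1.0, 0.5], [0.0, 0.0]), mapped,
            coeffs=UNIT_COEFFS,
        )
        assert pseudo.data.loc["mir-1", "s0"] == pytest.approx(3.5)

    def test_linear_in_expression(self, paired_dataset):
        mrna, _, mapping, design, _ = paired_dataset
        stats = row_stats(mrna, design)
        mapped = map_expression_rows(mapping, mrna)
        p1 = scaling_predict(mrna, stats, mapped)
        scaled = ExpressionMatrix(mrna.data * 3.0, role="mrna")
        p3 = scaling_predict(scaled, stats, mapped)
        assert np.allclose(p3.values, 3.0 * p1.values)

    def test_dominant_host_tracks_truth(self):
        mrna, mirna, mapping, design, truth = make_paired_dataset(
            seed=5, noise_sd=0.1
        )
        stats = row_stats(mrna, design)
        mid = sorted(truth.differential)[0]
        hosts = truth.hosts[mid]
        # suppress all but the first host via pval -> 1
        stats.table.loc[hosts[1:], "pval"] = 1.0
        stats.table.loc[hosts[0], "pval"] = 0.0
        mapped = map_expression_rows(mapping, mrna)
        pseudo = scaling_predict(mrna, stats, mapped)
        r = np.corrcoef(pseudo.data.loc[mid], mirna.data.loc[mid])[0, 1]
        assert r > 0.95

    def test_weighting_enriches_strong_correlations(self):
        """With spurious decoy edges in the mapping, the fold-change /
        p-value weighting recovers more strong miRNA correlations than the
        flat host mean."""
        mrna, mirna, mapping, design, _ = make_paired_dataset(
            seed=1, decoy_edges_per_mirna=10, noise_sd=0.4, diff_fraction=1.0
        )
        stats = row_stats(mrna, design)
        mapped = map_expression_rows(mapping, mrna)
        weighted = scaling_predict(mrna, stats, mapped)
        flat = _stats(mrna.row_ids, np.ones(mrna.shape[0]), np.zeros(mrna.shape[0]))
        unweighted = scaling_predict(mrna, flat, mapped, coeffs=UNIT_COEFFS)

        def high_corr_count(pseudo):
            common = [m for m in pseudo.data.index if m in mirna.data.index]
            r = [np.corrcoef(pseudo.data.loc[m], mirna.data.loc[m])[0, 1]
                 for m in common]
            return int(np.sum(np.asarray(r) >= 0.6))

        assert high_corr_count(weighted) >= high_corr_count(unweighted)


class TestDesignRows:
    def test_row_counts(self):
        mrna, mirna, mapping, design, _ = make_paired_dataset(
            n_samples=10, n_mirna=5, n_genes=30, seed=2
        )
        stats = row_stats(mrna, design)
        mapped = map_expression_rows(mapping, mrna)
        rows = build_design_rows(mirna, mrna, stats, mapped, variant="eq9")
        assert len(rows) == 5 * 3 * 10  # miRNAs x hosts x samples

    def test_unpaired_columns_rejected(self):
        mrna, mirna, mapping, design, _ = make_paired_dataset(
            n_samples=10, n_mirna=2, n_genes=12, seed=2
        )
        stats = row_stats(mrna, design)
        mapped = map_expression_rows(mapping, mrna)
        shrunk = ExpressionMatrix(mirna.data.iloc[:, :-1], role="mirna")
        with pytest.raises(ValueError, match="sample"):
            build_design_rows(shrunk, mrna, stats, mapped)


class TestFitLinearModel:
    def _noiseless(self, n_mirna=4, n_samples=12, seed=3):
        return make_paired_dataset(
            n_samples=n_samples, n_mirna=n_mirna, n_genes=n_mirna * 4,
            noise_sd=0.0, seed=seed, hosts_per_mirna=1, targets_per_mirna=3,
            diff_fraction=1.0,
        )

    def test_noiseless_truth_interpolated_exactly(self):
        mrna, mirna, mapping, design, truth = self._noiseless()
        stats = row_stats(mrna, design)
        mapped = map_expression_rows(mapping, mrna)
        rows = build_design_rows(mirna, mrna, stats, mapped, variant="eq10")
        fit = fit_linear_model(rows, variant="eq10", seed=0)
        assert fit.test_r == pytest.approx(1.0, abs=1e-9)
        for mid, (a, b) in truth.coefficients.items():
            coef = fit.coefficients[mid]
            assert coef["Intercept"] == pytest.approx(a, abs=1e-6)
            assert coef["e"] == pytest.approx(b, abs=1e-6)
        pseudo = lm_predict(fit, mrna, stats, mapped)
        assert np.allclose(
            pseudo.data.loc[mirna.data.index], mirna.data, atol=1e-9
        )

    def test_deterministic_under_seed(self):
        mrna, mirna, mapping, design, _ = make_paired_dataset(
            n_samples=10, n_mirna=3, n_genes=18, seed=4
        )
        stats = row_stats(mrna, design)
        rows = build_design_rows(
            mirna, mrna, stats, map_expression_rows(mapping, mrna)
        )
        f1 = fit_linear_model(rows, seed=7)
        f2 = fit_linear_model(rows, seed=7)
        assert f1.coefficients == f2.coefficients

    def test_per_mirna_blocks_equal_global_interaction_fit(self):
        """The miRNA-identity interaction model solved globally (one
        block-diagonal least-squares system) must match the per-miRNA fits."""
        mrna, mirna, mapping, design, _ = make_paired_dataset(
            n_samples=10, n_mirna=4, n_genes=24, seed=6, noise_sd=0.3
        )
        stats = row_stats(mrna, design)
        rows = build_design_rows(
            mirna, mrna, stats, map_expression_rows(mapping, mrna), variant="eq10"
        )
        fit = fit_linear_model(rows, variant="eq10", train_frac=1.0, seed=0)
        blocks, ys, names = [], [], []
        for mid, block in rows.groupby("mirna_id", sort=True):
            X, ns = _factorial_design(
                _variant_groups("eq10", block, None), len(block)
            )
            blocks.append(X)
            ys.append(block["response"].to_numpy(float))
            names.extend((mid, n) for n in ns)
        beta = np.linalg.lstsq(sla.block_diag(*blocks), np.concatenate(ys),
                               rcond=None)[0]
        oracle = {}
        for (mid, name), b in zip(names, beta):
            oracle.setdefault(mid, {})[name] = b
        for mid in fit.coefficients:
            for name, b in fit.coefficients[mid].items():
                assert b == pytest.approx(oracle[mid][name], abs=1e-8)

    def test_heldout_r_monotone_in_noise(self):
        rs = []
        for sd in (0.0, 0.1, 0.5, 1.0):
            mrna, mirna, mapping, design, _ = make_paired_dataset(
                n_samples=40, n_mirna=8, n_genes=64, seed=9, noise_sd=sd,
                diff_fraction=1.0, hosts_per_mirna=1,
            )
            stats = row_stats(mrna, design)
            rows = build_design_rows(
                mirna, mrna, stats, map_expression_rows(mapping, mrna)
            )
            rs.append(fit_linear_model(rows, variant="eq9", seed=1).test_r)
        assert all(a >= b - 1e-9 for a, b in zip(rs, rs[1:]))

    def test_median_aggregation_across_transcripts(self):
        # three transcripts predicting (2, 10, 4) for a sample -> median 4
        m = _matrix([[2.0, 2.0], [10.0, 10.0], [4.0, 4.0]],
                    ["ps1", "ps2", "ps3"])
        edges = MappingTable([_edge(p) for p in ("ps1", "ps2", "ps3")])
        mapped = map_expression_rows(edges, m)
        stats = _stats(["ps1", "ps2", "ps3"], [1.0] * 3, [0.0] * 3)
        fit = LinearModelFit(
            formula_variant="eq10", mir_levels=["mir-1"],
            coefficients={"mir-1": {"Intercept": 0.0, "e": 1.0}},
            std_errors={"mir-1": {}}, factor_levels={"mir-1": {}},
            train_frac=1.0, seed=0, prefilter="none", test_r=1.0,
        )
        pseudo = lm_predict(fit, m, stats, mapped)
        assert pseudo.data.loc["mir-1", "s0"] == pytest.approx(4.0)


class TestSignificanceAndConsensus:
    def test_planted_shift_called_with_direction(self):
        mrna, _, mapping, design, truth = make_paired_dataset(
            seed=12, noise_sd=0.05, effect=1.0
        )
        stats = row_stats(mrna, design)
        mapped = map_expression_rows(mapping, mrna)
        pseudo = scaling_predict(mrna, stats, mapped)
        calls = significant_mirnas(pseudo, design, n_perm=1, seed=3)
        planted = set(truth.differential)
        assert planted <= calls.mirnas
        for mid in planted:
            want = "up" if truth.differential[mid] > 0 else "down"
            assert calls.directions[mid] == want

    def test_null_data_rarely_calls(self):
        n_calls = []
        for seed in range(20):
            mrna, _, mapping, design, _ = make_paired_dataset(
                n_samples=10, n_mirna=10, n_genes=60, seed=100 + seed,
                effect=0.0, noise_sd=0.5, diff_fraction=0.0,
            )
            stats = row_stats(mrna, design)
            pseudo = scaling_predict(
                mrna, stats, map_expression_rows(mapping, mrna)
            )
            calls = significant_mirnas(pseudo, design, n_perm=1, seed=seed)
            n_calls.append(len(calls.mirnas))
        assert np.mean(n_calls) < 2.0

    def test_deterministic_calls(self, paired_dataset):
        mrna, _, mapping, design, _ = paired_dataset
        stats = row_stats(mrna, design)
        pseudo = scaling_predict(mrna, stats, map_expression_rows(mapping, mrna))
        a = significant_mirnas(pseudo, design, seed=5)
        b = significant_mirnas(pseudo, design, seed=5)
        assert a.directions == b.directions and a.cutoff == b.cutoff

    def _calls(self, directions, predictor="scaling"):
        return PredictorCalls(predictor, 0.01,
                              DiffStats(pd.DataFrame({"fc": [], "pval": []})),
                              directions)

    def test_union_with_provenance(self):
        cons = consensus(self._calls({"a": "up", "b": "down"}),
                         self._calls({"b": "down", "c": "up"}, "linear"))
        assert cons.mirnas == {"a", "b", "c"}
        assert cons.provenance == {"a": "scaling", "b": "both", "c": "linear"}
        assert not cons.terminate

    def test_one_empty_side(self):
        cons = consensus(None, self._calls({"x": "up"}, "linear"))
        assert cons.provenance == {"x": "linear"}

    def test_both_empty_terminates(self):
        cons = consensus(self._calls({}), self._calls({}, "linear"))
        assert cons.terminate and not cons.mirnas
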
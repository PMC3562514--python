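"""Duplex-energy backend, the sliding-window scan, randomized controls and
the Welch comparison machinery."""

import numpy as np
import pytest
from scipy import stats as sps

from mirhost import (
    RnaSequence,
    compare_energy_distributions,
    duplex_energy,
    energy_walk,
    make_mirna_sequences,
    make_sequences,
    n_windows,
    randomize_labels,
    randomize_sequences,
    read_fasta,
    reverse_complement,
    select_longest_utr,
    welch_ttest,
)
from mirhost.energy_walk import random_rna, walk_pairs


class TestSelectLongestUtr:
    def test_longest_isoform_selected(self):
        iso = {"G1": [RnaSequence("t1", "A" * 80), RnaSequence("t2", "A" * 150)]}
        out = select_longest_utr(iso)
        assert out["G1"].id == "t2"

    def test_short_gene_dropped(self):
        iso = {"G1": [RnaSequence("t1", "A" * 80), RnaSequence("t2", "A" * 99)]}
        assert select_longest_utr(iso) == {}

    def test_tie_breaks_on_transcript_id(self):
        iso = {"G1": [RnaSequence("tB", "G" * 120), RnaSequence("tA", "C" * 120)]}
        assert select_longest_utr(iso)["G1"].id == "tA"


class TestDuplexEnergy:
    def test_no_complementarity_is_zero(self):
        # an all-A window against an all-A miRNA cannot form any pair
        assert duplex_energy("A" * 25, "A" * 22) == 0.0

    def test_energy_is_never_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            e = duplex_energy(random_rna(25, rng), random_rna(22, rng))
            assert e <= 0.0

    def test_perfect_complement_beats_every_shuffle(self):
        rng = np.random.default_rng(1)
        mir = random_rna(22, rng)
        window = reverse_complement(mir)
        matched = duplex_energy(window, mir)
        chars = np.array(list(window))
        for _ in range(100):
            shuffled = "".join(rng.permutation(chars))
            assert matched < duplex_energy(shuffled, mir)

    def test_linker_identity_irrelevant(self):
        rng = np.random.default_rng(2)
        w, m = random_rna(25, rng), random_rna(22, rng)
        values = {duplex_energy(w, m, linker=l)
                  for l in ("XXXXXXXX", "NNNNNNNN", "LLLL")}
        assert len(values) == 1

    def test_dna_input_normalized(self):
        assert duplex_energy("ATGC" * 6, "AUGC" * 5) == duplex_energy(
            "AUGC" * 6, "AUGC" * 5
        )

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            duplex_energy("A" * 26, "A" * 22)

    def test_rank_agreement_with_external_engine(self):
        """The internal nearest-neighbour backend must rank candidate
        duplexes like an external folding engine (approximate agreement)."""
        rng = np.random.default_rng(3)
        internal, external = [], []
        for _ in range(200):
            w, m = random_rna(25, rng), random_rna(22, rng)
            internal.append(duplex_energy(w, m, backend="internal"))
            external.append(duplex_energy(w, m, backend="rnaduplex"))
        rho = sps.spearmanr(internal, external).statistic
        assert rho >= 0.8


class TestEnergyWalk:
    def test_window_count_formula(self):
        assert n_windows(100, 25, 5) == 16
        assert n_windows(25, 25, 5) == 1

    def test_short_utr_rejected(self):
        mir = RnaSequence("m", "ACGU" * 5, kind="mature_mirna")
        with pytest.raises(ValueError):
            energy_walk(mir, RnaSequence("u", "ACGU" * 5))

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(4)
        mir = RnaSequence("m", random_rna(22, rng), kind="mature_mirna")
        utr = RnaSequence("u", random_rna(130, rng))
        res = energy_walk(mir, utr, window=25, step=5)
        energies = [
            duplex_energy(utr.sequence[s : s + 25], mir)
            for s in range(0, 130 - 25 + 1, 5)
        ]
        assert res.min_energy == min(energies)
        assert res.window_start == 5 * int(np.argmin(energies)) + 1
        assert res.n_windows == len(energies)

    def test_planted_site_localized(self):
        rng = np.random.default_rng(5)
        mir = RnaSequence("m", random_rna(22, rng), kind="mature_mirna")
        seq = list(random_rna(100, rng))
        seq[40:62] = reverse_complement(mir.sequence)  # 1-based position 41
        res = energy_walk(mir, RnaSequence("u", "".join(seq)))
        assert abs(res.window_start - 41) <= 5

    def test_finer_step_never_raises_minimum(self):
        rng = np.random.default_rng(6)
        mir = RnaSequence("m", random_rna(22, rng), kind="mature_mirna")
        utr = RnaSequence("u", random_rna(150, rng))
        minima = [energy_walk(mir, utr, step=s).min_energy for s in (1, 5, 10)]
        assert minima[0] <= minima[1] <= minima[2]

    def test_bit_reproducible(self):
        rng = np.random.default_rng(7)
        mir = RnaSequence("m", random_rna(22, rng), kind="mature_mirna")
        utr = RnaSequence("u", random_rna(120, rng))
        a = energy_walk(mir, utr)
        b = energy_walk(mir, utr)
        assert (a.min_energy, a.window_start) == (b.min_energy, b.window_start)


class TestRandomizations:
    def _pairs(self, n=6, seed=8):
        mirs = make_mirna_sequences(n, seed=seed)
        pairs, _ = make_sequences(n, (110, 140), mirs, planted_fraction=1.0,
                                  seed=seed)
        return pairs

    def test_labels_preserve_multiset(self):
        pairs = self._pairs()
        permuted = randomize_labels(pairs, seed=1)
        assert sorted(u.sequence for _, u in permuted) == sorted(
            u.sequence for _, u in pairs
        )
        assert [m.id for m, _ in permuted] == [m.id for m, _ in pairs]

    def test_labels_deterministic(self):
        pairs = self._pairs(2)
        assert randomize_labels(pairs, seed=3) == randomize_labels(pairs, seed=3)

    def test_sequence_substitution_pool_of_one(self):
        pairs = self._pairs(1)
        # a single pair requires no permutation machinery
        pool = [RnaSequence("alt", "ACGU" * 30)]
        out = randomize_sequences(pairs, pool, seed=0)
        assert out[0][1].id == "alt"

    def test_sequence_substitution_falls_back_to_synthetic(self):
        pairs = self._pairs(4)
        pool = [RnaSequence("alt", "ACGU" * 30)]
        out = randomize_sequences(pairs, pool, seed=0)
        assert sum(u.id.startswith("synthetic") for _, u in out) == 3
        again = randomize_sequences(pairs, pool, seed=0)
        assert [u.sequence for _, u in again] == [u.sequence for _, u in out]


class TestWelch:
    def test_identical_samples_null(self):
        c = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.t == pytest.approx(0.0)
        assert c.pval == pytest.approx(1.0)

    def test_textbook_example_matches_reference(self):
        c = welch_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        ref = sps.ttest_ind([1, 2, 3], [2, 3, 4], equal_var=False)
        assert c.t == pytest.approx(-1.224745, abs=1e-6)
        assert c.df == pytest.approx(4.0, abs=1e-9)
        assert c.pval == pytest.approx(ref.pvalue, abs=1e-12)

    def test_antisymmetry(self):
        a = welch_ttest([1.0, 2.0, 4.0], [5.0, 6.0, 9.0])
        b = welch_ttest([5.0, 6.0, 9.0], [1.0, 2.0, 4.0])
        assert a.t == pytest.approx(-b.t)
        assert a.pval == pytest.approx(b.pval)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0, 1.0], [1.0, 1.0])

    def test_pairwise_grid(self):
        rng = np.random.default_rng(9)
        groups = {k: rng.normal(size=10) for k in ("a", "b", "c")}
        groups["a2"] = groups["a"].copy()
        grid = compare_energy_distributions(groups)
        assert len(grid) == 6
        row = grid[(grid.group_x == "a") & (grid.group_y == "a2")]
        assert row["pval"].iloc[0] == pytest.approx(1.0)


class TestFastaIO:
    def test_round_trip_ids_first_token(self, tmp_path):
        p = tmp_path / "seqs.fa"
        p.write_text(">utr1 some description\nACGUACGU\n>utr2\nGGGGCCCC\n")
        seqs = read_fasta(p, kind="utr3")
        assert [s.id for s in seqs] == ["utr1", "utr2"]
        assert seqs[0].sequence == "ACGUACGU"

    def test_t_normalized_to_u(self, tmp_path):
        p = tmp_path / "seqs.fa"
        p.write_text(">x\nACGT\n")
        assert read_fasta(p, kind="utr3")[0].sequence == "ACGU"


class TestPlantedSeparation:
    def test_planted_minima_lower_than_random(self):
        mirs = make_mirna_sequences(10, seed=10)
        planted, _ = make_sequences(10, (110, 150), mirs, planted_fraction=1.0,
                                    seed=11)
        unplanted, _ = make_sequences(10, (110, 150), mirs, planted_fraction=0.0,
                                      seed=12)
        e_planted = walk_pairs(planted)["min_energy"]
        e_random = walk_pairs(unplanted)["min_energy"]
        c = welch_ttest(e_planted, e_random)
        assert c.mean_x < c.mean_y
        assert c.pval < 0.01
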
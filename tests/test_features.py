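"""The nine features: hand examples, oracle equivalence, table assembly."""

import math

import numpy as np
import pandas as pd
import pytest

import oracle
from ucnescan import classify, features, synthetic
from ucnescan.features import (FeatureTable, build_feature_table,
                               compute_features, f1_gpc, f2_ccgg,
                               f3_l4_l3_ratio, f4_gc_triplets, f5_at_triplets,
                               f6_adjacent_pairs, f7_one_spacer_pairs,
                               f8_alt_ratio, f9_gc, ratio_R,
                               single_feature_power)
from ucnescan.seqio import MaskedSequence


class TestHandExamples:
    def test_f1_f2_gcgcgc(self):
        assert f1_gpc("GCGCGC") == pytest.approx(100 * 3 / 5)
        assert f2_ccgg("GCGCGC") == 0.0

    def test_f2_homopolymer(self):
        assert f1_gpc("CCCC") == 0.0
        assert f2_ccgg("CCCC") == pytest.approx(100.0)

    def test_f4_overlapping_triplets(self):
        assert f4_gc_triplets("GGGG") == pytest.approx(100.0)

    def test_f5_overlapping_triplets(self):
        assert f5_at_triplets("TTAA") == pytest.approx(100.0)

    def test_f6_f7_single_window(self):
        assert f6_adjacent_pairs("AATT") == pytest.approx(100.0)
        assert f7_one_spacer_pairs("ACAGC") == pytest.approx(100.0)

    def test_f8_hand_enumeration(self):
        assert f8_alt_ratio("AGAGAG") == 0.0
        assert f8_alt_ratio("ACAG") == pytest.approx(2.0)  # AC,CA vs AG
        assert math.isnan(f8_alt_ratio("ACAC"))  # no homotype dinucleotides

    @pytest.mark.parametrize("seq,expected", [
        ("GCGC", 100.0), ("ATAT", 0.0), ("ACGT", 50.0), ("ACGN", 2 / 3 * 100),
    ])
    def test_f9(self, seq, expected):
        assert f9_gc(seq) == pytest.approx(expected)

    def test_f3_equal_planted_occurrences(self):
        # one L=3 and one L=4 occurrence of the TA..GC pair
        seq = "TACGC" + "T" * 10 + "TACCGC" + "T" * 10
        assert f3_l4_l3_ratio(seq) == pytest.approx(100.0)

    def test_f3_zero_l3_is_nan(self):
        # one TAnnGC (L=4) occurrence and no L=3 occurrence of any pair
        assert math.isnan(f3_l4_l3_ratio("AACCGC" + "A" * 10))


class TestRatioR:
    def test_arithmetic(self):
        assert ratio_R(10, 20) == pytest.approx(100.0)

    def test_published_example_row(self):
        # F1=13.33, F2=11.9 gives R = 200*13.33/11.9 = 224.03%
        assert ratio_R(13.33, 11.9) == pytest.approx(224.03, abs=0.005)

    def test_degenerate_inputs(self):
        assert ratio_R(0, 0) == 0.0
        assert math.isnan(ratio_R(5, 0))


class TestOracleEquivalence:
    def test_all_features_match_brute_force(self, random_sequences):
        for seq in random_sequences:
            expect = oracle.oracle_features(seq.residues)
            fv = compute_features(seq)
            for name in features.FEATURE_NAMES:
                got = getattr(fv, name)
                want = expect[name]
                if want is None:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, rel=1e-12), name

    def test_case_invariance(self, random_sequences):
        seq = random_sequences[0]
        lower = MaskedSequence(seq.id, seq.residues.lower())
        assert compute_features(seq).values() == compute_features(lower).values()

    def test_binomial_expectation_for_f1(self, rng):
        # equal-composition sequence: GpC window probability is 1/16
        seq = MaskedSequence("u", "".join(rng.choice(list("ACGT"), 100_000)))
        assert f1_gpc(seq) == pytest.approx(100 / 16, abs=0.3)

    def test_determinism(self, random_sequences):
        seq = random_sequences[2]
        assert compute_features(seq) == compute_features(seq)


class TestGpcEnrichmentMonotonicity:
    def test_mean_f1_rises_f2_falls_with_enrichment(self):
        means = []
        for fold in (1.0, 1.3, 1.6):
            spec = synthetic.spec_from_targets(40.0, fold, 1 / fold)
            seqs = synthetic.markov_generate(spec, 30, seed=5)
            f1 = np.mean([f1_gpc(s) for s in seqs])
            f2 = np.mean([f2_ccgg(s) for s in seqs])
            means.append((f1, f2))
        assert means[0][0] < means[1][0] < means[2][0]
        assert means[0][1] > means[1][1] > means[2][1]


class TestFeatureTable:
    def _toy_seqs(self, n, prefix, rng):
        return [MaskedSequence(f"{prefix}{i}",
                               "".join(rng.choice(list("ACGT"), 250)))
                for i in range(n)]

    def test_labels_and_layout(self, rng):
        table = build_feature_table(self._toy_seqs(5, "p", rng),
                                    self._toy_seqs(5, "n", rng))
        assert list(table.frame["Class"]) == [1] * 5 + [0] * 5
        assert list(table.frame.columns) == ["ID", *features.FEATURE_NAMES, "Class"]

    def test_empty_negatives_rejected(self, rng):
        with pytest.raises(ValueError):
            build_feature_table(self._toy_seqs(3, "p", rng), [])

    def test_duplicate_ids_rejected(self, rng):
        seqs = self._toy_seqs(3, "x", rng)
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(seqs, seqs)

    def test_tsv_round_trip(self, tmp_path, small_table):
        p = tmp_path / "t.tsv"
        small_table.to_tsv(p)
        back = FeatureTable.from_tsv(p)
        pd.testing.assert_frame_equal(back.frame, small_table.frame)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="below the minimum"):
            compute_features(MaskedSequence("s", "ACGT" * 10))

    def test_sentinel_fills_degenerate_f3(self, rng):
        # one positive engineered to have no L3 occurrence at all
        weird = MaskedSequence("w", "A" * 250)
        normal = self._toy_seqs(4, "p", rng)
        with pytest.warns(UserWarning, match="sentinel"):
            table = build_feature_table([weird] + normal,
                                        self._toy_seqs(5, "n", rng))
        col = table.frame["F3"]
        assert not col.isna().any()
        assert col.iloc[0] == col.iloc[1:].max()  # table-wide max sentinel

    def test_scale_invariance_through_zscore(self, small_table):
        X = small_table.X
        scaled = X.copy()
        scaled[:, 3] *= 7.3
        z1 = classify.zscore_apply(classify.zscore_fit(X), X)
        z2 = classify.zscore_apply(classify.zscore_fit(scaled), scaled)
        np.testing.assert_allclose(z1, z2, rtol=1e-9)

    def test_f9_invariant_under_dinucleotide_shuffle(self, random_sequences):
        from ucnescan.sampling import dinucleotide_shuffle
        seq = random_sequences[3]
        assert f9_gc(seq) == f9_gc(dinucleotide_shuffle(seq, 1).residues)


class TestSingleFeaturePower:
    def test_separable(self):
        assert single_feature_power([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_alternating_labels_best_cut(self):
        # exhaustive search: predict 1 for the single smallest value
        assert single_feature_power([1, 2, 3, 4], [1, 0, 1, 0]) == 0.75

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            v = rng.normal(size=40).round(1)  # rounding forces ties
            y = (rng.random(40) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            assert single_feature_power(v, y) == \
                pytest.approx(oracle.brute_force_power(list(v), list(y)))

    def test_independent_labels_approach_class_prior(self, rng):
        n = 4000
        v = rng.normal(size=n)
        y = (rng.random(n) < 0.5).astype(int)
        prior = max(y.mean(), 1 - y.mean())
        assert single_feature_power(v, y) == pytest.approx(prior, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            single_feature_power([1, 2, 3], [1, 1, 1])
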
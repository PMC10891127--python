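import numpy as np
import pandas as pd
import pytest

import clonalsig as cs

from .oracles import hypergeom_tail_by_enumeration


class TestHypergeometricOverlap:
    def test_small_case_equals_enumeration_fraction(self):
        # N=10, K=4, n=3, k=2: exactly 1/3 of all C(10,3) draws hit >= 2
        r = cs.hypergeometric_overlap(10, 4, 3, 2)
        assert r.p == pytest.approx(1 / 3, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        assert cs.hypergeometric_overlap(50, 10, 5, 0).p == 1.0

    def test_published_overlap_counts(self):
        # the four printed set sizes; both tail conventions pinned
        r = cs.hypergeometric_overlap(7064, 948, 472, 208)
        assert r.p == pytest.approx(1.4188209944e-65, rel=1e-8)
        assert r.p_phyper == pytest.approx(2.2615920485e-66, rel=1e-8)
        assert r.p_phyper <= 1.19e-65
        assert r.enrichment_ratio == pytest.approx(208 / (948 * 472 / 7064), rel=1e-12)

    def test_agrees_with_scipy_tail(self):
        from scipy.stats import hypergeom

        for (N, K, n, k) in [(100, 30, 20, 10), (1000, 100, 50, 3), (7064, 948, 472, 208)]:
            r = cs.hypergeometric_overlap(N, K, n, k)
            assert r.p == pytest.approx(float(hypergeom.sf(k - 1, N, K, n)), rel=1e-9)

    @pytest.mark.parametrize("N", [5, 8, 12])
    def test_exhaustive_enumeration_sweep(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                lo = max(0, K + n - N)
                for k in range(lo, min(K, n) + 1):
                    r = cs.hypergeometric_overlap(N, K, n, k)
                    ref = hypergeom_tail_by_enumeration(N, K, n, k)
                    assert r.p == pytest.approx(ref, abs=1e-12)

    def test_p_monotone_nonincreasing_in_k(self):
        ps = [cs.hypergeometric_overlap(60, 20, 15, k).p for k in range(16)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_invalid_overlaps_rejected(self):
        with pytest.raises(ValueError):
            cs.hypergeometric_overlap(10, 4, 3, 4)  # k > min(K, n)
        with pytest.raises(ValueError):
            cs.hypergeometric_overlap(10, 9, 8, 2)  # k < K + n - N

    def test_no_underflow_for_extreme_tails(self):
        r = cs.hypergeometric_overlap(20000, 10000, 700, 690)
        assert 0 < r.p < 1e-190
        deep = cs.hypergeometric_overlap(20000, 5000, 490, 490)
        assert 0 < deep.p < 1e-300

    def test_overlap_from_sets_restricts_to_universe(self):
        uni = [f"g{i}" for i in range(10)]
        r = cs.overlap_from_sets(uni, ["g0", "g1", "g2", "g3", "zzz"], ["g0", "g1", "g9"])
        assert (r.N, r.K, r.n, r.k) == (10, 4, 3, 2)


class TestCnvFrequencies:
    def test_hand_counted_calls(self):
        calls = pd.DataFrame(
            [[1, 1, 0, -1]], index=["g"], columns=list("abcd")
        )
        prof = cs.cnv_frequencies(calls)
        assert prof.table.loc["g", "amp_freq"] == 0.5
        assert prof.table.loc["g", "del_freq"] == 0.25

    def test_all_zero_matrix_gives_zero_frequencies(self):
        calls = pd.DataFrame(0, index=["g1", "g2"], columns=list("abc"))
        prof = cs.cnv_frequencies(calls)
        assert (prof.table.to_numpy() == 0).all()

    def test_real_valued_thresholds_match_pre_thresholded_calls(self):
        rng = np.random.default_rng(4)
        raw = pd.DataFrame(
            rng.normal(0, 0.5, size=(20, 30)),
            index=[f"g{i}" for i in range(20)],
        )
        calls = pd.DataFrame(
            np.where(raw >= 0.3, 1, np.where(raw <= -0.3, -1, 0)),
            index=raw.index, columns=raw.columns,
        )
        a = cs.cnv_frequencies(raw).table
        b = cs.cnv_frequencies(calls, amp_threshold=0.5, del_threshold=-0.5).table
        pd.testing.assert_frame_equal(a, b)

    def test_frequencies_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(5)
        calls = pd.DataFrame(
            rng.integers(-1, 2, size=(10, 25)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(25)],
        )
        shuffled = calls[rng.permutation(calls.columns)]
        pd.testing.assert_frame_equal(
            cs.cnv_frequencies(calls).table, cs.cnv_frequencies(shuffled).table
        )

    def test_non_finite_entries_rejected(self):
        calls = pd.DataFrame([[np.nan]], index=["g"], columns=["s"])
        with pytest.raises(ValueError, match="non-finite"):
            cs.cnv_frequencies(calls)


class TestBandAggregate:
    def test_band_mean_of_two_genes(self):
        prof = cs.CnvFrequencyProfile(
            table=pd.DataFrame(
                {"amp_freq": [0.2, 0.4], "del_freq": [0.0, 0.1]},
                index=["g1", "g2"],
            ),
            n_samples=10,
        )
        bm = pd.Series(["1p36", "1p36"], index=["g1", "g2"])
        agg = cs.band_aggregate(prof, bm)
        assert agg.table.loc["1p36", "amp_freq"] == pytest.approx(0.3)
        assert agg.table.loc["1p36", "del_freq"] == pytest.approx(0.05)

    def test_identical_member_frequencies_pass_through(self):
        prof = cs.CnvFrequencyProfile(
            table=pd.DataFrame(
                {"amp_freq": [0.7, 0.7, 0.1], "del_freq": [0.0, 0.0, 0.0]},
                index=["g1", "g2", "g3"],
            ),
            n_samples=5,
        )
        bm = pd.Series(["b1", "b1", "b2"], index=["g1", "g2", "g3"])
        agg = cs.band_aggregate(prof, bm)
        assert agg.table.loc["b1", "amp_freq"] == pytest.approx(0.7)

    def test_unmapped_genes_excluded(self):
        prof = cs.CnvFrequencyProfile(
            table=pd.DataFrame(
                {"amp_freq": [0.5, 0.9], "del_freq": [0.0, 0.0]}, index=["g1", "gX"]
            ),
            n_samples=4,
        )
        bm = pd.Series(["b1"], index=["g1"])
        agg = cs.band_aggregate(prof, bm)
        assert list(agg.table.index) == ["b1"]
        assert agg.table.loc["b1", "amp_freq"] == pytest.approx(0.5)


class TestCorrelateProfiles:
    def test_identity_and_reversal(self):
        a = pd.Series([0.1, 0.5, 0.9, 0.3], index=list("abcd"))
        r, _ = cs.correlate_profiles(a, a)
        assert r == pytest.approx(1.0)
        r2, _ = cs.correlate_profiles(a, -a)
        assert r2 == pytest.approx(-1.0)

    def test_too_few_shared_keys_rejected(self):
        a = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValueError, match="shared"):
            cs.correlate_profiles(a, a)
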
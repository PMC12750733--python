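import numpy as np
import pandas as pd
import pytest

from duinet import synthetic
from duinet.expression import (
    FEMALE,
    MALE,
    UNASSIGNED,
    classify_sex_bias,
    cpm,
    cpm_filter,
    de_test,
    sexratio_correlation,
    tmm_factors,
)

from oracles import naive_tmm_factors


class TestSexBias:
    @pytest.mark.parametrize(
        "ratios,label",
        [
            ((0.75, 0.72, 0.71), MALE),
            ((0.20, 0.25, 0.28), FEMALE),
            ((0.5, 0.6, 0.4), UNASSIGNED),
            ((0.70,), MALE),         # boundary: median exactly 0.70
            ((0.30,), FEMALE),       # boundary: dispersed exactly 0.70
            ((0.69, 0.69, 0.69), UNASSIGNED),
        ],
    )
    def test_median_rule(self, ratios, label):
        assert classify_sex_bias(ratios) == label

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_sex_bias([])


class TestCpmFilter:
    def _matrix(self, rows):
        # integer counts with library size exactly 1e6 per sample, so a
        # count of 2 is exactly 2 cpm
        rows = np.array(rows, dtype=np.int64)
        pad = np.full((50, 8), 20000, dtype=np.int64)
        pad[0] -= rows.sum(axis=0)
        mat = np.vstack([rows, pad])
        assert (mat.sum(axis=0) == 1_000_000).all()
        idx = [f"f{i}" for i in range(len(rows))] + [
            f"pad{i}" for i in range(50)
        ]
        return pd.DataFrame(mat, index=idx, columns=list("ABCDEFGH"))

    def test_boundaries(self):
        counts = self._matrix(
            [
                [1] * 8,            # below threshold everywhere (1 cpm)
                [2] + [0] * 7,      # exactly 2 cpm in one sample
                [0] * 8,            # all zero
            ]
        )
        kept = cpm_filter(counts, min_cpm=2.0)
        assert "f0" not in kept
        assert "f1" in kept
        assert "f2" not in kept


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        col = np.arange(1, 201, dtype=float)
        counts = pd.DataFrame({s: col for s in "ABCD"})
        f, norm = tmm_factors(counts)
        assert np.allclose(f.values, 1.0, atol=1e-12)

    def test_sample_order_invariance(self, rng):
        cm, _ = synthetic.simulate_counts(400, 6, de_frac=0.0, seed=21)
        f1, _ = tmm_factors(cm.counts)
        perm = list(cm.counts.columns[::-1])
        f2, _ = tmm_factors(cm.counts[perm])
        assert np.allclose(f1[perm].values, f2.values, atol=1e-12)

    def test_matches_naive_reimplementation(self):
        cm, _ = synthetic.simulate_counts(600, 8, de_frac=0.02, seed=22)
        f, _ = tmm_factors(cm.counts)
        ref = naive_tmm_factors(cm.counts)
        for s in cm.counts.columns:
            assert abs(f[s] - ref[s]) < 1e-6

    def test_zero_overlap_rejected(self):
        counts = pd.DataFrame(
            {"A": [5, 0, 9, 4, 2], "B": [0, 7, 0, 0, 0]}, dtype=float
        )
        with pytest.raises(ValueError, match="positive"):
            tmm_factors(counts, ref_sample="A")


class TestDeTest:
    def test_constant_feature_not_called(self):
        cm, _ = synthetic.simulate_counts(200, 8, de_frac=0.0, seed=23)
        norm = cpm(cm.counts)
        norm.iloc[0] = 55.5
        out = de_test(norm, cm.groups.to_numpy(), seed=1)
        row = out.iloc[0]
        assert row["M"] == 0.0 and row["D"] == 0.0
        assert row["prob"] == 0.0 and not row["called"]

    def test_calls_invariant_to_library_rescaling(self):
        cm, _ = synthetic.simulate_counts(400, 8, de_frac=0.05, seed=24)
        kept = cpm_filter(cm.counts)
        _, n1 = tmm_factors(cm.counts.loc[kept])
        scaled = cm.counts.copy()
        scaled["S1"] = (scaled["S1"] * 3).astype(int)  # triple one library
        _, n2 = tmm_factors(scaled.loc[kept])
        d1 = de_test(n1, cm.groups.to_numpy(), seed=2)
        d2 = de_test(n2, cm.groups.to_numpy(), seed=2)
        agree = (d1["called"] == d2["called"]).mean()
        assert agree > 0.98

    def test_insufficient_null_resolution_rejected(self):
        norm = pd.DataFrame(np.ones((10, 4)), columns=list("ABCD"))
        with pytest.raises(ValueError, match="resolve"):
            de_test(norm, ["a", "a", "b", "b"], q=0.95)

    def test_two_tier_reporting_subset(self):
        # features called AND correlation-significant form a subset of called
        cm, _ = synthetic.simulate_counts(500, 8, de_frac=0.05, seed=25)
        kept = cpm_filter(cm.counts)
        _, norm = tmm_factors(cm.counts.loc[kept])
        de = de_test(norm, cm.groups.to_numpy(), seed=3)
        sig = cm.sex_ratios.to_numpy()
        called = de.index[de["called"]]
        corr_sig = {
            f for f in called
            if sexratio_correlation(norm.loc[f], sig)[1] < 0.05
        }
        assert corr_sig <= set(called)
        assert len(corr_sig) <= len(called)


class TestSpearman:
    def test_monotone_pairs(self):
        rho, p = sexratio_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho, _ = sexratio_correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_at_n8(self):
        x = list(range(8))
        y = [v * 2.0 + 1 for v in x]
        rho, p = sexratio_correlation(x, y)
        assert rho == pytest.approx(1.0)
        # exactly two of the 8! rankings reach |rho| = 1
        assert p == pytest.approx(2 / 40320, rel=1e-9)

    def test_constant_vector_flagged(self):
        rho, p = sexratio_correlation([1.0] * 8, list(range(8)))
        assert np.isnan(rho)
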
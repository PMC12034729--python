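import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from cislink.cis_pairing import CisPair
from cislink.correlation import (
    CorrelationConfig,
    pearson_p,
    pearson_r,
    permutation_p,
    screen_pairs,
)
from cislink.diffexpr import ExpressionMatrix


def t_sf_by_integration(t, df):
    """Independent oracle: numerically integrate the Student t density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    val, _ = integrate.quad(lambda u: c * (1 + u * u / df) ** (-(df + 1) / 2), t, np.inf)
    return val


class TestPearsonR:
    def test_self_correlation_is_one(self):
        assert pearson_r([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_worked_covariance_example(self):
        # hand evaluation: sum(dx*dy) = 14.5, sum(dx^2) = sum(dy^2) = 17.5
        r = pearson_r([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5])
        assert r == pytest.approx(14.5 / 17.5, abs=1e-12)

    def test_zero_variance_flagged_undefined(self):
        assert math.isnan(pearson_r([5, 5, 5, 5], [1, 2, 3, 4]))

    @settings(max_examples=60, deadline=None)
    @given(
        xs=st.lists(st.floats(-100, 100), min_size=4, max_size=12),
        a=st.floats(0.01, 50),
        b=st.floats(-100, 100),
    )
    def test_symmetric_and_affine_invariant(self, xs, a, b):
        rng = np.random.default_rng(len(xs))
        ys = rng.normal(size=len(xs))
        x = np.asarray(xs)
        # spread below float epsilon is destroyed by the shift b itself
        if np.ptp(x) < 1e-6:
            return
        r = pearson_r(x, ys)
        if math.isnan(r):
            return
        assert pearson_r(ys, x) == pytest.approx(r, abs=1e-9)
        assert pearson_r(a * x + b, ys) == pytest.approx(r, abs=1e-6)


class TestPearsonP:
    def test_null_r_gives_p_one(self):
        for n in (3, 10, 50):
            assert pearson_p(0.0, n) == pytest.approx(1.0)

    def test_perfect_r_gives_p_zero(self):
        assert pearson_p(1.0, 5) == 0.0
        assert pearson_p(-1.0, 5) == 0.0

    def test_worked_example_n6(self):
        # r = 14.5/17.5 -> t = 2.9597 on 4 df -> p about 0.0415
        p = pearson_p(14.5 / 17.5, 6)
        assert p == pytest.approx(0.0415, abs=5e-4)

    @pytest.mark.parametrize("r,n", [(0.3, 8), (0.6, 15), (0.9, 5), (-0.75, 30)])
    def test_matches_t_density_integration(self, r, n):
        t = abs(r) * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        assert pearson_p(r, n) == pytest.approx(2 * t_sf_by_integration(t, n - 2), abs=1e-6)

    def test_strictly_decreasing_in_abs_r_and_n(self):
        ps = [pearson_p(r, 10) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        ps = [pearson_p(0.5, n) for n in (5, 10, 20, 40)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pearson_p(0.5, 2)


class TestPermutationP:
    def test_agrees_with_t_on_gaussian_data(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.normal(size=10)
            y = 0.5 * x + rng.normal(size=10)
            pt = pearson_p(pearson_r(x, y), 10)
            pp = permutation_p(x, y, n_permutations=20_000, seed=rng)
            assert abs(pt - pp) < 0.02


def two_matrices(x_rows, y_rows, n_case=3):
    n = len(x_rows[0])
    samples = [f"s{i}" for i in range(n)]
    cond = {s: ("case" if i < n_case else "control") for i, s in enumerate(samples)}
    mx = ExpressionMatrix(
        pd.DataFrame(x_rows, index=[f"L{i}" for i in range(len(x_rows))], columns=samples),
        cond,
    )
    my = ExpressionMatrix(
        pd.DataFrame(y_rows, index=[f"M{i}" for i in range(len(y_rows))], columns=samples),
        cond,
    )
    return mx, my


class TestScreenPairs:
    def test_joint_threshold_rule(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 10, size=8)
        x_rows = [base, base]
        y_rows = [base + rng.normal(0, 0.1, 8), rng.uniform(1, 10, size=8)]
        mx, my = two_matrices(x_rows, y_rows)
        pairs = [CisPair("L0", "M0", "chr1", 0), CisPair("L1", "M1", "chr1", 0)]
        out = screen_pairs(pairs, mx, my)
        assert out[0].significant and out[0].sign == "positive"
        assert not out[1].significant

    def test_negative_correlation_passes_absolute_screen(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        mx, my = two_matrices([x], [100 - x + np.random.default_rng(0).normal(0, 0.1, 8)])
        (p,) = screen_pairs([CisPair("L0", "M0", "chr1", 0)], mx, my)
        assert p.significant and p.sign == "negative" and p.r < -0.9

    def test_zero_variance_member_excluded_not_significant(self):
        mx, my = two_matrices([[5.0] * 8], [list(range(8))])
        (p,) = screen_pairs([CisPair("L0", "M0", "chr1", 0)], mx, my)
        assert p.r is None and p.p_value is None and not p.significant
        assert p.sign == "undefined"

    def test_sample_mismatch_rejected(self):
        mx, my = two_matrices([[1, 2, 3, 4.0]], [[1, 2, 3, 4.0]])
        my.values.columns = ["a", "b", "c", "d"]
        my.condition = {c: "case" for c in "abcd"}
        with pytest.raises(ValueError, match="aligned"):
            screen_pairs([CisPair("L0", "M0", "chr1", 0)], mx, my)

    def test_significant_set_monotone_in_thresholds(self, default_dataset):
        from cislink.diffexpr import counts_to_tpm
        from cislink.cis_pairing import find_cis_pairs

        ds = default_dataset
        tpm = counts_to_tpm(ds.counts, {f.feature_id: f.length_nt for f in ds.features})
        lnc = ds.features.with_biotype("lncRNA")
        mrna = ds.features.with_biotype("mRNA")
        pairs = find_cis_pairs(lnc, mrna)
        counts_r = []
        for min_r in (0.5, 0.8, 0.9, 0.99):
            out = screen_pairs(pairs, tpm, tpm, CorrelationConfig(min_abs_r=min_r))
            counts_r.append(sum(p.significant for p in out))
        assert counts_r == sorted(counts_r, reverse=True)
        counts_a = []
        for alpha in (0.1, 0.05, 0.01):
            out = screen_pairs(pairs, tpm, tpm, CorrelationConfig(alpha=alpha))
            counts_a.append(sum(p.significant for p in out))
        assert counts_a == sorted(counts_a, reverse=True)

    def test_raw_p_used_by_default_bh_only_on_request(self):
        # many null pairs plus one borderline signal: BH adjustment can only
        # shrink the significant set; default must not apply it
        rng = np.random.default_rng(3)
        n = 12
        x_rows = list(rng.uniform(1, 10, size=(30, n)))
        y_rows = list(rng.uniform(1, 10, size=(30, n)))
        base = rng.uniform(1, 10, size=n)
        x_rows.append(base)
        y_rows.append(base + 5 + rng.normal(0, 0.9, n))
        mx, my = two_matrices(x_rows, y_rows, n_case=6)
        pairs = [CisPair(f"L{i}", f"M{i}", "chr1", 0) for i in range(31)]
        raw = screen_pairs(pairs, mx, my, CorrelationConfig(min_abs_r=0.5))
        adj = screen_pairs(pairs, mx, my, CorrelationConfig(min_abs_r=0.5, fdr_correct=True))
        raw_sig = {p.key for p in raw if p.significant}
        adj_sig = {p.key for p in adj if p.significant}
        assert adj_sig <= raw_sig
        # reported p_value stays the raw one in both modes
        assert [p.p_value for p in raw] == [p.p_value for p in adj]
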
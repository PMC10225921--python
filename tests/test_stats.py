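"""Statistical layer: closed-form oracles, calibration, and cross-checks."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from dyadlink import (
    DegenerateInputError,
    StatsConfig,
    correlation,
    fdr_adjust,
    kruskal_wallis,
    mediate,
    paired_t,
    partial_correlation,
    rank_sum,
    steiger_z,
    univariate_f_regression,
    wilcoxon_paired,
)


def bh_oracle(p):
    """Direct step-up computation of Benjamini-Hochberg adjusted values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestFRegression:
    def test_flat_response(self):
        r = univariate_f_regression([1, 2, 3], [5, 5, 5])
        assert r.estimate == 0.0 and r.stat == 0.0 and r.p == pytest.approx(1.0)

    def test_perfect_fit(self):
        x = np.arange(10.0)
        r = univariate_f_regression(x, x)
        assert r.p <= 1e-300

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateInputError):
            univariate_f_regression([2, 2, 2, 2], [1, 2, 3, 4])

    def test_f_equals_t_squared_by_matrix_formulas(self, rng):
        n = 30
        x, y = rng.normal(size=n), rng.normal(size=n)
        r = univariate_f_regression(x, y)
        # explicit OLS via the normal equations, independent of the implementation
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 2)
        se = math.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        assert r.estimate == pytest.approx(beta[1])
        assert r.stat == pytest.approx(t**2)
        assert r.p == pytest.approx(2 * sps.t.sf(abs(t), n - 2), rel=1e-9)

    def test_null_pvalues_uniform(self, rng):
        pvals = []
        x = rng.normal(size=40)
        for _ in range(500):
            pvals.append(univariate_f_regression(x, rng.normal(size=40)).p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestFdr:
    def test_known_example(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.5]) == pytest.approx([0.04, 0.04, 0.04, 0.5])

    def test_single_p_identity(self):
        assert fdr_adjust([0.5]) == pytest.approx([0.5])

    def test_never_decreases(self, rng):
        p = rng.random(50)
        assert (fdr_adjust(p) >= p).all()

    def test_matches_stepup_oracle(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            assert fdr_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_order_invariance(self, rng):
        p = rng.random(20)
        perm = rng.permutation(20)
        assert fdr_adjust(p)[perm] == pytest.approx(fdr_adjust(p[perm]))

    def test_domain_check(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestCorrelation:
    def test_identity(self, rng):
        x = rng.normal(size=20)
        assert correlation(x, x).estimate == pytest.approx(1.0)

    def test_reversed_ranks(self):
        x = np.arange(10.0)
        r = correlation(x, x[::-1], method="spearman")
        assert r.estimate == pytest.approx(-1.0)

    def test_monte_carlo_consistency(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = 0.5 * x + math.sqrt(1 - 0.25) * rng.normal(size=n)
        assert abs(correlation(x, y).estimate - 0.5) < 0.03

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateInputError):
            correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestPartialCorrelation:
    def test_orthogonal_covariate_equals_plain(self):
        # z orthogonal to both x and y by construction
        x = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        y = np.array([1.5, -1.5, 2.1, -2.1, 0.3, -0.3])
        z = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])
        assert abs(z @ x) < 1e-12 and abs(z @ y) < 1e-12 and abs(z.sum()) < 1e-12
        plain = correlation(x, y).estimate
        part = partial_correlation(x, y, z).estimate
        assert part == pytest.approx(plain)

    def test_y_equal_to_z_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        z = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        with pytest.raises(DegenerateInputError):
            partial_correlation(x, z, z)

    def test_matches_recursive_formula(self, rng):
        for _ in range(20):
            n = 200
            z = rng.normal(size=n)
            x = 0.5 * z + rng.normal(size=n)
            y = -0.3 * z + rng.normal(size=n)
            r_xy = np.corrcoef(x, y)[0, 1]
            r_xz = np.corrcoef(x, z)[0, 1]
            r_yz = np.corrcoef(y, z)[0, 1]
            expected = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
            assert partial_correlation(x, y, z).estimate == pytest.approx(expected)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        n = 60
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x", "y", "z"])
        ours = partial_correlation(df.x, df.y, df.z)
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        assert ours.estimate == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)


class TestPairedTests:
    def test_zero_mean_difference(self):
        r = paired_t([2, 2, 0], [1, 1, 2])
        assert r.stat == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_constant_shift_tiny_p(self, rng):
        x = rng.normal(size=20)
        assert paired_t(x + 1.0 + 1e-9 * rng.normal(size=20), x).p < 1e-12

    def test_all_zero_differences_rejected(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_exact_signed_rank_five_equal_pairs(self):
        r = wilcoxon_paired([2, 2, 2, 2, 2], [1, 1, 1, 1, 1])
        assert r.p == pytest.approx(2 / 32)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            d = rng.normal(size=12)
            x = rng.normal(size=12)
            ours = wilcoxon_paired(x + d, x)
            ref = sps.wilcoxon(x + d, x, method="exact")
            assert ours.p == pytest.approx(ref.pvalue)

    def test_normal_branch_matches_scipy(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        ours = wilcoxon_paired(x, y)
        ref = sps.wilcoxon(x, y, method="approx", correction=False)
        assert ours.p == pytest.approx(ref.pvalue)
        assert ours.method == "wilcoxon_signed_rank_normal"

    def test_rank_sum_effect_size(self, rng):
        x = rng.normal(size=30) + 1.0
        y = rng.normal(size=30)
        r = rank_sum(x, y)
        assert r.p < 0.01
        assert 0 <= r.effect_size <= 1


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        r = steiger_z(0.4, 0.4, 0.3, 30)
        assert r.stat == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_sign_symmetry(self):
        a = steiger_z(0.6, 0.3, 0.5, 28)
        b = steiger_z(0.3, 0.6, 0.5, 28)
        assert a.stat == pytest.approx(-b.stat)

    def test_matches_independent_transcription(self):
        # independent spelling-out of the dependent-correlation Z with the
        # back-transformed average correlation
        r_jk, r_jh, r_kh, n = 0.6, 0.3, 0.5, 28
        z1 = 0.5 * math.log((1 + r_jk) / (1 - r_jk))
        z2 = 0.5 * math.log((1 + r_jh) / (1 - r_jh))
        rbar = math.tanh((z1 + z2) / 2)
        cov = (
            r_kh * (1 - rbar**2 - rbar**2)
            - 0.5 * rbar**2 * (1 - rbar**2 - rbar**2 - r_kh**2)
        ) / (1 - rbar**2) ** 2
        expected = (z1 - z2) * math.sqrt((n - 3) / (2 * (1 - cov)))
        r = steiger_z(r_jk, r_jh, r_kh, n)
        assert r.stat == pytest.approx(expected)
        assert r.p == pytest.approx(2 * sps.norm.sf(abs(expected)))

    def test_domain_check(self):
        with pytest.raises(ValueError):
            steiger_z(1.0, 0.3, 0.2, 30)


def kw_oracle(samples):
    """Brute-force Kruskal-Wallis H with tie correction from the rank formula."""
    values = np.concatenate(samples)
    ranks = sps.rankdata(values)
    n = values.size
    start = 0
    h = 0.0
    for s in samples:
        r = ranks[start:start + s.size]
        start += s.size
        h += r.sum() ** 2 / s.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_two_groups_match_rank_formula(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        groups = np.array(["a", "a", "b", "b"])
        r = kruskal_wallis(values, groups)
        assert r.stat == pytest.approx(kw_oracle([values[:2], values[2:]]))

    def test_label_permutation_invariance(self, rng):
        v = rng.normal(size=20)
        g = np.array(["a"] * 10 + ["b"] * 10)
        swapped = np.where(g == "a", "b", "a")
        assert kruskal_wallis(v, g).stat == pytest.approx(kruskal_wallis(v, swapped).stat)

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        sims = 1000
        for _ in range(sims):
            v = rng.normal(size=24)
            g = np.array(["a"] * 12 + ["b"] * 12)
            if kruskal_wallis(v, g).p < 0.05:
                hits += 1
        assert 0.03 <= hits / sims <= 0.07


class TestMediation:
    def cfg(self, seed=0):
        return StatsConfig(seed=seed)

    def test_indirect_is_product_of_ols_paths(self, rng):
        x = rng.normal(size=80)
        m = 0.5 * x + rng.normal(size=80)
        y = 0.7 * m + rng.normal(size=80)
        r = mediate(x, m, y, self.cfg())
        X1 = np.column_stack([np.ones(80), x])
        a = np.linalg.lstsq(X1, m, rcond=None)[0][1]
        X2 = np.column_stack([np.ones(80), x, m])
        b = np.linalg.lstsq(X2, y, rcond=None)[0][2]
        assert r.indirect == pytest.approx(a * b)
        assert r.ci_low <= r.indirect <= r.ci_high

    def test_bit_reproducible(self, rng):
        x = rng.normal(size=50)
        m = 0.5 * x + rng.normal(size=50)
        y = m + rng.normal(size=50)
        a = mediate(x, m, y, self.cfg(seed=9))
        b = mediate(x, m, y, self.cfg(seed=9))
        assert a.to_dict() == b.to_dict()

    def test_near_deterministic_chain(self, rng):
        x = rng.normal(size=100)
        m = x + 1e-3 * rng.normal(size=100)
        y = m + 1e-6 * rng.normal(size=100)
        r = mediate(x, m, y, self.cfg())
        assert r.indirect == pytest.approx(1.0, abs=1e-3)
        assert (r.ci_high - r.ci_low) < 1e-3

    def test_collinear_mediator_rejected(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(DegenerateInputError):
            mediate(x, 2 * x, x + rng.normal(size=50), self.cfg())

    def test_matches_statsmodels_parametric_mediation(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.stats.mediation import Mediation

        n = 300
        x = rng.normal(size=n)
        m = 0.8 * x + rng.normal(size=n)
        y = 0.8 * m + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        ref = Mediation(
            sm.OLS.from_formula("y ~ x + m", df),
            sm.OLS.from_formula("m ~ x", df),
            "x", "m",
        ).fit(method="parametric", n_rep=1000)
        acme = float(ref.summary().loc["ACME (average)", "Estimate"])
        ours = mediate(x, m, y, self.cfg())
        assert ours.indirect == pytest.approx(acme, abs=0.1)
        assert ours.significant


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_fdr_output_in_unit_interval_and_above_input(p):
    q = fdr_adjust(p)
    assert ((q >= np.asarray(p) - 1e-15) & (q <= 1.0)).all()
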
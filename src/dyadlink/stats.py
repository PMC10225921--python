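"""Statistical layer: mass-univariate F-regression with FDR control,
plain/partial/dependent correlations, paired tests, Kruskal-Wallis, and
quasi-Bayesian causal mediation.

All p-values are two-sided.  The mediation routine fits the mediator and
outcome models by ordinary least squares, draws coefficient vectors from
each fit's asymptotic normal distribution, and summarises the simulated
product-of-coefficients distribution by percentile confidence interval and
a sign-share p-value.  A mediation is flagged significant when the indirect
effect's interval excludes zero, the total effect is significant, and the
direct effect is not once the mediator is controlled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, SpecError


@dataclass
class StatResult:
    """One test's outcome: estimate, statistic, p, optional q/CI/effect size."""

    name: str
    method: str
    estimate: float
    stat: float
    n: int
    p: float
    df: float | None = None
    q: float | None = None
    ci_low: float = math.nan
    ci_high: float = math.nan
    effect_size: float | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "method": self.method,
            "estimate": self.estimate,
            "stat": self.stat,
            "n": self.n,
            "p": self.p,
            "df": self.df,
            "q": self.q,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "effect_size": self.effect_size,
        }


@dataclass
class MediationResult:
    """Path coefficients and the quasi-Bayesian indirect-effect summary."""

    exposure: str
    mediator: str
    outcome: str
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float          # point estimate, exactly a*b from the OLS fits
    ci_low: float
    ci_high: float
    p_indirect: float
    p_total: float           # p of c in y ~ x
    p_direct: float          # p of c' in y ~ x + m
    iterations: int
    alpha: float
    significant: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class StatsConfig:
    alpha: float = 0.05
    fdr_method: str = "fdr_bh"
    mediation_iterations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise SpecError(f"alpha must be in (0,1), got {self.alpha}")
        if self.mediation_iterations < 100:
            raise SpecError("mediation needs >= 100 iterations")


def _as1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if np.isnan(a).any():
        raise ValueError("input contains NaN")
    return a


def univariate_f_regression(x, y, name: str = "", alpha: float = 0.05) -> StatResult:
    """OLS of y on x with intercept, F-test for the single slope.

    F = (regression SS / 1) / (residual SS / (n-2)), referred to F(1, n-2);
    equals the square of the slope's t statistic.  The CI is on the slope.
    """
    x, y = _as1d(x), _as1d(y)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("x and y must share length n >= 3")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise DegenerateInputError("constant predictor in F-regression")
    sxy = float(xc @ (y - y.mean()))
    slope = sxy / sxx
    ss_reg = sxy * sxy / sxx
    ss_res = float(((y - y.mean()) ** 2).sum()) - ss_reg
    ss_res = max(ss_res, 0.0)
    dfe = n - 2
    if ss_reg == 0.0 and ss_res <= 1e-300:
        F, p, se = 0.0, 1.0, 0.0
    elif ss_res <= 1e-300:
        F, p, se = math.inf, 0.0, 0.0
    else:
        F = ss_reg / (ss_res / dfe)
        p = float(sps.f.sf(F, 1, dfe))
        se = math.sqrt(ss_res / dfe / sxx)
    tcrit = float(sps.t.ppf(1 - alpha / 2, dfe))
    return StatResult(
        name=name, method="f_regression", estimate=slope, stat=F, n=n, p=p,
        df=dfe, ci_low=slope - tcrit * se, ci_high=slope + tcrit * se,
    )


def fdr_adjust(p, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = _as1d(p)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def correlation(x, y, method: str = "pearson", name: str = "", alpha: float = 0.05) -> StatResult:
    """Pearson's r or Spearman's rho with a two-sided p and Fisher-z CI."""
    x, y = _as1d(x), _as1d(y)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("x and y must share length n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero-variance input to correlation")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    r, p = float(r), float(p)
    lo = hi = math.nan
    if n > 3 and abs(r) < 1:
        z = math.atanh(r)
        zse = 1.0 / math.sqrt(n - 3)
        zcrit = float(sps.norm.ppf(1 - alpha / 2))
        lo, hi = math.tanh(z - zcrit * zse), math.tanh(z + zcrit * zse)
    return StatResult(
        name=name, method=method, estimate=r, stat=r, n=n, p=p,
        ci_low=lo, ci_high=hi,
    )


def partial_correlation(x, y, z, method: str = "pearson", name: str = "", alpha: float = 0.05) -> StatResult:
    """Correlation of x and y after removing one covariate z from both.

    For Spearman all three variables are midranked first.  The residual
    correlation is tested on n-3 degrees of freedom.
    """
    x, y, z = _as1d(x), _as1d(y), _as1d(z)
    n = x.size
    if not (n == y.size == z.size) or n < 4:
        raise ValueError("x, y, z must share length n >= 4")
    if np.std(z) == 0:
        raise DegenerateInputError("constant covariate in partial correlation")
    if method == "spearman":
        x, y, z = sps.rankdata(x), sps.rankdata(y), sps.rankdata(z)
    elif method != "pearson":
        raise ValueError(f"unknown partial correlation method {method!r}")
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.std(rx) < 1e-12 or np.std(ry) < 1e-12:
        raise DegenerateInputError("a variable is collinear with the covariate")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dfe = n - 3
    r = max(min(r, 1.0), -1.0)
    if abs(r) >= 1.0:
        t, p = math.inf, 0.0
    else:
        t = r * math.sqrt(dfe / (1 - r * r))
        p = 2 * float(sps.t.sf(abs(t), dfe))
    lo = hi = math.nan
    if dfe > 1 and abs(r) < 1:
        zse = 1.0 / math.sqrt(n - 4) if n > 4 else math.nan
        zcrit = float(sps.norm.ppf(1 - alpha / 2))
        if not math.isnan(zse):
            zr = math.atanh(r)
            lo, hi = math.tanh(zr - zcrit * zse), math.tanh(zr + zcrit * zse)
    return StatResult(
        name=name, method=f"partial_{method}", estimate=r, stat=t, n=n, p=p,
        df=dfe, ci_low=lo, ci_high=hi,
    )


def paired_t(x, y, name: str = "", alpha: float = 0.05) -> StatResult:
    """Paired t-test on the within-pair differences."""
    x, y = _as1d(x), _as1d(y)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must share length n >= 3")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            raise DegenerateInputError("all paired differences are zero")
        t, p, se = math.copysign(math.inf, d.mean()), 0.0, 0.0
    else:
        t, p = sps.ttest_rel(x, y)
        t, p = float(t), float(p)
        se = sd / math.sqrt(n)
    tcrit = float(sps.t.ppf(1 - alpha / 2, n - 1))
    md = float(d.mean())
    return StatResult(
        name=name, method="paired_t", estimate=md, stat=t, n=n, p=p, df=n - 1,
        ci_low=md - tcrit * se, ci_high=md + tcrit * se,
        effect_size=md / sd if sd > 0 else math.nan,
    )


def _signed_rank_exact_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p with midranks, by DP over rank sums.

    Midranks of |d| are doubled to integers; the null distribution of the
    positive-rank sum is built by dynamic programming over all 2^n sign
    patterns without enumerating them.
    """
    ranks = sps.rankdata(np.abs(d))
    units = np.rint(2 * ranks).astype(int)  # doubled midranks are integral
    w_plus = int(units[d > 0].sum())
    total = int(units.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for u in units:
        shifted = np.zeros_like(dist)
        shifted[u:] = dist[: total + 1 - u]
        dist = 0.5 * (dist + shifted)
    cdf = float(dist[: w_plus + 1].sum())
    sf = float(dist[w_plus:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_paired(x, y, name: str = "", exact_max_n: int = 25) -> StatResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  Up to ``exact_max_n`` non-zero pairs the
    exact null distribution (tie-aware, via midranks) is enumerated; above
    that a tie-corrected normal approximation is used.  The effect size is
    r = |Z| / sqrt(n) with n the number of original pairs.
    """
    x, y = _as1d(x), _as1d(y)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must share length n >= 3")
    n_pairs = x.size
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    m = d.size
    mu = m * (m + 1) / 4.0
    # tie correction on the variance of W+
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = m * (m + 1) * (2 * m + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = 0.0 if var == 0 else (w_plus - mu) / math.sqrt(var)
    if m <= exact_max_n:
        p = _signed_rank_exact_p(d)
        method = "wilcoxon_signed_rank_exact"
    else:
        p = 2 * float(sps.norm.sf(abs(z)))
        method = "wilcoxon_signed_rank_normal"
    return StatResult(
        name=name, method=method, estimate=w_plus, stat=z, n=n_pairs, p=min(p, 1.0),
        effect_size=abs(z) / math.sqrt(n_pairs),
    )


def rank_sum(x, y, name: str = "") -> StatResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test."""
    x, y = _as1d(x), _as1d(y)
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    n1, n2 = x.size, y.size
    mu = n1 * n2 / 2.0
    ranks = sps.rankdata(np.concatenate([x, y]))
    _, tie_counts = np.unique(ranks, return_counts=True)
    nn = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (nn * (nn - 1))
    var = n1 * n2 / 12.0 * (nn + 1 - tie_term)
    z = 0.0 if var == 0 else (float(u) - mu) / math.sqrt(var)
    return StatResult(
        name=name, method="rank_sum", estimate=float(u), stat=z, n=nn, p=float(p),
        effect_size=abs(z) / math.sqrt(nn),
    )


def steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int, name: str = "") -> StatResult:
    """Difference between two dependent correlations sharing variable j.

    Fisher-transforms r_jk and r_jh and scales their difference by the
    covariance of dependent correlations, evaluated at the back-transformed
    average correlation.  Two-sided p from the standard normal.
    """
    for r in (r_jk, r_jh, r_kh):
        if not -1 < r < 1:
            raise ValueError(f"correlation {r} outside (-1, 1) (Fisher transform domain)")
    if n < 4:
        raise ValueError("need n >= 4")
    z1, z2 = math.atanh(r_jk), math.atanh(r_jh)
    rm = math.tanh((z1 + z2) / 2.0)
    rm2 = rm * rm
    num = r_kh * (1 - 2 * rm2) - 0.5 * rm2 * (1 - 2 * rm2 - r_kh * r_kh)
    s = num / ((1 - rm2) ** 2)
    if s >= 1:
        raise ValueError("infeasible correlation triple (matrix not positive definite)")
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 - 2.0 * s))
    p = 2 * float(sps.norm.sf(abs(z)))
    return StatResult(
        name=name, method="steiger_z", estimate=r_jk - r_jh, stat=z, n=n, p=p,
    )


def kruskal_wallis(values, groups, name: str = "") -> StatResult:
    """Kruskal-Wallis one-way ANOVA on ranks across >= 2 groups."""
    values = _as1d(values)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("values and groups must share length")
    labels = sorted(set(groups.tolist()), key=str)
    if len(labels) < 2:
        raise DegenerateInputError("Kruskal-Wallis needs at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(s.size == 0 for s in samples):
        raise DegenerateInputError("every group must be non-empty")
    h, p = sps.kruskal(*samples)
    return StatResult(
        name=name, method="kruskal_wallis", estimate=float(h), stat=float(h),
        n=values.size, p=float(p), df=len(labels) - 1,
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least squares fit: coefficients, covariance matrix, residuals."""
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise DegenerateInputError("collinear design in mediation fit")
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return coef, cov, resid


def _coef_p(coef: float, se: float, dfe: int) -> float:
    if se == 0:
        return 0.0 if coef != 0 else 1.0
    return 2 * float(sps.t.sf(abs(coef) / se, dfe))


def mediate(x, m, y, cfg: StatsConfig | None = None,
            exposure: str = "x", mediator: str = "m", outcome: str = "y") -> MediationResult:
    """Quasi-Bayesian mediation of the x → m → y path.

    Fits m ~ x (path a) and y ~ x + m (paths c', b) by OLS, then simulates
    ``cfg.mediation_iterations`` coefficient vectors from each fit's
    asymptotic normal distribution; each draw contributes a_i * b_i to the
    indirect-effect distribution.  The CI is the alpha/2 .. 1-alpha/2
    percentile band; p is twice the smaller sign share (draws at exactly 0
    count in both shares).  ``significant`` additionally requires the total
    effect c (from y ~ x) to be significant and the direct effect c' not.
    """
    cfg = cfg or StatsConfig()
    x, m, y = _as1d(x), _as1d(m), _as1d(y)
    n = x.size
    if not (n == m.size == y.size) or n < 10:
        raise ValueError("x, m, y must share length n >= 10")
    if np.std(x) == 0:
        raise DegenerateInputError("constant exposure")
    if abs(np.corrcoef(x, m)[0, 1]) > 1 - 1e-12:
        raise DegenerateInputError("mediator collinear with exposure")
    ones = np.ones(n)
    X1 = np.column_stack([ones, x])           # m ~ 1 + x
    X2 = np.column_stack([ones, x, m])        # y ~ 1 + x + m
    coef1, cov1, _ = _ols(X1, m)
    coef2, cov2, _ = _ols(X2, y)
    coef3, cov3, _ = _ols(X1, y)              # y ~ 1 + x (total effect)
    a, b, c_prime, c = coef1[1], coef2[2], coef2[1], coef3[1]
    p_total = _coef_p(c, math.sqrt(max(cov3[1, 1], 0.0)), n - 2)
    p_direct = _coef_p(c_prime, math.sqrt(max(cov2[1, 1], 0.0)), n - 3)

    rng = np.random.default_rng(cfg.seed)
    iters = cfg.mediation_iterations
    draws1 = rng.multivariate_normal(coef1, cov1, size=iters, method="eigh")
    draws2 = rng.multivariate_normal(coef2, cov2, size=iters, method="eigh")
    indirect_draws = draws1[:, 1] * draws2[:, 2]
    lo, hi = np.percentile(indirect_draws, [100 * cfg.alpha / 2, 100 * (1 - cfg.alpha / 2)])
    share_le = float(np.mean(indirect_draws <= 0))
    share_ge = float(np.mean(indirect_draws >= 0))
    p_ind = min(1.0, 2.0 * min(share_le, share_ge))
    ci_excludes_zero = lo > 0 or hi < 0
    significant = bool(
        ci_excludes_zero and p_total < cfg.alpha and p_direct >= cfg.alpha
    )
    return MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        a=float(a), b=float(b), c=float(c), c_prime=float(c_prime),
        indirect=float(a * b), ci_low=float(lo), ci_high=float(hi),
        p_indirect=p_ind, p_total=p_total, p_direct=p_direct,
        iterations=iters, alpha=cfg.alpha, significant=significant,
    )
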
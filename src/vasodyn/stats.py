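"""Statistical machinery used throughout the pipeline.

Two-sample t tests, p-values from printed t/χ²/F statistics, the
Cochran–Armitage chi-square test for trend across ordered distance bins,
rank tests, Bonferroni correction, and display-only Gaussian fits to
binned distance distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "TestResult",
    "p_from_statistic",
    "two_sample_t",
    "chi2_trend",
    "rank_compare",
    "bonferroni",
    "gaussian_fit",
    "GaussianFit",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``p`` is two-tailed unless the method label says otherwise; ``df`` is a
    float or an ``(df1, df2)`` pair for F statistics; ``n`` holds the group
    sizes that entered the test.
    """

    statistic: float
    df: float | tuple[float, float]
    p: float
    method: str
    n: tuple[int, ...] = field(default=())
    note: str = ""


def p_from_statistic(value: float, family: str, df) -> float:
    """p-value for a printed test statistic.

    ``family='t'`` gives the two-tailed tail probability; ``'chi2'`` and
    ``'F'`` give the upper-tail probability.  ``df`` is a scalar for t and
    chi2 and an ``(df1, df2)`` pair for F.
    """
    if family == "t":
        if df <= 0:
            raise ValueError(f"t distribution needs df > 0, got {df}")
        return float(2.0 * sps.t.sf(abs(value), df))
    if family == "chi2":
        if df <= 0:
            raise ValueError(f"chi2 distribution needs df > 0, got {df}")
        return float(sps.chi2.sf(value, df))
    if family == "F":
        df1, df2 = df
        if df1 <= 0 or df2 <= 0:
            raise ValueError(f"F distribution needs positive df, got {df}")
        return float(sps.f.sf(value, df1, df2))
    raise ValueError(f"unknown family {family!r}; expected 't', 'chi2' or 'F'")


def two_sample_t(x, y, pooled: bool = True) -> TestResult:
    """Unpaired two-sample t test, pooled-variance Student by default.

    ``pooled=False`` switches to Welch's unequal-variance form.  With zero
    pooled variance and unequal means the statistic is infinite and the
    result is flagged in ``note``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    nx, ny = x.size, y.size
    if pooled:
        df = nx + ny - 2
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
        denom = math.sqrt(sp2 * (1 / nx + 1 / ny))
        method = "Student t (pooled, two-tailed)"
    else:
        vx, vy = x.var(ddof=1) / nx, y.var(ddof=1) / ny
        denom = math.sqrt(vx + vy)
        if vx + vy > 0:
            df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
        else:
            df = nx + ny - 2
        method = "Welch t (two-tailed)"
    delta = x.mean() - y.mean()
    if denom == 0.0:
        if delta == 0.0:
            return TestResult(0.0, df, 1.0, method, (nx, ny))
        t = math.copysign(math.inf, delta)
        return TestResult(t, df, 0.0, method, (nx, ny), note="zero variance, unequal means")
    t = delta / denom
    return TestResult(float(t), float(df), p_from_statistic(t, "t", df), method, (nx, ny))


def chi2_trend(counts, scores=None) -> TestResult:
    """Cochran–Armitage chi-square test for trend over K ordered bins.

    ``counts`` is a (K, 2) table: per-bin counts for the two classes in bin
    order.  ``scores`` default to 1..K (equivalent to equally spaced bin
    midpoints; the statistic is invariant to affine rescaling of scores).
    df = 1, p two-tailed (upper tail of χ²₁).
    """
    tab = np.asarray(counts, dtype=float)
    if tab.ndim != 2 or tab.shape[1] != 2 or tab.shape[0] < 2:
        raise ValueError("counts must be a (K>=2, 2) table")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    col = tab.sum(axis=0)
    if np.any(col == 0):
        raise ValueError("each class needs a nonzero total")
    if scores is None:
        scores = np.arange(1, tab.shape[0] + 1, dtype=float)
    s = np.asarray(scores, dtype=float)
    n_k = tab.sum(axis=1)
    big_n = n_k.sum()
    a_k = tab[:, 0]
    big_a = a_k.sum()
    pbar = big_a / big_n
    t_num = float(np.sum(s * (a_k - n_k * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n_k * s**2) - np.sum(n_k * s) ** 2 / big_n)
    if var <= 0:
        # all weight in a single bin: no trend is testable
        return TestResult(0.0, 1.0, 1.0, "Cochran-Armitage trend", tuple(int(c) for c in col))
    stat = t_num**2 / var
    return TestResult(
        float(stat),
        1.0,
        p_from_statistic(stat, "chi2", 1),
        "Cochran-Armitage trend",
        tuple(int(c) for c in col),
    )


def rank_compare(x, y, paired: bool = False) -> TestResult:
    """Rank test: Mann–Whitney U (unpaired) or Wilcoxon signed-rank (paired).

    Exact p for small samples (min n ≤ 8 unpaired without ties; n ≤ 15
    paired), tie-corrected normal approximation otherwise; two-tailed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            raise ValueError("all paired differences are zero")
        mode = "exact" if x.size <= 15 and not _has_zero_or_ties(d) else "approx"
        res = sps.wilcoxon(x, y, alternative="two-sided",
                           method="exact" if mode == "exact" else "asymptotic")
        return TestResult(float(res.statistic), float(x.size), float(res.pvalue),
                          f"Wilcoxon signed-rank ({mode})", (int(x.size),))
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = min(x.size, y.size) <= 8 and not ties
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return TestResult(float(res.statistic), float(x.size + y.size - 2), float(res.pvalue),
                      f"Mann-Whitney U ({'exact' if exact else 'normal approx'})",
                      (int(x.size), int(y.size)))


def _has_zero_or_ties(d: np.ndarray) -> bool:
    if np.any(d == 0):
        return True
    return np.unique(np.abs(d)).size < d.size


def bonferroni(p_values, m: int | None = None):
    """Bonferroni-adjust a list of p-values: min(1, m·p) each."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


@dataclass(frozen=True)
class GaussianFit:
    """Display-only Gaussian fit to a binned distribution."""

    mean: float
    sd: float
    amplitude: float
    normalized_counts: np.ndarray
    display_only: bool = True


def gaussian_fit(bin_centers, counts) -> GaussianFit:
    """Least-squares Gaussian fit plus counts normalized to the raw maximum.

    Used solely for graphical display of distance distributions; inference
    runs on the raw bins (``chi2_trend``).
    """
    x = np.asarray(bin_centers, dtype=float)
    c = np.asarray(counts, dtype=float)
    nonzero = np.count_nonzero(c)
    if nonzero < 3:
        raise ValueError("need at least 3 nonzero bins for a Gaussian fit")
    cmax = c.max()
    mu0 = float(np.sum(x * c) / c.sum())
    sd0 = float(math.sqrt(max(np.sum(c * (x - mu0) ** 2) / c.sum(), 1e-6)))

    def model(xv, amp, mu, sd):
        return amp * np.exp(-0.5 * ((xv - mu) / sd) ** 2)

    popt, _ = optimize.curve_fit(model, x, c, p0=(cmax, mu0, sd0), maxfev=10000)
    amp, mu, sd = popt
    return GaussianFit(float(mu), float(abs(sd)), float(amp), c / cmax)
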
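"""Method-agreement statistics for simplified-protocol validation.

Agreement of an extrapolated protocol with the per-cycle reference is
quantified by Bland–Altman limits of agreement on paired differences,
``mu +/- z * sigma`` with the Gaussian quantile ``z = z_{1-alpha/2}``
(1.96 at alpha = 0.05) and sample standard deviation (n-1 denominator),
the 95% CI of the mean difference ``mu +/- z * sigma / sqrt(n)``, the
percentage of subjects outside the limits ("out-of-bound"), per-patient
percent differences, and the Wilcoxon signed-rank test.  Cohort-level
association analyses (Fisher's exact test on the liver-burden / kidney-dose
table, covariate-adjusted linear regression, paired cycle I-vs-IV TIAC
trends) live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AgreementResult",
    "TrendResult",
    "bland_altman",
    "out_of_bound_fraction",
    "wilcoxon_signed_rank",
    "percent_difference",
    "summarize_percent_differences",
    "fisher_exact_2x2",
    "adjusted_linear_association",
    "tiac_trend_test",
]


@dataclass
class AgreementResult:
    """Bland–Altman / Wilcoxon summary for one region and method pair."""

    region: str
    pair: str
    n: int
    mu_delta: float
    sigma_delta: float
    z: float
    loa_low: float
    loa_high: float
    ci_low: float
    ci_high: float
    pct_out_of_bounds: float
    wilcoxon_p: float | None = None
    mean_pct_diff: float | None = None
    sd_pct_diff: float | None = None

    def __post_init__(self) -> None:
        if not self.loa_low - 1e-12 <= self.mu_delta <= self.loa_high + 1e-12:
            raise ValueError("mean difference must lie within the LOAs")
        if not 0.0 <= self.pct_out_of_bounds <= 100.0:
            raise ValueError("out-of-bound percentage must lie in [0, 100]")


@dataclass(frozen=True)
class TrendResult:
    """Paired cycle I-minus-IV TIAC difference summary."""

    region: str
    n: int
    mean_diff_h: float
    sd_diff_h: float
    p: float


def bland_altman(differences, alpha: float = 0.05, region: str = "",
                 pair: str = "") -> AgreementResult:
    """Limits of agreement and CI of the mean difference.

    ``LOA = mu +/- z*sigma`` and ``CI = mu +/- z*sigma/sqrt(n)`` with the
    standard-normal quantile ``z = z_{1-alpha/2}`` and sigma the sample SD.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("Bland–Altman needs at least 2 paired differences")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    mu = float(d.mean())
    sigma = float(d.std(ddof=1))
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    loa = (mu - z * sigma, mu + z * sigma)
    half = z * sigma / np.sqrt(d.size)
    pct = out_of_bound_fraction(d, loa)
    return AgreementResult(region, pair, int(d.size), mu, sigma, z,
                           loa[0], loa[1], mu - half, mu + half, pct)


def out_of_bound_fraction(differences, loa: tuple[float, float]) -> float:
    """Percent of differences strictly outside the closed LOA interval,
    rounded to one decimal; boundary values count as inside."""
    d = np.asarray(differences, dtype=float)
    lo, hi = loa
    out = int(np.sum((d < lo) | (d > hi)))
    return round(100.0 * out / d.size, 1)


def wilcoxon_signed_rank(paired_a, paired_b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired data.

    Zero differences are dropped (Wilcoxon's original treatment); the null
    distribution is exact up to n = 25 and a continuity-corrected normal
    approximation above.  All-zero differences return p = 1 with a warning.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; no location shift "
                      "is testable (p = 1)", stacklevel=2)
        return 1.0
    if nz.size < 5:
        raise ValueError("need >= 5 non-zero differences for the signed-rank "
                         "test")
    if nz.size <= 25:
        res = stats.wilcoxon(nz, method="exact")
    else:
        res = stats.wilcoxon(nz, method="approx", correction=True)
    return float(res.pvalue)


def percent_difference(mx_gy: float, m0_gy: float) -> float:
    """Relative difference of a simplified-method dose vs the reference, %."""
    if m0_gy <= 0:
        raise ValueError("reference dose must be > 0")
    return 100.0 * (mx_gy - m0_gy) / m0_gy


def summarize_percent_differences(mx, m0) -> tuple[float, float]:
    """Cohort mean and SD of the per-patient percent differences.

    Note this is the mean of per-patient ratios, which differs from the
    percent difference of cohort means when doses are skewed.
    """
    mx = np.asarray(mx, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    pct = np.array([percent_difference(x, r) for x, r in zip(mx, m0)])
    return float(pct.mean()), float(pct.std(ddof=1))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table (sum of
    hypergeometric probabilities at or below the observed table's)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table margins must be positive")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def adjusted_linear_association(y, x, covariates=None) -> tuple[float, float]:
    """OLS slope of ``y`` on ``x`` adjusted for covariates, with its
    two-sided t-test p-value.

    ``covariates`` is a mapping of name -> numeric array (e.g. gender coded
    0/1 and weight in kg).  A rank-deficient design raises ``ValueError``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cols = {"x": x}
    if covariates:
        for name, vals in covariates.items():
            cols[name] = np.asarray(vals, dtype=float)
    design = np.column_stack(list(cols.values()))
    design = sm.add_constant(design, has_constant="add")
    if y.size <= design.shape[1]:
        raise ValueError("need more observations than predictors")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(y, design).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def tiac_trend_test(per_cycle_tiacs, region: str = "") -> TrendResult:
    """Paired cycle I-minus-IV TIAC change across the cohort.

    Reports mean and SD of the per-patient difference (cycle I minus cycle
    IV, the published sign convention: an increasing TIAC gives a negative
    mean) and the Wilcoxon signed-rank p.
    """
    t = np.asarray(per_cycle_tiacs, dtype=float)
    if t.ndim != 2 or t.shape[1] != 4:
        raise ValueError("expect an (n_patients, 4 cycles) array")
    if t.shape[0] < 2:
        raise ValueError("trend test needs at least 2 patients")
    if np.any(np.isnan(t)):
        raise ValueError("missing cycle TIACs")
    diff = t[:, 0] - t[:, 3]
    p = wilcoxon_signed_rank(t[:, 0], t[:, 3])
    return TrendResult(region, int(t.shape[0]), float(diff.mean()),
                       float(diff.std(ddof=1)), p)
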
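"""Group-level equivalence statistics for per-bone mean surface distances.

The question this layer answers: is the mean signed surface distance
between two modalities' bone models within a clinically negligible margin?
Equivalence is assessed with the two one-sided tests (TOST) procedure on
the pooled per-bone means, with margin Δ = 0.15 mm — half the smallest
voxel dimension of the acquisition protocols.  TOST declares equivalence
when both one-sided t tests against −Δ and +Δ reject at level α,
equivalently when the (1 − 2α) two-sided t interval lies inside (−Δ, +Δ).
The interval reported alongside TOST is therefore the 90% interval at
α = 0.05, the standard TOST reporting convention.

Normality of the pooled means is screened with Shapiro–Wilk and a
Kolmogorov–Smirnov test against a normal with the sample's fitted mean and
standard deviation.  The KS p-value uses the standard parameters-known
distribution, which is anti-conservative when parameters are estimated
(no Lilliefors correction is applied); treat it as a descriptive screen.

Conventions: summary tables use the population (÷n) standard deviation and
the μ ± 1.96σ spread interval (see :mod:`bonequiv.summaries`); inferential
statistics here use the sample (÷(n−1)) standard deviation.  Pooling all
bones of a subject into one sample ignores within-subject correlation of
segmentation error; the group-level p-values should be read with that
caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateSampleError
from .summaries import BoneSummary, summarize_values

__all__ = [
    "NormalityResult",
    "EquivalenceResult",
    "aggregate_group",
    "shapiro_wilk",
    "ks_normal",
    "normality_tests",
    "tost_one_sample",
    "power_sample_size",
    "qq_points",
]


@dataclass(frozen=True)
class NormalityResult:
    shapiro_w: float
    shapiro_p: float
    ks_d: float
    ks_p: float
    alpha: float = 0.05

    @property
    def deviates(self) -> bool:
        """True when either test flags deviation from normality at alpha."""
        return min(self.shapiro_p, self.ks_p) < self.alpha

    @property
    def interpretation(self) -> str:
        return "deviation from normality" if self.deviates else "no significant deviation"


@dataclass(frozen=True)
class EquivalenceResult:
    """One-sample TOST against a symmetric margin."""

    n: int
    mean: float
    std: float  # sample std, ddof=1
    se: float
    margin: float
    alpha: float
    p_lower: float  # H0: mean <= -margin
    p_upper: float  # H0: mean >= +margin
    ci_lower: float  # (1 - 2 alpha) two-sided t interval
    ci_upper: float
    equivalent: bool


def aggregate_group(means: np.ndarray, bone: str = "") -> BoneSummary:
    """Summary-table row over per-subject bone means (population σ, μ±1.96σ)."""
    return summarize_values(np.asarray(means, dtype=float), bone=bone)


def _check_sample(x: np.ndarray, min_n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < min_n:
        raise DegenerateSampleError(f"need n >= {min_n}, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("sample is constant")
    return x


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk W and p (Royston's AS R94 algorithm), 3 <= n <= 5000."""
    x = _check_sample(x, 3)
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk supported for n <= 5000")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def ks_normal(x: np.ndarray, mean: float | None = None, std: float | None = None) -> tuple[float, float]:
    """Kolmogorov–Smirnov D and p against a normal reference.

    D is the two-sided sup of |ECDF − Φ((x − μ)/σ)| evaluated just before
    and at each order statistic.  By default μ and σ are estimated from the
    sample (mean and ddof=1 std); pass them explicitly for a
    parameters-known test.  The p-value always uses the standard
    parameters-known KS distribution, which is anti-conservative when the
    parameters were estimated.
    """
    x = _check_sample(x, 2)
    mean = float(x.mean()) if mean is None else float(mean)
    std = float(x.std(ddof=1)) if std is None else float(std)
    res = sps.kstest(x, "norm", args=(mean, std))
    return float(res.statistic), float(res.pvalue)


def normality_tests(x: np.ndarray, alpha: float = 0.05) -> NormalityResult:
    w, pw = shapiro_wilk(x)
    d, pd = ks_normal(x)
    return NormalityResult(shapiro_w=w, shapiro_p=pw, ks_d=d, ks_p=pd, alpha=alpha)


def tost_one_sample(x: np.ndarray, margin: float = 0.15, alpha: float = 0.05) -> EquivalenceResult:
    """Two one-sided t tests of |mean| < margin, plus the (1−2α) t interval."""
    if margin <= 0:
        raise ValueError("margin must be > 0")
    x = _check_sample(x, 3)
    n = x.size
    mean = float(x.mean())
    s = float(x.std(ddof=1))
    se = s / np.sqrt(n)
    df = n - 1
    t_lower = (mean + margin) / se
    t_upper = (mean - margin) / se
    p_lower = float(sps.t.sf(t_lower, df))
    p_upper = float(sps.t.cdf(t_upper, df))
    t_crit = float(sps.t.ppf(1.0 - alpha, df))
    ci_lower = mean - t_crit * se
    ci_upper = mean + t_crit * se
    equivalent = max(p_lower, p_upper) < alpha
    return EquivalenceResult(
        n=n,
        mean=mean,
        std=s,
        se=float(se),
        margin=float(margin),
        alpha=float(alpha),
        p_lower=p_lower,
        p_upper=p_upper,
        ci_lower=float(ci_lower),
        ci_upper=float(ci_upper),
        equivalent=bool(equivalent),
    )


def _t_power(n: int, d: float, alpha: float) -> float:
    """Power of the two-sided one-sample t test at effect size d."""
    df = n - 1
    nc = abs(d) * np.sqrt(n)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))


def power_sample_size(d: float, alpha: float = 0.05, power: float = 0.80, max_n: int = 10**6) -> int:
    """Smallest n with two-sided one-sample t-test power >= target.

    Power is computed from the noncentral t distribution with
    noncentrality d·√n.
    """
    if d == 0:
        raise ValueError("effect size must be nonzero")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    for n in range(2, max_n + 1):
        if _t_power(n, d, alpha) >= power:
            return n
    raise ValueError(f"power {power} not reached within n <= {max_n}")


def qq_points(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Normal Q–Q pairs and the fitted reference line.

    Returns ``(theoretical, ordered, (intercept, slope))`` where theoretical
    quantiles are Φ⁻¹((i − 0.5)/n) and the reference line maps standardized
    quantiles back to data units (the 45° line after standardization).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateSampleError("Q-Q plot needs n >= 2")
    n = x.size
    theoretical = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    ordered = np.sort(x)
    return theoretical, ordered, (float(x.mean()), float(x.std(ddof=1)))
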
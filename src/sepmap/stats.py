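"""Statistical layer: circular statistics, rank tests, developmental trends.

Circular quantities (the angle of the N peak relative to the P peak, pooled
over animals) are summarized by the mean resultant vector and tested for
uniformity with the Rayleigh test. Monotone age trends use Spearman rank
correlation; two-group comparisons (high- vs low-threshold hearing periods)
use the one-sided Wilcoxon rank-sum test; latency-vs-age trajectories are
fit with a decaying exponential. Group summaries are mean ± SEM. All
p-values are reported raw (no multiple-testing correction); the conventional
0.05 level is never used to gate pipeline outputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.optimize import curve_fit

__all__ = [
    "RayleighResult",
    "TestResult",
    "TrendFit",
    "wrap_angles",
    "rayleigh_test",
    "circular_mean_sem",
    "spearman",
    "wilcoxon_rank_sum",
    "fit_exponential_trend",
    "mean_sem",
]


@dataclass(frozen=True)
class RayleighResult:
    mean_angle: float  # degrees in (−180, 180]
    r_bar: float  # mean resultant length in [0, 1]
    z: float  # n · r_bar²
    p: float  # in (0, 1]
    n: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    test_name: str
    n_per_group: tuple
    one_sided: bool


@dataclass(frozen=True)
class TrendFit:
    """Least-squares fit of value(age) = a·e^{−b·(age − age₀)} + c."""

    a: float
    b: float
    c: float
    reference_age: float
    residual_rms: float
    n_points: int

    def predict(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.a * np.exp(-self.b * (age - self.reference_age)) + self.c


def wrap_angles(angles_deg) -> np.ndarray:
    """Reduce angles to the interval (−180, 180] degrees."""
    a = np.asarray(angles_deg, dtype=float)
    wrapped = np.mod(-a + 180.0, 360.0)
    return -(wrapped - 180.0)


def _resultant(angles_deg: np.ndarray) -> tuple[float, float]:
    """(mean resultant length, mean angle in degrees)."""
    rad = np.radians(angles_deg)
    z = np.exp(1j * rad).mean()
    return float(np.abs(z)), float(np.degrees(np.angle(z)))


def rayleigh_test(angles_deg) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    R̄ is the mean resultant length of the unit vectors e^{iθ}; Z = n·R̄².
    The p-value uses the standard series approximation

        p ≈ e^{−Z} [1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)]

    clipped to (0, 1]. Invariant under global rotation of the sample.
    """
    angles = wrap_angles(angles_deg)
    n = angles.size
    if n < 3:
        raise ValueError("Rayleigh test needs at least 3 angles")
    r_bar, mean_angle = _resultant(angles)
    z = n * r_bar * r_bar
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4)
        / (288.0 * n * n)
    )
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return RayleighResult(mean_angle=mean_angle, r_bar=r_bar, z=z, p=p, n=n)


def circular_mean_sem(angles_deg) -> tuple[float, float]:
    """Circular mean and circular standard error of the mean, in degrees.

    The SEM follows Fisher's dispersion-based estimate: with ρ̂₁ and ρ̂₂ the
    mean resultant lengths of the angles and the doubled angles, the circular
    dispersion is δ̂ = (1 − ρ̂₂)/(2ρ̂₁²) and SEM = √(δ̂/n). An identical
    sample has SEM 0; a sample with ρ̂₁ = 0 has no defined mean.
    """
    angles = wrap_angles(angles_deg)
    n = angles.size
    if n < 2:
        raise ValueError("circular SEM needs at least 2 angles")
    rho1, mean_angle = _resultant(angles)
    if rho1 < 1e-12:
        raise ValueError("mean resultant length is 0: mean angle undefined")
    rho2, _ = _resultant(2.0 * angles)
    dispersion = (1.0 - rho2) / (2.0 * rho1 * rho1)
    sem = math.degrees(math.sqrt(max(dispersion, 0.0) / n))
    return mean_angle, sem


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by full enumeration of y-rank permutations."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = x.size
    rx_c = rx - rx.mean()
    denom = math.sqrt(float((rx_c**2).sum()) * float(((ry - ry.mean()) ** 2).sum()))
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(ry):
        num = float(np.dot(rx_c, np.asarray(perm) - ry.mean()))
        if abs(num / denom) >= target:
            count += 1
        total += 1
    return count / total


def spearman(x, y, exact_max_n: int = 9) -> TestResult:
    """Spearman rank correlation with two-sided p-value.

    Mid-ranks for ties; p by the t-approximation, replaced by exact
    permutation enumeration for n ≤ ``exact_max_n``. Constant inputs have no
    defined rank correlation and are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 4:
        raise ValueError("Spearman correlation needs at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation is undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    if x.size <= exact_max_n:
        p = _spearman_exact_p(x, y, rho)
    if abs(rho) == 1.0:
        p = min(p, 1.0)
    return TestResult(statistic=rho, p=float(min(max(p, 0.0), 1.0)),
                      test_name="spearman", n_per_group=(x.size,),
                      one_sided=False)


def wilcoxon_rank_sum(group_a, group_b,
                      alternative: str = "less") -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test; one-sided by default.

    ``alternative='less'`` tests whether group A is stochastically smaller
    than group B. Exact p by enumeration when n_A + n_B ≤ 20 with no ties,
    else a normal approximation with tie and continuity correction. The
    reported statistic is the rank sum of group A.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError("alternative must be less/greater/two-sided")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method,
                           use_continuity=True)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U → rank sum
    return TestResult(statistic=w, p=float(res.pvalue),
                      test_name=f"wilcoxon_rank_sum[{method}]",
                      n_per_group=(a.size, b.size),
                      one_sided=alternative != "two-sided")


def fit_exponential_trend(ages, values, n_starts: int = 12) -> TrendFit:
    """Least-squares fit of a·e^{−b·(age − min age)} + c with multi-start b.

    The decay rate axis is the hard one, so b is started over a log-spaced
    grid (plus b = 0 for flat data) and the lowest-SSE solution is kept.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.shape != values.shape or ages.ndim != 1:
        raise ValueError("ages and values must be equal-length 1-D arrays")
    if np.unique(ages).size < 4:
        raise ValueError("trend fit needs at least 4 distinct ages")
    age0 = float(ages.min())

    def model(age, a, b, c):
        return a * np.exp(-b * (age - age0)) + c

    spread = float(values.max() - values.min())
    starts = [0.0] + list(np.geomspace(0.01, 2.0, n_starts - 1))
    best = None
    for b0 in starts:
        p0 = [spread if spread > 0 else 1.0, b0, float(values.min())]
        try:
            popt, _ = curve_fit(
                model, ages, values, p0=p0,
                bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(((model(ages, *popt) - values) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError(
            "exponential trend fit failed to converge from every start; "
            "inspect the input for degenerate structure"
        )
    sse, (a, b, c) = best
    return TrendFit(a=float(a), b=float(b), c=float(c), reference_age=age0,
                    residual_rms=math.sqrt(sse / ages.size),
                    n_points=ages.size)


def mean_sem(values) -> tuple[float, float]:
    """Group summary as (mean, standard error of the mean)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), sem
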
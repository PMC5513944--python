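"""Agreement and consistency statistics for kinetics indices.

Pearson correlation, Bland–Altman agreement (bias and 1.96·SD limits),
group CI95 expressed as a percentage of the mean, t-test sample-size
curves at a given power, and the sigmoid description of MNG as a
function of log10(τ).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats
from scipy.optimize import curve_fit
from statsmodels.stats.power import TTestIndPower, TTestPower

__all__ = [
    "AgreementResult",
    "SigmoidFit",
    "pearson",
    "bland_altman",
    "group_ci95_pct",
    "sample_size_curve",
    "sigmoid_fit",
    "PHYSIOLOGICAL_TAU_RANGE",
]

#: Physiological range of the V̇O2 time constant (s).
PHYSIOLOGICAL_TAU_RANGE = (10.0, 100.0)


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman agreement summary.

    ``bias`` is the mean paired difference x − y and ``loa`` the
    1.96·SD half-width of the limits of agreement, both in index units.
    ``bias_pct``/``loa_pct`` express them relative to the total
    variation of the pooled values (range by default, configurable to
    the pooled mean).
    """

    bias: float
    loa: float
    bias_pct: float
    loa_pct: float
    normalization: str = "range"

    def __post_init__(self) -> None:
        if self.loa < 0:
            raise ValueError("loa must be non-negative")


@dataclass(frozen=True)
class SigmoidFit:
    """Four-parameter logistic description of MNG vs log10(τ).

    MNG(log10 τ) = lower + (upper − lower) / (1 + 10^(slope·(log10 τ − inflection)))

    ``r`` correlates fitted with observed values; ``linear_r`` is the
    Pearson r of a straight-line fit restricted to the physiological τ
    sub-range, for the sigmoid-vs-linear comparison.
    """

    lower: float
    upper: float
    inflection: float
    slope: float
    r: float
    linear_r: float | None = None

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError("lower asymptote must be below the upper asymptote")

    def predict(self, taus: np.ndarray) -> np.ndarray:
        x = np.log10(np.asarray(taus, dtype=float))
        return _logistic(x, self.lower, self.upper, self.inflection, self.slope)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sp_stats.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(
    x: Sequence[float],
    y: Sequence[float],
    normalization: str = "range",
) -> AgreementResult:
    """Bland–Altman agreement between paired measurements.

    ``bias = mean(x − y)`` and ``loa = 1.96·sd(x − y)``; the percentage
    forms divide by the total variation of the pooled values — their
    range (max − min) by default, or their mean with
    ``normalization="mean"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired with equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    loa = float(1.96 * d.std(ddof=1))
    pooled = np.concatenate([x, y])
    if normalization == "range":
        denom = float(pooled.max() - pooled.min())
    elif normalization == "mean":
        denom = float(abs(pooled.mean()))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom > 0:
        bias_pct, loa_pct = 100.0 * bias / denom, 100.0 * loa / denom
    else:
        bias_pct = loa_pct = 0.0
    return AgreementResult(
        bias=bias, loa=loa, bias_pct=bias_pct, loa_pct=loa_pct, normalization=normalization
    )


def group_ci95_pct(values: Sequence[float]) -> float:
    """Group CI95 (1.96·SD) as a percentage of the group mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CI95 as % of mean is undefined for zero mean")
    return float(100.0 * 1.96 * values.std(ddof=1) / mean)


def sample_size_curve(
    effect_sizes: Sequence[float],
    sd: float,
    power: float = 0.8,
    alpha: float = 0.05,
    paired: bool = False,
) -> np.ndarray:
    """Sample size per effect size for a (paired) t-test at given power.

    Uses the noncentral-t power formulation (statsmodels); ``n`` is the
    per-group size for the two-sample test or the number of pairs for
    the paired test, rounded up with a floor of 2.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    effects = np.asarray(effect_sizes, dtype=float)
    if np.any(effects <= 0):
        raise ValueError("effect sizes must be positive")
    solver = TTestPower() if paired else TTestIndPower()
    out = np.empty(effects.size, dtype=int)
    for i, eff in enumerate(effects):
        es = eff / sd
        kwargs = {"nobs": 2.0} if paired else {"nobs1": 2.0}
        if solver.power(effect_size=es, alpha=alpha, **kwargs) >= power:
            out[i] = 2  # already powered at the minimum size
            continue
        n = solver.solve_power(effect_size=es, power=power, alpha=alpha)
        out[i] = max(int(np.ceil(n)), 2)
    return out


def _logistic(x: np.ndarray, lower: float, upper: float, inflection: float, slope: float):
    return lower + (upper - lower) / (1.0 + 10.0 ** (slope * (x - inflection)))


def sigmoid_fit(
    taus: Sequence[float],
    mngs: Sequence[float],
    physiological_range: tuple[float, float] = PHYSIOLOGICAL_TAU_RANGE,
) -> SigmoidFit:
    """Four-parameter logistic fit of MNG against log10(τ).

    Also reports the linear-fit Pearson r on the physiological τ
    sub-range (when at least 3 points fall inside it), since the
    mid-section of the logistic is nearly linear there.
    """
    taus = np.asarray(taus, dtype=float)
    mngs = np.asarray(mngs, dtype=float)
    if taus.size != mngs.size:
        raise ValueError("taus and mngs must have equal length")
    if taus.size < 5:
        raise ValueError("need at least 5 points spanning the transition")
    if np.any(taus <= 0):
        raise ValueError("time constants must be positive")
    x = np.log10(taus)
    p0 = (float(mngs.min()), float(mngs.max()), float(np.median(x)), 1.0)
    try:
        popt, _ = curve_fit(_logistic, x, mngs, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"sigmoid fit did not converge: {exc}") from exc
    lower, upper, inflection, slope = (float(v) for v in popt)
    if lower > upper:  # equivalent parameterization with flipped slope
        lower, upper, slope = upper, lower, -slope
    predicted = _logistic(x, lower, upper, inflection, slope)
    r, _ = sp_stats.pearsonr(predicted, mngs)

    lo, hi = physiological_range
    sub = (taus >= lo) & (taus <= hi)
    linear_r = None
    if sub.sum() >= 3 and np.std(mngs[sub]) > 0:
        linear_r = float(sp_stats.pearsonr(x[sub], mngs[sub])[0])
    return SigmoidFit(
        lower=lower, upper=upper, inflection=inflection, slope=slope,
        r=float(r), linear_r=linear_r,
    )
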
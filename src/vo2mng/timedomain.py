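"""Time-domain V̇O2 kinetics: mono-exponential fitting on the step
embedded in the PRBS.

The classical reference analysis fits the delayed mono-exponential

    V̇O2(t) = a0 + a · (1 − exp(−(t − TD)/τ))    for t ≥ TD,
    V̇O2(t) = a0                                  for t < TD,

to the longest input-invariant window of the protocol: the final 10 s of
a 90-s low-work-rate stretch followed by 120 s at the high level
(onset at the 180th second of the step-aligned PRBS period).  The first
20 s after onset, dominated by the cardio-dynamic (phase I) component,
are excluded from the fit.  The mean response time is MRT = τ + TD.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from scipy.optimize import least_squares

from .series import UniformSeries, WorkRateSeries

__all__ = [
    "FitWindow",
    "StepWindowData",
    "ExpFit",
    "FitError",
    "find_step_runs",
    "validate_window",
    "extract_fit_window",
    "fit_monoexp",
]

TAU_BOUNDS = (0.1, 200.0)
TD_BOUNDS = (0.0, 60.0)


class FitError(RuntimeError):
    """Raised when the nonlinear fit fails to converge."""


@dataclass(frozen=True)
class FitWindow:
    """Location of the step window inside one PRBS period.

    ``start`` is the onset of the step (s into the period),
    ``baseline_span`` the low-level seconds retained before onset,
    ``step_span`` the high-level seconds after onset and
    ``cardio_exclusion`` the post-onset seconds flagged as the
    cardio-dynamic phase and excluded from fitting.
    """

    start: float = 180.0
    baseline_span: float = 10.0
    step_span: float = 120.0
    cardio_exclusion: float = 20.0

    def __post_init__(self) -> None:
        if self.baseline_span <= 0 or self.step_span <= 0:
            raise ValueError("window spans must be positive")
        if not 0 <= self.cardio_exclusion < self.step_span:
            raise ValueError("cardio_exclusion must lie within the step span")


@dataclass(frozen=True)
class StepWindowData:
    """Step-window samples with onset-relative time.

    ``t`` runs from −baseline_span to step_span (onset at t = 0);
    ``fit_mask`` is False for samples inside the cardio-dynamic
    exclusion, True for samples that participate in the fit.
    """

    t: np.ndarray
    vo2: np.ndarray
    fit_mask: np.ndarray
    window: FitWindow


@dataclass(frozen=True)
class ExpFit:
    """Mono-exponential fit result.

    Units: ml·min⁻¹ for a0/a, seconds for tau/td/mrt.  ``ci95`` and
    ``p_values`` are per-parameter (a0, a, tau, td) from the asymptotic
    covariance of the least-squares estimator.
    """

    a0: float
    a: float
    tau: float
    td: float
    mrt: float
    r2: float
    sse: float
    ci95: dict[str, float]
    p_values: dict[str, float]
    n_fit: int
    tau_at_bound: bool = False

    def __post_init__(self) -> None:
        if abs(self.mrt - (self.tau + self.td)) > 1e-9:
            raise ValueError("mrt must equal tau + td")


def find_step_runs(protocol: WorkRateSeries) -> list[dict[str, float]]:
    """Low→high transitions of one protocol period, with cyclic run lengths.

    Returns one record per transition: onset time (s into the period), the
    length of the low run ending at the onset and of the high run starting
    there (both in seconds, scanned cyclically across the period wrap).
    """
    values = protocol.one_period()
    n = values.size
    high = values == protocol.high
    runs = []
    for k in range(n):
        if high[k] and not high[k - 1]:  # low -> high transition (cyclic)
            low_len = 0
            i = (k - 1) % n
            while not high[i] and low_len < n:
                low_len += 1
                i = (i - 1) % n
            high_len = 0
            i = k
            while high[i] and high_len < n:
                high_len += 1
                i = (i + 1) % n
            runs.append(
                {
                    "onset_s": k * protocol.dt,
                    "low_run_s": low_len * protocol.dt,
                    "high_run_s": high_len * protocol.dt,
                }
            )
    return runs


def validate_window(
    protocol: WorkRateSeries,
    window: FitWindow = FitWindow(),
    min_low_run_s: float = 90.0,
) -> dict[str, float]:
    """Check that the protocol supports the configured step window.

    Requires a low→high transition at ``window.start`` preceded by at
    least ``min_low_run_s`` at the low level and followed by at least
    ``window.step_span`` at the high level.  Raises with the available
    runs otherwise (the embedded step depends on the register seed; the
    step-aligned seed places it at 180 s).
    """
    runs = find_step_runs(protocol)
    for run in runs:
        if (
            abs(run["onset_s"] - window.start) < protocol.dt / 2
            and run["low_run_s"] >= min_low_run_s - 1e-9
            and run["high_run_s"] >= window.step_span - 1e-9
        ):
            return run
    raise ValueError(
        f"protocol has no >= {min_low_run_s:g} s low / >= {window.step_span:g} s high "
        f"transition at {window.start:g} s; available low->high runs: {runs}"
    )


def extract_fit_window(
    series: UniformSeries,
    window: FitWindow = FitWindow(),
) -> StepWindowData:
    """Extract baseline and step segments around the embedded step.

    Returns onset-relative samples: the ``baseline_span`` seconds before
    the onset at ``window.start`` plus the ``step_span`` seconds after
    it, with cardio-dynamic samples (0 ≤ t < cardio_exclusion) flagged
    for exclusion from fitting.
    """
    t_abs = series.times
    lo = window.start - window.baseline_span
    hi = window.start + window.step_span
    if lo < t_abs[0] - 1e-9 or hi > t_abs[-1] + series.dt + 1e-9:
        raise ValueError(
            f"window [{lo}, {hi}] s is outside the series support "
            f"[{t_abs[0]}, {t_abs[-1]}] s"
        )
    sel = (t_abs >= lo - 1e-9) & (t_abs < hi - 1e-9)
    t_rel = t_abs[sel] - window.start
    vo2 = series.values[sel]
    excluded = (t_rel >= -1e-9) & (t_rel < window.cardio_exclusion - 1e-9)
    return StepWindowData(t=t_rel, vo2=vo2, fit_mask=~excluded, window=window)


def _model(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    a0, a, tau, td = theta
    out = np.full_like(t, a0, dtype=float)
    on = t >= td
    out[on] = a0 + a * (1.0 - np.exp(-(t[on] - td) / tau))
    return out


def fit_monoexp(
    data: StepWindowData,
    x0: tuple[float, float, float, float] | None = None,
) -> ExpFit:
    """Nonlinear least-squares fit of the delayed mono-exponential.

    Baseline samples (t < 0) participate with model value a0; samples
    inside the cardio-dynamic exclusion are ignored.  Starting values
    default to a0 = mean(baseline), a = mean(last 30 s) − a0, τ = 30 s,
    TD = 15 s, with bounds τ ∈ [0.1, 200] s and TD ∈ [0, 60] s covering
    the physiological range.  Confidence intervals and p-values use the
    asymptotic normal approximation with a t reference distribution.
    """
    t = data.t[data.fit_mask]
    y = data.vo2[data.fit_mask]
    if t.size < 4:
        raise ValueError("need at least 4 non-excluded samples spanning baseline and step")

    if x0 is None:
        baseline = y[t < 0]
        a0_start = float(baseline.mean()) if baseline.size else float(y[0])
        tail = y[t >= t.max() - 30.0]
        a_start = max(float(tail.mean()) - a0_start, 1.0)
        x0 = (a0_start, a_start, 30.0, 15.0)

    lower = np.array([-np.inf, -np.inf, TAU_BOUNDS[0], TD_BOUNDS[0]])
    upper = np.array([np.inf, np.inf, TAU_BOUNDS[1], TD_BOUNDS[1]])
    x0 = np.clip(np.asarray(x0, dtype=float), lower + 1e-9, upper - 1e-9)

    result = least_squares(
        lambda th: _model(th, t) - y,
        x0=x0,
        bounds=(lower, upper),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    if not result.success:
        raise FitError(
            f"mono-exponential fit did not converge (status {result.status}: "
            f"{result.message}); starts {tuple(x0)}"
        )
    a0, a, tau, td = result.x
    residuals = result.fun
    sse = float(residuals @ residuals)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    dof = max(t.size - 4, 1)

    # covariance from the Jacobian at the solution
    names = ("a0", "a", "tau", "td")
    jtj = result.jac.T @ result.jac
    try:
        cov = np.linalg.inv(jtj) * (sse / dof)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    tcrit = sp_stats.t.ppf(0.975, dof)
    ci95 = {k: float(tcrit * s) for k, s in zip(names, se)}
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.abs(result.x) / se
    p_values = {k: float(2.0 * sp_stats.t.sf(tv, dof)) for k, tv in zip(names, tvals)}

    eps = 1e-6
    tau_at_bound = tau <= TAU_BOUNDS[0] + eps or tau >= TAU_BOUNDS[1] - eps
    return ExpFit(
        a0=float(a0),
        a=float(a),
        tau=float(tau),
        td=float(td),
        mrt=float(tau + td),
        r2=float(min(max(r2, 0.0), 1.0)),
        sse=sse,
        ci95=ci95,
        p_values=p_values,
        n_fit=int(t.size),
        tau_at_bound=bool(tau_at_bound),
    )
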
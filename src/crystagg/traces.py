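"""Turbidity-trace kinetic statistics.

The central statistic is the tangent method: a line is fitted to the
steepest part of the turbidity curve; its slope is the maximum
aggregation rate and its intersection with the pre-growth baseline is
the apparent lag time.  Traces that grow in two distinct phases (seen
at low degrees of oxidation with inositol, and at low protein
concentration) are segmented first, and the statistic may be computed
from the second phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, optimize, signal, stats

from .containers import TurbidityTrace

__all__ = [
    "TangentFit",
    "DoseResponseFit",
    "DoseResponseModel",
    "smooth",
    "segment_phases",
    "tangent_fit",
    "endpoint_turbidity",
    "turbidity_soluble_correlation",
    "dose_response",
]


class TraceAnalysisError(ValueError):
    """Raised when a trace cannot support the requested statistic."""


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth(trace: TurbidityTrace, window: int = 5) -> TurbidityTrace:
    """Local quadratic (Savitzky–Golay) smoothing on the trace grid.

    Endpoints are handled by polynomial extension of the edge window,
    which—like the interior filter—reproduces any quadratic exactly.
    """
    if window % 2 == 0 or window < 3:
        raise TraceAnalysisError("window must be odd and >= 3")
    if window >= len(trace):
        raise TraceAnalysisError(
            f"trace too short ({len(trace)} points) for window {window}")
    tau = signal.savgol_filter(trace.turbidity, window, 2, mode="interp")
    return TurbidityTrace(well=trace.well, condition=trace.condition,
                          times=trace.times.copy(), turbidity=tau,
                          flags=dict(trace.flags, smoothed=True))


def _derivative(trace: TurbidityTrace, window: int = 5) -> np.ndarray:
    """Smoothed first derivative (AU/s) by local quadratic fitting."""
    dt = np.diff(trace.times)
    if np.allclose(dt, dt[0], rtol=1e-6):
        return signal.savgol_filter(trace.turbidity, min(window, len(trace) - 1) | 1,
                                    2, deriv=1, delta=dt[0], mode="interp")
    return np.gradient(trace.turbidity, trace.times)


# ---------------------------------------------------------------------------
# phase segmentation
# ---------------------------------------------------------------------------

def segment_phases(trace: TurbidityTrace, window: int = 5,
                   min_peak_frac: float = 0.10,
                   valley_frac: float = 0.50) -> list[tuple[int, int]]:
    """Split a trace into growth phases from its smoothed derivative.

    Phases are maximal intervals around local derivative maxima that
    exceed ``min_peak_frac`` of the global maximum and are separated
    from their neighbour by a valley below ``valley_frac`` of the
    smaller adjacent peak.  Returns index intervals (start, stop)
    covering the whole trace, ordered by time; a trace with no interior
    derivative structure is a single phase.
    """
    d = _derivative(trace, window)
    dmax = d.max()
    if dmax <= 0:
        return [(0, len(trace) - 1)]
    peaks, _ = signal.find_peaks(d, height=min_peak_frac * dmax)
    # a monotone-derivative trace (ramp, half-sigmoid) has no interior peak
    if peaks.size == 0:
        return [(0, len(trace) - 1)]
    # merge peaks not separated by a deep enough valley
    groups: list[list[int]] = [[int(peaks[0])]]
    for pk in peaks[1:]:
        prev = groups[-1][-1]
        valley = d[prev:pk + 1].min()
        if valley < valley_frac * min(d[prev], d[pk]):
            groups.append([int(pk)])
        else:
            groups[-1].append(int(pk))
    if len(groups) == 1:
        return [(0, len(trace) - 1)]
    bounds = [0]
    for g0, g1 in zip(groups[:-1], groups[1:]):
        lo, hi = g0[-1], g1[0]
        bounds.append(lo + int(np.argmin(d[lo:hi + 1])))
    bounds.append(len(trace) - 1)
    return [(bounds[i], bounds[i + 1]) for i in range(len(groups))]


# ---------------------------------------------------------------------------
# tangent fit
# ---------------------------------------------------------------------------

@dataclass
class TangentFit:
    """Tangent-method statistics of one turbidity trace.

    ``max_rate`` is the slope of the best-fit tangent to the steepest
    part of the (selected phase of the) curve; ``lag_time`` is where
    that tangent crosses the baseline.  ``method`` records whether the
    tangent came from a local logistic refinement or the smoothed
    discrete derivative.
    """

    max_rate: float          # AU/s
    t_at_max: float          # s
    lag_time: float          # s; may be negative (flagged, not clamped)
    baseline: float          # AU
    phase_index: int
    n_phases: int
    tangent_value: float     # τ at the anchor point
    method: str = "logistic"
    rmse: float = float("nan")
    flags: dict = field(default_factory=dict)

    def tangent(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the tangent line at times t."""
        return self.tangent_value + self.max_rate * (np.asarray(t) - self.t_at_max)

    def summary(self) -> str:
        lines = [
            "Tangent fit",
            f"  max rate      {self.max_rate:.4e} AU/s (at t = {self.t_at_max:.0f} s)",
            f"  apparent lag  {self.lag_time:.0f} s",
            f"  baseline      {self.baseline:.4f} AU",
            f"  phase         {self.phase_index + 1} of {self.n_phases}",
            f"  method        {self.method} (rmse {self.rmse:.3e} AU)",
        ]
        return "\n".join(lines)


def _logistic(t, b, L, k, t0):
    return b + L / (1.0 + np.exp(-np.clip(k * (t - t0), -500, 500)))


def tangent_fit(
    trace: TurbidityTrace,
    phase_rule: str | int = "global_max",
    window: int = 5,
    baseline_points: int = 3,
) -> TangentFit:
    """Fit the tangent to the steepest part of a turbidity trace.

    Parameters
    ----------
    trace : TurbidityTrace
        The trace; smoothing is applied internally.
    phase_rule : {"global_max", "second_phase"} or int
        Which growth phase carries the tangent.  ``global_max`` (the
        default) uses the phase containing the overall steepest point;
        ``second_phase`` uses the second phase when the trace is
        biphasic (falling back to the only phase otherwise); an integer
        selects a phase by index.
    window : int
        Savitzky–Golay window for smoothing/differentiation.
    baseline_points : int
        Number of initial readings averaged into the baseline.

    Notes
    -----
    Within the selected phase the discrete estimate is refined by a
    least-squares logistic fit (offset + scale + rate + midpoint); when
    the local fit converges and reproduces the phase closely, the
    tangent is anchored at the fitted inflection, which makes the
    estimator exact on logistic curves regardless of the read
    interval.  Otherwise the smoothed discrete derivative is used.
    """
    if len(trace) < 8:
        raise TraceAnalysisError("tangent fit needs at least 8 readings")
    t, tau_raw = trace.times, trace.turbidity
    sm = smooth(trace, window)
    tau = sm.turbidity
    d = _derivative(trace, window)
    if d.max() <= 0:
        raise TraceAnalysisError("no growth phase: derivative <= 0 everywhere")
    baseline = float(np.mean(tau_raw[:baseline_points]))

    phases = segment_phases(trace, window)
    n_phases = len(phases)
    if phase_rule == "global_max":
        imax = int(np.argmax(d))
        phase_index = next(i for i, (a, b) in enumerate(phases) if a <= imax <= b)
    elif phase_rule == "second_phase":
        phase_index = 1 if n_phases >= 2 else 0
    elif isinstance(phase_rule, int):
        if not 0 <= phase_rule < n_phases:
            raise TraceAnalysisError(
                f"phase index {phase_rule} out of range for {n_phases} phases")
        phase_index = phase_rule
    else:
        raise TraceAnalysisError(f"unknown phase rule {phase_rule!r}")
    a, b = phases[phase_index]
    if b - a + 1 < 4:
        a, b = max(0, a - 2), min(len(trace) - 1, b + 2)
    seg_t, seg_tau = t[a:b + 1], tau_raw[a:b + 1]
    d_seg = d[a:b + 1]
    j = int(np.argmax(d_seg))
    disc_rate = float(d_seg[j])
    disc_t = float(seg_t[j])
    disc_val = float(tau[a + j])
    # spline refinement of the discrete maximum: exact for smooth traces
    # sampled well below their feature scale
    if len(seg_t) >= 5:
        cs = interpolate.CubicSpline(seg_t, tau[a:b + 1])
        tfine = np.linspace(seg_t[0], seg_t[-1], max(20 * len(seg_t), 200))
        dfine = cs(tfine, 1)
        jj = int(np.argmax(dfine))
        if dfine[jj] > 0:
            disc_rate = float(dfine[jj])
            disc_t = float(tfine[jj])
            disc_val = float(cs(tfine[jj]))

    # local logistic refinement
    rng = float(seg_tau.max() - seg_tau.min())
    fit = None
    if rng > 0 and len(seg_t) >= 5:
        p0 = (float(seg_tau.min()), rng, max(4.0 * disc_rate / rng, 1e-6), disc_t)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    _logistic, seg_t, seg_tau, p0=p0, maxfev=5000,
                    bounds=([-np.inf, 0, 0, seg_t[0] - (seg_t[-1] - seg_t[0])],
                            [np.inf, np.inf, np.inf, seg_t[-1] + (seg_t[-1] - seg_t[0])]),
                )
            resid = seg_tau - _logistic(seg_t, *popt)
            rmse = float(np.sqrt(np.mean(resid ** 2)))
            if rmse <= 0.005 * rng:
                fit = (popt, rmse)
        except (RuntimeError, ValueError):
            fit = None

    flags: dict = {}
    if fit is not None:
        (bb, L, k, t0), rmse = fit
        max_rate = float(L * k / 4.0)
        t_at_max = float(t0)
        tangent_value = float(bb + L / 2.0)
        method = "logistic"
    else:
        max_rate, t_at_max, tangent_value = disc_rate, disc_t, disc_val
        rmse = float("nan")
        method = "discrete"
    lag = t_at_max - (tangent_value - baseline) / max_rate
    if lag < 0:
        flags["negative_lag"] = True
        warnings.warn("apparent lag time is negative", stacklevel=2)
    if lag > t_at_max:
        # tangent anchored below baseline cannot happen for growing traces,
        # but guard against pathological smoothing artefacts
        flags["lag_after_peak"] = True
    return TangentFit(max_rate=max_rate, t_at_max=t_at_max, lag_time=float(lag),
                      baseline=baseline, phase_index=phase_index,
                      n_phases=n_phases, tangent_value=tangent_value,
                      method=method, rmse=rmse, flags=flags)


# ---------------------------------------------------------------------------
# endpoint and correlation
# ---------------------------------------------------------------------------

def endpoint_turbidity(trace: TurbidityTrace, tail_points: int = 3) -> float:
    """Mean of the final ``tail_points`` readings (end-of-incubation turbidity)."""
    if tail_points < 1:
        raise TraceAnalysisError("tail_points must be >= 1")
    return float(np.mean(trace.turbidity[-tail_points:]))


def turbidity_soluble_correlation(endpoints, soluble_fractions) -> dict:
    """OLS line and Pearson r between endpoint turbidity and soluble fraction.

    A strong negative correlation reflects turbidity being proportional
    to the aggregated (insoluble) protein mass.
    """
    x = np.asarray(soluble_fractions, dtype=float)
    y = np.asarray(endpoints, dtype=float)
    if x.size != y.size or x.size < 3:
        raise TraceAnalysisError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise TraceAnalysisError("zero variance in inputs")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue)}


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    """Normalized dose-response of the maximum aggregation rate."""

    doses: np.ndarray                 # mM
    normalized_rates: np.ndarray      # fraction of zero-dose rate
    percent_lag_change: np.ndarray | None
    K_I: float = float("nan")         # mM
    K_I_se: float = float("nan")
    saturated: bool = False           # rates flat: K_I unidentifiable (→ ∞)
    reference: str = "0 mM"

    def summary(self) -> str:
        lines = ["Dose-response (rates normalized to 0 mM)"]
        for i, ds in enumerate(self.doses):
            lag = ("" if self.percent_lag_change is None
                   else f"   lag change {self.percent_lag_change[i]:+.1f}%")
            lines.append(f"  {ds:8.1f} mM   rate {self.normalized_rates[i]:.3f}{lag}")
        if self.saturated:
            lines.append("  K_I unidentifiable (no dose effect)")
        elif np.isfinite(self.K_I):
            lines.append(f"  K_I = {self.K_I:.1f} ± {self.K_I_se:.1f} mM")
        return "\n".join(lines)


class DoseResponseModel:
    """One-parameter inhibition model r(d) = 1/(1 + d/K_I) for normalized rates.

    Built from per-dose tangent statistics; ``fit()`` normalizes to the
    zero-dose rate and estimates K_I by least squares.
    """

    def __init__(self, doses_mM, max_rates, lag_times=None):
        self.doses = np.asarray(doses_mM, dtype=float)
        self.rates = np.asarray(max_rates, dtype=float)
        self.lags = None if lag_times is None else np.asarray(lag_times, dtype=float)
        if self.doses.shape != self.rates.shape:
            raise TraceAnalysisError("doses and rates must have equal length")
        if not np.any(self.doses == 0):
            raise TraceAnalysisError("dose 0 (reference condition) is required")

    @classmethod
    def from_fits(cls, fits_by_dose: dict[float, TangentFit]) -> "DoseResponseModel":
        doses = sorted(fits_by_dose)
        return cls(doses,
                   [fits_by_dose[d].max_rate for d in doses],
                   [fits_by_dose[d].lag_time for d in doses])

    def fit(self) -> DoseResponseFit:
        i0 = int(np.nonzero(self.doses == 0)[0][0])
        r0 = self.rates[i0]
        if r0 <= 0:
            raise TraceAnalysisError("zero-dose rate must be positive")
        norm = self.rates / r0
        lag_pct = None
        if self.lags is not None and self.lags[i0] != 0:
            lag_pct = 100.0 * (self.lags - self.lags[i0]) / abs(self.lags[i0])

        nz = self.doses > 0
        K_I, se, saturated = float("nan"), float("nan"), False
        if np.allclose(norm, 1.0, atol=1e-12):
            saturated = True
        elif nz.sum() == 1:
            d, r = float(self.doses[nz][0]), float(norm[nz][0])
            if r < 1:
                K_I = d * r / (1.0 - r)  # closed form from one point
        else:
            # joint fit of scale and K on the log scale (multiplicative
            # plate-reader noise): ln r = ln r0 − ln(1 + d/K).  Normalizing
            # to the observed dose-0 rate would pin that point and
            # understate the uncertainty of K.
            def model(d, ln_r0, ln_K):
                return ln_r0 - np.log1p(d / np.exp(ln_K))

            try:
                popt, pcov = optimize.curve_fit(
                    model, self.doses, np.log(self.rates),
                    p0=(np.log(r0), np.log(float(np.median(self.doses[nz])))),
                    maxfev=5000)
                K_I = float(np.exp(popt[1]))
                se = float(K_I * np.sqrt(pcov[1, 1]))  # delta method
            except (RuntimeError, ValueError):
                pass
        return DoseResponseFit(doses=self.doses.copy(), normalized_rates=norm,
                               percent_lag_change=lag_pct, K_I=K_I, K_I_se=se,
                               saturated=saturated)


def dose_response(fits_by_dose: dict[float, TangentFit]) -> DoseResponseFit:
    """Normalize per-dose tangent fits to the zero-dose condition and fit K_I."""
    return DoseResponseModel.from_fits(fits_by_dose).fit()
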
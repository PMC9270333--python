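"""Shared mono-exponential fitting machinery.

Two models cover every series the pipeline sees:

* decay      ``S(t) = S0 * exp(-t / tau)``            (pulse train, liquid decay)
* recovery   ``S(t) = S_inf * (1 - exp(-t / T))``     (thermal recovery, DNP build-up)

Fits are deterministic: start values come from closed-form/log-linear
estimates, refined by lmfit least squares.  Degenerate or wrong-model data
raise :class:`FitFailure` carrying diagnostics — never a silent success.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

__all__ = ["SignalSeries", "FitFailure", "fit_exponential_decay", "fit_exponential_recovery"]

PHASE_LABELS = ("thermal_recovery", "dnp_buildup", "liquid_decay", "pulse_train")


@dataclass(frozen=True)
class SignalSeries:
    """Ordered (time, signal-integral) observations from one experiment phase."""

    times: np.ndarray  # seconds, strictly increasing
    signals: np.ndarray  # arbitrary units (spectrum integrals)
    phase_label: str = "liquid_decay"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signals", s)
        if t.ndim != 1 or s.ndim != 1 or t.shape != s.shape:
            raise ValueError("times and signals must be 1-D arrays of equal length")
        if t.size < 3:
            raise ValueError(f"need >= 3 points for fitting, got {t.size}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise ValueError("times and signals must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.phase_label not in PHASE_LABELS:
            raise ValueError(f"phase_label must be one of {PHASE_LABELS}, got {self.phase_label!r}")

    def __len__(self) -> int:
        return int(self.times.size)

    def skip_first(self, k: int) -> "SignalSeries":
        """Drop the first ``k`` (low-SNR) points."""
        if k <= 0:
            return self
        if len(self) - k < 3:
            raise ValueError(f"skipping {k} of {len(self)} points leaves fewer than 3")
        return SignalSeries(self.times[k:], self.signals[k:], self.phase_label)


class FitFailure(RuntimeError):
    """A mono-exponential fit could not be performed or did not converge.

    Carries the reason and any partial diagnostics in :attr:`diagnostics`.
    """

    def __init__(self, reason: str, **diagnostics) -> None:
        super().__init__(reason)
        self.reason = reason
        self.diagnostics = diagnostics


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def _decay_model(t, s0, tau):
    return s0 * np.exp(-t / tau)


def _recovery_model(t, s_inf, tc):
    return s_inf * (1.0 - np.exp(-t / tc))


def fit_exponential_decay(series: SignalSeries) -> tuple[float, float, float]:
    """Fit ``S0 * exp(-t/tau)``; returns ``(s0, tau, r_squared)``.

    Start values: ``S0`` from the first sample, ``tau`` from an ordinary
    least-squares line through ``log|S|`` of the positive samples.
    """
    t, s = series.times, series.signals
    if np.allclose(s, s[0]):
        raise FitFailure("constant signal: no decay to fit", value=float(s[0]))
    if np.all(s == 0):
        raise FitFailure("all-zero signal")

    pos = s > 0
    if np.count_nonzero(pos) >= 3:
        slope, intercept = np.polyfit(t[pos], np.log(s[pos]), 1)
    else:
        slope, intercept = np.polyfit(t, np.log(np.abs(s) + np.finfo(float).eps), 1)
    if slope >= 0:
        raise FitFailure(
            "signal does not decay (log-linear slope >= 0)",
            slope=float(slope),
        )
    tau0 = -1.0 / slope
    s0_0 = float(s[0]) if s[0] != 0 else float(np.exp(intercept))

    model = Model(_decay_model)
    params = model.make_params(s0=s0_0, tau=tau0)
    params["tau"].set(min=np.finfo(float).tiny)
    result = model.fit(s, params, t=t)
    if not result.success:
        raise FitFailure("decay fit did not converge", lmfit_message=result.message)
    tau = float(result.params["tau"].value)
    s0 = float(result.params["s0"].value)
    if tau <= 0:
        raise FitFailure("fitted tau is non-positive", tau=tau)
    return s0, tau, _r_squared(s, result.best_fit)


def fit_exponential_recovery(series: SignalSeries) -> tuple[float, float, float]:
    """Fit ``S_inf * (1 - exp(-t/T))``; returns ``(s_inf, tc, r_squared)``.

    The model assumes zero signal at t = 0 (magnetization saturated before
    monitoring).  Monotonically decreasing data are rejected as the wrong
    model.
    """
    t, s = series.times, series.signals
    if np.allclose(s, s[0]):
        raise FitFailure("constant signal: no recovery to fit", value=float(s[0]))
    # A recovery grows on average; a decreasing trend means the wrong model.
    slope_guess = np.polyfit(t, s, 1)[0]
    if slope_guess <= 0:
        raise FitFailure(
            "signal decreases over time: not a recovery/build-up",
            trend_slope=float(slope_guess),
        )

    s_inf0 = float(np.max(s))
    if s_inf0 <= 0:
        s_inf0 = float(np.abs(s).max())
    # log-linear estimate of T from 1 - S/S_inf for samples safely below S_inf
    resid = 1.0 - s / (s_inf0 * 1.05)
    ok = resid > 1e-6
    if np.count_nonzero(ok) >= 2:
        slope = np.polyfit(t[ok], np.log(resid[ok]), 1)[0]
        tc0 = -1.0 / slope if slope < 0 else (t[-1] - t[0])
    else:
        tc0 = (t[-1] - t[0]) / 2.0
    tc0 = abs(tc0) or (t[-1] - t[0])

    model = Model(_recovery_model)
    params = model.make_params(s_inf=s_inf0, tc=tc0)
    params["tc"].set(min=np.finfo(float).tiny)
    result = model.fit(s, params, t=t)
    if not result.success:
        raise FitFailure("recovery fit did not converge", lmfit_message=result.message)
    tc = float(result.params["tc"].value)
    s_inf = float(result.params["s_inf"].value)
    if tc <= 0 or s_inf <= 0:
        raise FitFailure("recovery fit produced non-physical parameters", tc=tc, s_inf=s_inf)
    # Unresolvable time constant: data never bend over (tc >> observation span)
    span = t[-1] - t[0]
    if tc > 100.0 * span:
        raise FitFailure(
            "time constant unresolved: data do not approach saturation",
            tc=tc,
            span=float(span),
        )
    return s_inf, tc, _r_squared(s, result.best_fit)
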
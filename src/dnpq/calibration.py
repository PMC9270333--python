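"""RF flip-angle calibration from a pulse-train decay.

A train of identical low-flip-angle pulses applied to a hyperpolarized
solid consumes longitudinal magnetization geometrically: each pulse leaves
a fraction :math:`\\cos\\alpha`.  With ``N = NX/TR`` excitations per second
and negligible relaxation over the train, the recorded signal decays
mono-exponentially with constant :math:`\\tau`, and the flip angle follows
from

.. math:: \\alpha \\cong \\arccos\\left(e^{-1/(\\tau N)}\\right).

Assuming a linear RF power amplifier, the calibrated angle transfers to
other pulse durations :math:`p_d` and attenuations :math:`p_a` (dB) as

.. math:: \\alpha(p_d, p_a) = \\alpha_{ref} \\cdot \\frac{p_d}{p_{d,ref}}
          \\cdot 10^{-(p_a - p_{a,ref})/20}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from dnpq._fitting import FitFailure, SignalSeries, fit_exponential_decay

__all__ = [
    "AcquisitionScheme",
    "PulseTrainDecay",
    "DecayFit",
    "fit_signal_decay",
    "flip_angle_from_decay",
    "scale_flip_angle",
]


@dataclass(frozen=True)
class AcquisitionScheme:
    """RF sampling parameters of one NMR measurement series.

    Parameters
    ----------
    flip_angle:
        Excitation flip angle in degrees; ``None`` until calibrated.
    pulse_duration:
        RF pulse duration p_d in microseconds (optional).
    attenuation:
        RF power attenuation p_a in dB (optional).
    ns:
        Scans per stored spectrum.
    nx:
        Excitations per repetition period TR.
    tr:
        Repetition time in seconds.
    tx:
        Spacing between consecutive excitations within one TR, seconds.
    rg:
        Linear receiver gain.
    """

    flip_angle: float | None = None  # degrees
    pulse_duration: float | None = None  # microseconds
    attenuation: float | None = None  # dB
    ns: int = 1
    nx: int = 1
    tr: float = 1.0
    tx: float | None = None  # seconds; defaults to TR/NX
    rg: float = 1.0

    def __post_init__(self) -> None:
        if self.ns < 1:
            raise ValueError(f"NS must be >= 1, got {self.ns}")
        if self.nx < 1:
            raise ValueError(f"NX must be >= 1, got {self.nx}")
        if self.tr <= 0:
            raise ValueError(f"TR must be > 0 s, got {self.tr}")
        if self.tx is None:
            object.__setattr__(self, "tx", self.tr / self.nx)
        if self.tx <= 0:
            raise ValueError(f"TX must be > 0 s, got {self.tx}")
        if self.tx * self.nx > self.tr * (1 + 1e-9):
            raise ValueError(
                f"TX*NX = {self.tx * self.nx:g} s exceeds TR = {self.tr:g} s"
            )
        if self.rg <= 0:
            raise ValueError(f"receiver gain must be > 0, got {self.rg}")
        if self.flip_angle is not None and not 0 <= self.flip_angle <= 180:
            raise ValueError(f"flip angle must be in [0, 180] deg, got {self.flip_angle}")
        if self.pulse_duration is not None and self.pulse_duration <= 0:
            raise ValueError(f"pulse duration must be > 0 us, got {self.pulse_duration}")

    @property
    def excitation_rate(self) -> float:
        """Average excitations per second, N = NX/TR."""
        return self.nx / self.tr

    def with_flip_angle(self, alpha_deg: float) -> "AcquisitionScheme":
        return AcquisitionScheme(
            flip_angle=alpha_deg,
            pulse_duration=self.pulse_duration,
            attenuation=self.attenuation,
            ns=self.ns,
            nx=self.nx,
            tr=self.tr,
            tx=self.tx,
            rg=self.rg,
        )


@dataclass(frozen=True)
class PulseTrainDecay:
    """A pulse-train decay series with its acquisition scheme."""

    series: SignalSeries
    scheme: AcquisitionScheme


@dataclass(frozen=True)
class DecayFit:
    """Result of a mono-exponential decay fit ``S0 * exp(-t/tau)``."""

    s0: float
    tau: float  # seconds
    r_squared: float


def fit_signal_decay(series: SignalSeries) -> DecayFit:
    """Fit ``S(t) = S0 exp(-t/tau)`` to a pulse-train (or liquid) decay.

    Raises
    ------
    FitFailure
        For constant, non-decaying or otherwise degenerate data; the
        exception carries diagnostics.
    """
    s0, tau, r2 = fit_exponential_decay(series)
    return DecayFit(s0=s0, tau=tau, r_squared=r2)


def flip_angle_from_decay(
    tau: float,
    scheme: AcquisitionScheme,
    relaxation_time: float | None = None,
) -> float:
    """Flip angle (degrees) from a pulse-train decay constant.

    ``alpha = arccos(exp(-1/(tau * N)))`` with ``N = NX/TR``.  Valid when
    relaxation during the train is negligible; if ``relaxation_time`` (the
    sample's T1 on the same clock) is supplied and ``tau > T1/10``, a
    warning is emitted because the recovered angle is then biased low.
    """
    if tau <= 0:
        raise ValueError(f"decay constant tau must be > 0 s, got {tau}")
    n = scheme.excitation_rate
    if relaxation_time is not None and tau > relaxation_time / 10.0:
        warnings.warn(
            f"pulse-train decay (tau = {tau:g} s) is not fast compared to "
            f"T1 = {relaxation_time:g} s; recovered flip angle is biased low",
            stacklevel=2,
        )
    alpha_rad = math.acos(math.exp(-1.0 / (tau * n)))
    return math.degrees(alpha_rad)


def scale_flip_angle(
    reference_angle: float,
    reference: AcquisitionScheme,
    target: AcquisitionScheme,
) -> float:
    """Scale a calibrated flip angle to other pulse settings.

    Amplitude-dB convention: ``alpha * (p_d/p_d_ref) * 10^(-(p_a-p_a_ref)/20)``.
    """
    for scheme, label in ((reference, "reference"), (target, "target")):
        if scheme.pulse_duration is None or scheme.attenuation is None:
            raise ValueError(
                f"{label} scheme must define pulse_duration and attenuation "
                "for flip-angle scaling"
            )
    duration_ratio = target.pulse_duration / reference.pulse_duration
    atten_factor = 10.0 ** (-(target.attenuation - reference.attenuation) / 20.0)
    return reference_angle * duration_ratio * atten_factor
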
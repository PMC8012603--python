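"""Sensitized-emission FRET quantification.

A FRET acquisition consists of three intensity channels: donor-excited
donor emission (``S_DD``), donor-excited acceptor emission (``S_DA``) and
acceptor-excited acceptor emission (``S_AA``).  ``S_DA`` is contaminated by
donor bleed-through (a fraction ``alpha`` of ``S_DD``) and direct acceptor
cross-excitation (a fraction ``delta`` of ``S_AA``).  Removing both yields
the sensitized emission

    F_c = S_DA - alpha * S_DD - delta * S_AA

from which the absolute FRET efficiency follows, given the relative
brightness/collection factor ``gamma``:

    theta = 1 / (gamma * S_DD / F_c + 1)

All intensities entering these functions are assumed background-corrected
(see :mod:`pcfret.timelapse` for ROI extraction and background subtraction).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SwitchState",
    "FretAcquisition",
    "CorrectionFactors",
    "FretMetrics",
    "PcfretError",
    "InvalidControlError",
    "DegenerateSignalError",
    "MissingChannelError",
    "estimate_crosstalk",
    "emission_ratio",
    "sensitized_emission",
    "sensitized_ratio",
    "fret_efficiency",
    "fc_from_theta",
    "fret_metrics",
    "interpolate_saa",
]


class PcfretError(ValueError):
    """Base class for domain errors raised by this package."""


class InvalidControlError(PcfretError):
    """A cross-talk control acquisition has a degenerate reference channel."""


class DegenerateSignalError(PcfretError):
    """A ratio denominator is zero or negative where positivity is required."""


class MissingChannelError(PcfretError):
    """An operation needs a channel (typically S_AA) that was not acquired."""


class SwitchState(str, enum.Enum):
    """Photochromic state of the donor at acquisition time."""

    ON = "on"
    OFF = "off"


def _check_intensity(name: str, value: float | None, *, required: bool = True):
    if value is None:
        if required:
            raise MissingChannelError(f"channel {name} is required but absent")
        return None
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise PcfretError(f"channel {name} must be finite and >= 0, got {value}")
    return value


@dataclass(frozen=True)
class FretAcquisition:
    """One timepoint's channel intensities in a given switching state.

    Parameters
    ----------
    s_dd, s_da:
        Donor-excited donor and acceptor emission (photons or counts).
    s_aa:
        Acceptor-excited acceptor emission; may be ``None`` because it is
        acquired at a reduced cadence (it varies slowly, being affected
        only by photodestruction).  Use :func:`interpolate_saa` to fill
        missing timepoints before cross-talk correction with ``delta > 0``.
    state:
        ``SwitchState.ON`` or ``SwitchState.OFF``.
    time:
        Acquisition time in seconds, optional.
    """

    s_dd: float
    s_da: float
    s_aa: float | None = None
    state: SwitchState = SwitchState.ON
    time: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "s_dd", _check_intensity("s_dd", self.s_dd))
        object.__setattr__(self, "s_da", _check_intensity("s_da", self.s_da))
        object.__setattr__(
            self, "s_aa", _check_intensity("s_aa", self.s_aa, required=False)
        )
        object.__setattr__(self, "state", SwitchState(self.state))


@dataclass(frozen=True)
class CorrectionFactors:
    """Cross-talk and brightness factors linking raw signals to efficiency.

    ``alpha`` is donor bleed-through into the acceptor channel, ``delta``
    direct acceptor cross-excitation, ``gamma`` the acceptor/donor
    brightness-and-collection factor.  ``gamma`` is never estimated
    internally: it comes from spectra or control experiments and is a
    required input (default 1.0 at the configuration layer).
    """

    alpha: float = 0.0
    delta: float = 0.0
    gamma: float = 1.0

    def __post_init__(self):
        for name in ("alpha", "delta"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise PcfretError(f"{name} must be finite and >= 0, got {v}")
        if not math.isfinite(self.gamma) or self.gamma <= 0:
            raise PcfretError(f"gamma must be finite and > 0, got {self.gamma}")


@dataclass(frozen=True)
class FretMetrics:
    """Derived FRET quantities for one acquisition.

    ``theta`` is clipped to [0, 1]; ``f_c`` keeps its raw (possibly
    negative) value so that noise propagates without bias into downstream
    fits.  ``clipped`` records whether clipping was applied.
    """

    r: float
    f_c: float
    r_c: float
    theta: float
    clipped: bool = False


def estimate_crosstalk(
    donor_only: FretAcquisition,
    acceptor_only: FretAcquisition,
    gamma: float = 1.0,
) -> CorrectionFactors:
    """Estimate ``alpha`` and ``delta`` from single-fluorophore controls.

    ``alpha = S_DA / S_DD`` of a donor-only sample and
    ``delta = S_DA / S_AA`` of an acceptor-only sample.  ``gamma`` passes
    through unchanged; it cannot be derived from these controls.
    """
    if donor_only.s_dd <= 0:
        raise InvalidControlError(
            "donor-only control has s_dd <= 0; cannot estimate alpha"
        )
    if donor_only.s_da < 0:
        raise InvalidControlError("donor-only control has negative s_da")
    if acceptor_only.s_aa is None or acceptor_only.s_aa <= 0:
        raise InvalidControlError(
            "acceptor-only control has s_aa absent or <= 0; cannot estimate delta"
        )
    alpha = donor_only.s_da / donor_only.s_dd
    delta = acceptor_only.s_da / acceptor_only.s_aa
    return CorrectionFactors(alpha=alpha, delta=delta, gamma=gamma)


def emission_ratio(acq: FretAcquisition) -> float:
    """Raw emission ratio ``R = S_DA / S_DD``."""
    if acq.s_dd <= 0:
        raise DegenerateSignalError("emission ratio undefined for s_dd <= 0")
    return acq.s_da / acq.s_dd


def sensitized_emission(acq: FretAcquisition, cf: CorrectionFactors) -> float:
    """Cross-talk-corrected acceptor emission ``F_c = S_DA - a S_DD - d S_AA``.

    May be negative under noise; the value is reported as-is and any
    clipping is the caller's policy (see :func:`fret_metrics`).
    """
    if cf.delta > 0 and acq.s_aa is None:
        raise MissingChannelError(
            "s_aa required for sensitized emission when delta > 0"
        )
    s_aa = acq.s_aa if acq.s_aa is not None else 0.0
    return acq.s_da - cf.alpha * acq.s_dd - cf.delta * s_aa


def sensitized_ratio(f_c: float, s_dd: float) -> float:
    """Sensitized emission ratio ``R_c = F_c / S_DD``."""
    if s_dd <= 0:
        raise DegenerateSignalError("sensitized ratio undefined for s_dd <= 0")
    return f_c / s_dd


def fret_efficiency(f_c: float, s_dd: float, gamma: float) -> float:
    """Absolute FRET efficiency ``theta = 1 / (gamma S_DD / F_c + 1)``.

    Nonpositive ``f_c`` (possible under noise) maps to ``theta = 0``;
    callers needing to know whether clipping occurred should use
    :func:`fret_metrics`.
    """
    if s_dd <= 0:
        raise DegenerateSignalError("FRET efficiency undefined for s_dd <= 0")
    if gamma <= 0:
        raise PcfretError(f"gamma must be > 0, got {gamma}")
    if f_c <= 0:
        return 0.0
    return 1.0 / (gamma * s_dd / f_c + 1.0)


def fc_from_theta(theta: float, s_dd: float, gamma: float) -> float:
    """Inverse map of :func:`fret_efficiency`: ``F_c = S_DD g theta/(1-theta)``.

    Used by the simulator and the unmixing solver; ``theta`` must lie in
    [0, 1).
    """
    theta = float(theta)
    if not 0.0 <= theta < 1.0:
        raise PcfretError(f"theta must lie in [0, 1), got {theta}")
    return s_dd * gamma * theta / (1.0 - theta)


def fret_metrics(acq: FretAcquisition, cf: CorrectionFactors) -> FretMetrics:
    """Compute all derived FRET quantities for a single acquisition."""
    r = emission_ratio(acq)
    f_c = sensitized_emission(acq, cf)
    r_c = sensitized_ratio(f_c, acq.s_dd)
    clipped = f_c <= 0
    theta = fret_efficiency(f_c, acq.s_dd, cf.gamma)
    if theta > 1.0:  # pragma: no cover - unreachable for finite inputs
        theta, clipped = 1.0, True
    return FretMetrics(r=r, f_c=f_c, r_c=r_c, theta=theta, clipped=clipped)


def interpolate_saa(
    times: np.ndarray, saa: np.ndarray
) -> np.ndarray:
    """Fill missing S_AA timepoints by linear interpolation.

    S_AA is acquired at a reduced cadence because it varies slowly
    (photodestruction only).  Missing entries are NaN; they are filled by
    linear interpolation between measured frames, with nearest-value
    extrapolation at the ends.
    """
    times = np.asarray(times, dtype=float)
    saa = np.asarray(saa, dtype=float)
    if times.shape != saa.shape:
        raise PcfretError("times and saa must have the same shape")
    measured = np.isfinite(saa)
    if not measured.any():
        raise MissingChannelError("no measured S_AA frames to interpolate from")
    return np.interp(times, times[measured], saa[measured])
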
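"""Photoswitching ratios, the FRET-photochromism competition model, and
empirical calibration-curve fitting.

Off-switching light depopulates the fluorescent state of a photochromic
donor.  The photoswitching ratio is the fraction of the original
fluorescence remaining after the off-switching dose:

    rho_D = S_DD,off / S_DD,on          (donor channel)
    rho_A = F_c,off / F_c,on            (acceptor channel, corrected)
          = S_DA,off / S_DA,on          (acceptor channel, raw)

FRET competes with photochromism: energy transferred to the acceptor is
unavailable to drive off-switching, so rho rises with the FRET efficiency
theta.  If off-switching is governed by an intrinsic quantum yield and a
single species is present, the dependence is the power law

    rho(theta) = rho0 ** (1 - theta)

with ``rho0`` the ratio measured absent FRET.  Real biosensors (two
interconverting species, multi-exponential donor photophysics) need an
empirical calibration instead; a double-exponential or straight line fit
by orthogonal distance regression covers the cases seen in practice.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore", DeprecationWarning)
    from scipy import odr as _odr

from .fret_core import (
    CorrectionFactors,
    DegenerateSignalError,
    FretAcquisition,
    PcfretError,
    SwitchState,
    sensitized_emission,
)

__all__ = [
    "RhoMode",
    "CalibrationKind",
    "Abscissa",
    "Channel",
    "PhotoswitchingRatios",
    "CalibrationModel",
    "FitFailureError",
    "photoswitching_ratios",
    "rho_from_theta_power",
    "fit_calibration",
    "evaluate_calibration",
]

# rho slightly above 1 is tolerated as noise; beyond this it is flagged
RHO_NOISE_CEILING = 1.05


class RhoMode(str, enum.Enum):
    CORRECTED = "corrected"  # F_c-based, needs correction factors
    RAW = "raw"  # S_DA-based


class CalibrationKind(str, enum.Enum):
    POWER_LAW = "power_law"
    DOUBLE_EXPONENTIAL = "double_exponential"
    LINEAR = "linear"


class Abscissa(str, enum.Enum):
    """Which FRET metric a calibration is expressed against."""

    THETA = "theta"
    RATIO = "ratio"  # (sensitized) emission ratio


class Channel(str, enum.Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"


class FitFailureError(PcfretError):
    """A calibration or baseline fit failed to converge."""


@dataclass(frozen=True)
class PhotoswitchingRatios:
    rho_d: float
    rho_a: float
    rho_a_mode: RhoMode
    flagged: bool = False  # rho above the noise ceiling

    def __post_init__(self):
        for name in ("rho_d", "rho_a"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise PcfretError(f"{name} must be finite and > 0, got {v}")


def photoswitching_ratios(
    on: FretAcquisition,
    off: FretAcquisition,
    cf: CorrectionFactors | None = None,
) -> PhotoswitchingRatios:
    """Compute rho_D and rho_A from a paired on/off acquisition.

    With correction factors, rho_A is based on the sensitized emission
    F_c (mode ``corrected``); otherwise on the raw S_DA (mode ``raw``).
    Either mode is valid as long as it is used consistently downstream.
    """
    if on.state is not SwitchState.ON or off.state is not SwitchState.OFF:
        raise PcfretError("photoswitching_ratios needs one ON and one OFF acquisition")
    if on.s_dd <= 0:
        raise DegenerateSignalError("on-state s_dd must be > 0")
    rho_d = off.s_dd / on.s_dd
    if cf is not None:
        num = sensitized_emission(off, cf)
        den = sensitized_emission(on, cf)
        mode = RhoMode.CORRECTED
    else:
        num, den = off.s_da, on.s_da
        mode = RhoMode.RAW
    if den <= 0 or num <= 0:
        raise DegenerateSignalError(
            f"nonpositive acceptor-channel signal in rho_A ({mode.value} mode)"
        )
    rho_a = num / den
    flagged = rho_d > RHO_NOISE_CEILING or rho_a > RHO_NOISE_CEILING
    return PhotoswitchingRatios(rho_d=rho_d, rho_a=rho_a, rho_a_mode=mode, flagged=flagged)


def rho_from_theta_power(theta, rho0: float):
    """Competition power law ``rho = rho0 ** (1 - theta)``.

    At ``theta = 0`` no transfer competes and ``rho = rho0``; at
    ``theta = 1`` all excitations transfer, off-switching is fully
    suppressed and ``rho = 1``.  In the single-species regime the donor
    and acceptor channels share this ratio (acceptor emission is
    proportional to the donor on-state population).
    """
    if not (math.isfinite(rho0) and 0 < rho0 <= 1):
        raise PcfretError(f"rho0 must lie in (0, 1], got {rho0}")
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise PcfretError("theta must lie in [0, 1]")
    out = rho0 ** (1.0 - theta)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Calibration models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted map from a FRET metric to a photoswitching ratio.

    ``params`` by kind: power_law ``{rho0}``; double_exponential
    ``{a1, k1, a2, k2}`` for ``a1 exp(-k1 x) + a2 exp(-k2 x)``; linear
    ``{m, q}`` for ``m x + q``.  ``valid_range`` is the convex hull of
    the fitted abscissa values; evaluation outside it clamps to the
    nearest endpoint (flag available via ``evaluate(..., return_flag=True)``).
    """

    kind: CalibrationKind
    params: dict[str, float]
    channel: Channel
    valid_range: tuple[float, float]
    abscissa: Abscissa = Abscissa.THETA
    residual_norm: float | None = None
    _required = {
        CalibrationKind.POWER_LAW: ("rho0",),
        CalibrationKind.DOUBLE_EXPONENTIAL: ("a1", "k1", "a2", "k2"),
        CalibrationKind.LINEAR: ("m", "q"),
    }

    def __post_init__(self):
        object.__setattr__(self, "kind", CalibrationKind(self.kind))
        object.__setattr__(self, "channel", Channel(self.channel))
        object.__setattr__(self, "abscissa", Abscissa(self.abscissa))
        lo, hi = self.valid_range
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
            raise PcfretError(f"invalid valid_range {self.valid_range}")
        object.__setattr__(self, "valid_range", (float(lo), float(hi)))
        missing = [k for k in self._required[self.kind] if k not in self.params]
        if missing:
            raise PcfretError(f"{self.kind.value} calibration missing params {missing}")
        if self.kind is CalibrationKind.POWER_LAW:
            rho0 = self.params["rho0"]
            if not 0 < rho0 <= 1:
                raise PcfretError(f"power_law rho0 must lie in (0, 1], got {rho0}")

    def evaluate(self, x, return_flag: bool = False):
        """Evaluate rho at metric value(s) ``x``, clamping to valid_range."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.valid_range
        out_of_range = (x < lo) | (x > hi)
        xc = np.clip(x, lo, hi)
        p = self.params
        if self.kind is CalibrationKind.POWER_LAW:
            val = p["rho0"] ** (1.0 - xc)
        elif self.kind is CalibrationKind.DOUBLE_EXPONENTIAL:
            val = p["a1"] * np.exp(-p["k1"] * xc) + p["a2"] * np.exp(-p["k2"] * xc)
        else:
            val = p["m"] * xc + p["q"]
        if val.ndim == 0:
            val = float(val)
            flag = bool(out_of_range)
        else:
            flag = out_of_range
        return (val, flag) if return_flag else val

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "params": dict(self.params),
            "channel": self.channel.value,
            "valid_range": list(self.valid_range),
            "abscissa": self.abscissa.value,
            "residual_norm": self.residual_norm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            kind=CalibrationKind(d["kind"]),
            params={k: float(v) for k, v in d["params"].items()},
            channel=Channel(d["channel"]),
            valid_range=tuple(d["valid_range"]),
            abscissa=Abscissa(d.get("abscissa", "theta")),
            residual_norm=d.get("residual_norm"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "CalibrationModel":
        return cls.from_dict(json.loads(s))


def evaluate_calibration(model: CalibrationModel, x, return_flag: bool = False):
    """Functional alias for :meth:`CalibrationModel.evaluate`."""
    return model.evaluate(x, return_flag=return_flag)


# --- ODR fitting -----------------------------------------------------------

_N_STARTS = 5  # multi-start count for the double-exponential fit
_START_SEED = 20210331


def _odr_fit(fcn, beta0, x, y, **kwargs):
    data = _odr.Data(x, y)
    model = _odr.Model(fcn)
    solver = _odr.ODR(data, model, beta0=beta0, **kwargs)
    out = solver.run()
    # ODRPACK info < 4 signals convergence (1-3); >= 4 is an error state
    if out.info >= 4:
        raise FitFailureError(
            f"orthogonal distance regression did not converge: {out.stopreason}"
        )
    return out


def fit_calibration(
    thetas,
    rhos,
    kind: CalibrationKind | str,
    channel: Channel | str = Channel.DONOR,
    abscissa: Abscissa | str = Abscissa.THETA,
) -> CalibrationModel:
    """Fit a calibration curve rho(metric) by orthogonal distance regression.

    Orthogonal (errors-in-both-variables) regression is appropriate here
    because the abscissa is itself a measured FRET metric, not a
    controlled variable.  Equal x/y error scales are assumed (no per-point
    uncertainties).  The double-exponential fit constrains both
    amplitudes to be nonnegative (fitted on a log scale) and uses 5
    deterministic multi-starts, keeping the lowest-residual solution.
    """
    kind = CalibrationKind(kind)
    x = np.asarray(thetas, dtype=float)
    y = np.asarray(rhos, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PcfretError("thetas and rhos must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise PcfretError("calibration data must be finite")
    min_pts = {
        CalibrationKind.LINEAR: 2,
        CalibrationKind.POWER_LAW: 2,
        CalibrationKind.DOUBLE_EXPONENTIAL: 5,
    }[kind]
    if x.size < min_pts:
        raise PcfretError(
            f"{kind.value} calibration needs >= {min_pts} points, got {x.size}"
        )

    if kind is CalibrationKind.LINEAR:
        b0 = np.polyfit(x, y, 1)
        out = _odr_fit(lambda B, t: B[0] * t + B[1], b0, x, y)
        params = {"m": float(out.beta[0]), "q": float(out.beta[1])}
        resid = float(out.sum_square)
    elif kind is CalibrationKind.POWER_LAW:
        rho0_0 = float(np.clip(np.min(y), 1e-6, 1.0))
        out = _odr_fit(lambda B, t: B[0] ** (1.0 - t), [rho0_0], x, y)
        rho0 = float(np.clip(out.beta[0], 1e-12, 1.0))
        params = {"rho0": rho0}
        resid = float(out.sum_square)
    else:  # double exponential with nonnegative amplitudes
        def fcn(B, t):
            e1 = np.clip(B[0] - B[1] * t, -700, 700)
            e2 = np.clip(B[2] - B[3] * t, -700, 700)
            return np.exp(e1) + np.exp(e2)

        rng = np.random.default_rng(_START_SEED)
        ymean = max(float(np.mean(np.abs(y))), 1e-12)
        best = None
        for _ in range(_N_STARTS):
            la = np.log(ymean * rng.uniform(0.2, 0.8, size=2))
            ks = rng.uniform(-3.0, 3.0, size=2)
            beta0 = [la[0], ks[0], la[1], ks[1]]
            try:
                out = _odr_fit(fcn, beta0, x, y, maxit=200)
            except FitFailureError:
                continue
            if best is None or out.sum_square < best.sum_square:
                best = out
        if best is None:
            raise FitFailureError(
                "double-exponential calibration failed for all starts"
            )
        b = best.beta
        params = {
            "a1": float(np.exp(b[0])),
            "k1": float(b[1]),
            "a2": float(np.exp(b[2])),
            "k2": float(b[3]),
        }
        resid = float(best.sum_square)

    return CalibrationModel(
        kind=kind,
        params=params,
        channel=Channel(channel),
        valid_range=(float(np.min(x)), float(np.max(x))),
        abscissa=Abscissa(abscissa),
        residual_norm=resid,
    )
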
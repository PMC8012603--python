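"""Per-cell time-lapse analysis of biosensor responses.

Pipeline: ROI-averaged intensities with background subtraction ->
photobleaching baseline correction -> percent-increase responses ->
per-interval response metrics (maximal response, onset time) -> k-means
classification of cellular response profiles.

Photobleaching makes both FRET-efficiency and intensity traces decay
slowly.  FRET traces are fitted over their full length with a decaying
exponential times a sigmoidal stimulus response,

    theta(t) = exp(-t / tau) * (b + A / (1 + exp((t0 - t) / r)))

whose baseline is ``b * exp(-t / tau)`` (tau is typically much longer
than the experiment).  Intensity traces (e.g. a calcium sensor with
repeated transients) are instead fitted with a bi-exponential restricted
to user-designated quiet intervals.  Responses are then

    % Increase(t) = (signal(t) - baseline(t)) / baseline(t) * 100

Onset times come from a sigmoidal fit (time at which the fit reaches
7.6% of its maximum) or from the argmax of the smoothed second
derivative, as appropriate for sigmoidal versus transient responses.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .fret_core import PcfretError
from .photochromism import FitFailureError

__all__ = [
    "ONSET_FRACTION",
    "BaselineKind",
    "OnsetMethod",
    "CellTrace",
    "BaselineFit",
    "extract_roi_traces",
    "fit_baseline",
    "percent_increase",
    "max_response",
    "onset_time",
    "cluster_responses",
]

# onset threshold: response reaches this fraction of the fitted maximum
ONSET_FRACTION = 0.076


class BaselineKind(str, enum.Enum):
    SIGMOID_EXP = "sigmoid_exp"
    BIEXPONENTIAL = "biexponential"


class OnsetMethod(str, enum.Enum):
    SIGMOID_7P6 = "sigmoid_7p6"
    SECOND_DERIVATIVE = "second_derivative"


@dataclass
class CellTrace:
    """A time-indexed metric for one ROI.

    ``flags`` marks timepoints where a correction intervened (e.g.
    background subtraction floored a negative intensity at zero).
    """

    time: np.ndarray
    values: np.ndarray
    roi_id: str = ""
    flags: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.values.shape:
            raise PcfretError("time and values must be 1-D arrays of equal length")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise PcfretError("time must be strictly increasing")
        if self.flags is None:
            self.flags = np.zeros(self.time.size, dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.time.shape:
                raise PcfretError("flags must match time in length")

    def __len__(self) -> int:
        return self.time.size


def extract_roi_traces(
    stack: np.ndarray,
    rois: np.ndarray,
    background_roi: np.ndarray,
    times: Sequence[float] | None = None,
) -> dict[int, CellTrace]:
    """Per-ROI mean intensities with per-frame background subtraction.

    ``stack`` is a (T, H, W) image time series, ``rois`` an integer label
    image (0 = unassigned), ``background_roi`` a boolean mask of a region
    outside the cells.  Each trace is the ROI-mean intensity minus the
    frame's background-ROI mean; negative results are floored at 0 and
    flagged.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise PcfretError(f"stack must be (T, H, W), got shape {stack.shape}")
    if not np.all(np.isfinite(stack)):
        raise PcfretError("stack contains non-finite frames")
    rois = np.asarray(rois)
    background_roi = np.asarray(background_roi, dtype=bool)
    if rois.shape != stack.shape[1:] or background_roi.shape != stack.shape[1:]:
        raise PcfretError("ROI masks must match the image shape")
    if not background_roi.any():
        raise PcfretError("background ROI is empty")
    if (rois[background_roi] > 0).any():
        raise PcfretError("background ROI overlaps a cell ROI")

    t = np.arange(stack.shape[0], dtype=float) if times is None else np.asarray(times, dtype=float)
    if t.size != stack.shape[0]:
        raise PcfretError("times must have one entry per frame")
    bg = stack[:, background_roi].mean(axis=1)

    traces: dict[int, CellTrace] = {}
    for label in np.unique(rois):
        if label == 0:
            continue
        mask = rois == label
        if not mask.any():  # pragma: no cover - unique() guarantees presence
            raise PcfretError(f"ROI {label} is empty")
        vals = stack[:, mask].mean(axis=1) - bg
        flags = vals < 0
        traces[int(label)] = CellTrace(
            time=t, values=np.maximum(vals, 0.0), roi_id=str(label), flags=flags
        )
    return traces


# ---------------------------------------------------------------------------
# Baseline correction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaselineFit:
    """A fitted photobleaching baseline with its evaluator."""

    kind: BaselineKind
    params: dict[str, float]
    baseline: Callable[[np.ndarray], np.ndarray]
    residual_norm: float = math.nan

    def __call__(self, t):
        return self.baseline(np.asarray(t, dtype=float))


def _sigmoid_exp(t, tau, b, a, t0, r):
    return np.exp(-t / tau) * (b + a / (1.0 + np.exp((t0 - t) / r)))


def _biexp(t, c1, k1, c2, k2):
    return c1 * np.exp(-k1 * t) + c2 * np.exp(-k2 * t)


def fit_baseline(
    trace: CellTrace,
    kind: BaselineKind | str = BaselineKind.SIGMOID_EXP,
    quiet_intervals: Sequence[tuple[float, float]] | None = None,
) -> BaselineFit:
    """Fit a photobleaching baseline to a trace.

    ``sigmoid_exp`` fits the full trace with the decaying-exponential x
    sigmoid model and returns ``b * exp(-t/tau)`` as the baseline.  The
    decay time tau is bounded below at a tenth of the trace duration to
    exclude degenerate fast decays.  ``biexponential`` fits a
    bi-exponential to the quiet (non-elevated) parts of the trace only,
    designated by ``quiet_intervals`` (half-open, seconds).
    """
    kind = BaselineKind(kind)
    if len(trace) < 8:
        raise PcfretError("baseline fitting needs at least 8 timepoints")
    t, y = trace.time, trace.values
    duration = t[-1] - t[0]

    if kind is BaselineKind.SIGMOID_EXP:
        b0 = float(np.median(y[: max(3, y.size // 10)]))
        a0 = max(float(np.max(y) - b0), 1e-6)
        above = np.nonzero(y > b0 + 0.5 * a0)[0]
        t00 = float(t[above[0]]) if above.size else float(t[t.size // 2])
        p0 = [10.0 * duration, max(b0, 1e-6), a0, t00, duration / 30.0]
        bounds = (
            [duration / 10.0, 0.0, 0.0, t[0] - duration, duration / 1e4],
            [np.inf, np.inf, np.inf, t[-1] + duration, duration],
        )
        try:
            popt, _ = curve_fit(
                _sigmoid_exp, t, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:
            raise FitFailureError(f"sigmoid_exp baseline fit failed: {exc}") from exc
        tau, b, a, t0, r = (float(v) for v in popt)
        resid = float(np.linalg.norm(_sigmoid_exp(t, *popt) - y))
        # responseless traces make A and b degenerate; prefer the reduced
        # pure-decay model when it explains the trace equally well
        try:
            popt0, _ = curve_fit(
                lambda tt, tau_, b_: b_ * np.exp(-tt / tau_), t, y,
                p0=[p0[0], max(float(np.mean(y)), 1e-6)],
                bounds=([duration / 10.0, 0.0], [np.inf, np.inf]),
                maxfev=20000,
            )
            resid0 = float(np.linalg.norm(popt0[1] * np.exp(-t / popt0[0]) - y))
            if resid0 <= resid * (1.0 + 1e-6) + 1e-12:
                tau, b, a = float(popt0[0]), float(popt0[1]), 0.0
                t0, r = float(t[t.size // 2]), duration / 30.0
                resid = resid0
        except (RuntimeError, ValueError):
            pass
        return BaselineFit(
            kind=kind,
            params={"tau": tau, "b": b, "A": a, "t0": t0, "r": r},
            baseline=lambda tt, tau=tau, b=b: b * np.exp(-np.asarray(tt, float) / tau),
            residual_norm=resid,
        )

    if quiet_intervals is None:
        raise PcfretError("biexponential baseline requires quiet_intervals")
    mask = np.zeros(t.size, dtype=bool)
    for start, end in quiet_intervals:
        mask |= (t >= start) & (t < end)
    if mask.sum() < 4:
        raise PcfretError("quiet intervals cover fewer than 4 timepoints")
    tq, yq = t[mask], y[mask]
    y0 = max(float(yq[0]), 1e-6)
    p0 = [0.7 * y0, 1.0 / (10.0 * duration), 0.3 * y0, 1.0 / duration]
    bounds = ([0.0, 0.0, 0.0, 0.0], [np.inf, np.inf, np.inf, np.inf])
    try:
        popt, _ = curve_fit(_biexp, tq, yq, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"biexponential baseline fit failed: {exc}") from exc
    c1, k1, c2, k2 = (float(v) for v in popt)
    resid = float(np.linalg.norm(_biexp(tq, *popt) - yq))
    return BaselineFit(
        kind=kind,
        params={"c1": c1, "k1": k1, "c2": c2, "k2": k2},
        baseline=lambda tt: _biexp(np.asarray(tt, float), c1, k1, c2, k2),
        residual_norm=resid,
    )


def percent_increase(trace: CellTrace, baseline: BaselineFit | Callable) -> CellTrace:
    """Baseline-relative response: (signal - baseline) / baseline * 100."""
    base = baseline(trace.time)
    base = np.asarray(base, dtype=float)
    if np.any(base <= 0):
        raise PcfretError("baseline must be > 0 over the trace domain")
    vals = (trace.values - base) / base * 100.0
    return CellTrace(time=trace.time, values=vals, roi_id=trace.roi_id,
                     flags=trace.flags.copy())


def max_response(response: CellTrace, interval: tuple[float, float]) -> float:
    """Maximum percent increase over the half-open interval [start, end).

    The maximum is taken as-is: an all-negative response yields its
    (negative) maximum, not zero.
    """
    start, end = interval
    mask = (response.time >= start) & (response.time < end)
    if not mask.any():
        raise PcfretError(f"interval [{start}, {end}) contains no timepoints")
    return float(np.max(response.values[mask]))


def _sigmoid(t, a, t0, r):
    return a / (1.0 + np.exp((t0 - t) / r))


def onset_time(
    response: CellTrace,
    method: OnsetMethod | str = OnsetMethod.SIGMOID_7P6,
    smooth_window: int = 5,
) -> float | None:
    """Response onset time in seconds, or None if no rise is detectable.

    ``sigmoid_7p6`` fits A / (1 + exp((t0 - t)/r)) and returns the time
    at which the fit reaches 7.6% of its maximum A, which has the closed
    form t0 - r ln(1/0.076 - 1).  ``second_derivative`` smooths the
    response with a local quadratic (Savitzky-Golay) window and returns
    the time of the maximal second derivative, suited to transient
    (calcium-like) responses.
    """
    method = OnsetMethod(method)
    t, y = response.time, response.values
    if t.size < 4 or np.ptp(y) <= 0:
        return None

    if method is OnsetMethod.SIGMOID_7P6:
        a0 = float(np.max(y) - np.min(y))
        above = np.nonzero(y - np.min(y) > 0.5 * a0)[0]
        t00 = float(t[above[0]]) if above.size else float(np.median(t))
        duration = t[-1] - t[0]
        try:
            popt, _ = curve_fit(
                _sigmoid, t, y, p0=[a0, t00, duration / 30.0],
                bounds=([0.0, t[0] - duration, duration / 1e4],
                        [np.inf, t[-1] + duration, duration]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            return None
        a, t0, r = (float(v) for v in popt)
        if a <= 0:
            return None
        return t0 - r * math.log(1.0 / ONSET_FRACTION - 1.0)

    window = min(smooth_window, y.size if y.size % 2 else y.size - 1)
    if window < 3:
        return None
    smooth = savgol_filter(y, window_length=window, polyorder=2)
    d2 = np.gradient(np.gradient(smooth, t), t)
    return float(t[int(np.argmax(d2))])


def cluster_responses(
    features: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 25,
) -> np.ndarray:
    """Classify cells by k-means on their per-interval maximal responses.

    Features (one row per cell, one column per designated interval and
    sensor) are z-scored per column before clustering.  Labels are
    canonicalized to 1..k by descending cluster size (ties broken by
    first occurrence), so label numbering is stable across runs.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise PcfretError("cluster features must be finite")
    n = x.shape[0]
    if k < 1 or k > n:
        raise PcfretError(f"k must lie in [1, n_cells={n}], got {k}")
    if k == 1:
        return np.ones(n, dtype=int)
    z = StandardScaler().fit_transform(x)
    z = np.nan_to_num(z)  # constant features standardize to 0, not NaN
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(z)
    sizes = np.bincount(raw, minlength=k)
    first_seen = np.array([
        np.nonzero(raw == c)[0][0] if sizes[c] else n for c in range(k)
    ])
    order = np.lexsort((first_seen, -sizes))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return relabel[raw]
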
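"""Separation of spectrally identical FRET pairs by donor photochromism.

When two FRET pairs share absorption and emission bands, the measured
donor- and acceptor-channel signals are sums over the pairs:

    S_DD,on  = S_DD,on,1 + S_DD,on,2
    S_DA,on  = S_DA,on,1 + S_DA,on,2
    S_DD,off = rho_D,1 S_DD,on,1 + rho_D,2 S_DD,on,2
    S_DA,off = rho_A,1 S_DA,on,1 + rho_A,2 S_DA,on,2

With the four photoswitching ratios known, this is a linear system of
four equations in the four per-pair on-state signals and is solved
exactly, channel by channel.  The ratios, however, depend on each pair's
FRET efficiency (the sought-after quantity), so the solver iterates:
evaluate each pair's calibration at the current efficiency estimate,
solve the linear system, recompute the efficiencies from the recovered
signals, and repeat to a fixed point.  Convergence is fast in practice;
oscillating updates are damped.

The same scheme extends to n pairs with n acquisitions per switching
cycle (one "on" plus n-1 progressively off-switched reads); see
:func:`solve_n_component`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fret_core import (
    CorrectionFactors,
    FretAcquisition,
    PcfretError,
    SwitchState,
    fret_efficiency,
    sensitized_emission,
)
from .photochromism import Abscissa, CalibrationModel, RhoMode

__all__ = [
    "PairModel",
    "UnmixResult",
    "UnresolvablePairsError",
    "solve_two_component",
    "solve_n_component",
    "iterative_unmix",
    "unmix_timeseries",
    "SINGULARITY_THRESHOLD",
    "THETA_CEILING",
]

# |rho_1 - rho_2| below this leaves the 2x2 system noise-dominated
SINGULARITY_THRESHOLD = 0.02
# working ceiling on theta inside the loop; keeps the efficiency->signal
# inversion finite
THETA_CEILING = 0.95
# condition-number ceiling for the n-component solve, chosen to match the
# two-component threshold (|drho| = 0.02 at rho ~ 0.3 gives cond ~ 1e2)
DEFAULT_MAX_CONDITION = 1e3

_DAMPING = 0.5


class UnresolvablePairsError(PcfretError):
    """The photoswitching contrast between pairs is too small to invert."""


@dataclass(frozen=True)
class PairModel:
    """Calibrated description of one FRET pair.

    ``donor_cal`` and ``acceptor_cal`` map the pair's FRET metric to its
    donor- and acceptor-channel photoswitching ratios.  ``dark_acceptor``
    marks a pair whose acceptor is non-fluorescent: its acceptor-channel
    contribution is identically zero and its efficiency is not updated
    from sensitized emission.
    """

    pair_id: str
    donor_cal: CalibrationModel
    acceptor_cal: CalibrationModel
    gamma: float = 1.0
    dark_acceptor: bool = False

    def __post_init__(self):
        if not (math.isfinite(self.gamma) and self.gamma > 0):
            raise PcfretError(f"gamma must be finite and > 0, got {self.gamma}")
        if self.donor_cal.abscissa is not self.acceptor_cal.abscissa:
            raise PcfretError(
                "donor and acceptor calibrations must share the same abscissa"
            )

    @property
    def abscissa(self) -> Abscissa:
        return self.donor_cal.abscissa


@dataclass(frozen=True)
class UnmixResult:
    """Per-pair recovered on-state signals and FRET metrics.

    ``s_dd_on`` and ``s_da_on`` hold the exact algebraic solution of the
    linear system, so they always sum to the measured mixed signals (in
    the working acceptor channel, see ``acceptor_channel``).  Negative
    components, possible under noise, are preserved here and clipped to
    zero only where they enter the efficiency update; ``clipped`` records
    the affected pairs.  ``theta`` is the final per-pair FRET efficiency,
    clipped to [0, 1]; it is NaN for dark-acceptor pairs.
    """

    pair_ids: tuple[str, ...]
    s_dd_on: np.ndarray
    s_da_on: np.ndarray
    theta: np.ndarray
    metric: np.ndarray
    iterations: int
    converged: bool
    residual: float
    clipped: tuple[bool, ...]
    acceptor_channel: RhoMode
    time: float | None = None


def solve_two_component(
    s_dd_on: float,
    s_dd_off: float,
    s_da_on: float,
    s_da_off: float,
    rho_d1: float,
    rho_d2: float,
    rho_a1: float,
    rho_a2: float,
    singularity_threshold: float = SINGULARITY_THRESHOLD,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Exact algebraic solution of the two-pair linear system.

    Returns ``((s_dd_on_1, s_dd_on_2), (s_da_on_1, s_da_on_2))``.  Each
    channel is a 2x2 system solved in closed form; no least squares is
    involved, so the components sum to the mixed inputs exactly.
    """
    if abs(rho_d1 - rho_d2) < singularity_threshold:
        raise UnresolvablePairsError(
            f"donor channel near-singular: |rho_d1 - rho_d2| = "
            f"{abs(rho_d1 - rho_d2):.3g} < {singularity_threshold}"
        )
    if abs(rho_a1 - rho_a2) < singularity_threshold:
        raise UnresolvablePairsError(
            f"acceptor channel near-singular: |rho_a1 - rho_a2| = "
            f"{abs(rho_a1 - rho_a2):.3g} < {singularity_threshold}"
        )
    s_dd_1 = (s_dd_off - rho_d2 * s_dd_on) / (rho_d1 - rho_d2)
    s_dd_2 = s_dd_on - s_dd_1
    s_da_1 = (s_da_off - rho_a2 * s_da_on) / (rho_a1 - rho_a2)
    s_da_2 = s_da_on - s_da_1
    return (s_dd_1, s_dd_2), (s_da_1, s_da_2)


def solve_n_component(
    signals: np.ndarray,
    rho_vectors: np.ndarray,
    channel: str = "donor",
    max_condition: float = DEFAULT_MAX_CONDITION,
) -> tuple[np.ndarray, float]:
    """Exact solve of the n-pair system for one channel.

    ``signals`` holds the n acquisitions of one switching cycle (index 0
    the fully on state, then n-1 progressively off-switched reads).
    ``rho_vectors[i, k]`` is pair i's remaining fluorescence fraction at
    acquisition k (so ``rho_vectors[:, 0] == 1``).  Returns the per-pair
    on-state signals and the condition number of the mixing matrix.
    """
    signals = np.asarray(signals, dtype=float)
    rho_vectors = np.asarray(rho_vectors, dtype=float)
    n = signals.size
    if rho_vectors.shape != (n, n):
        raise PcfretError(
            f"need {n} rho-vectors of length {n}, got shape {rho_vectors.shape}"
        )
    # acquisitions are rows, pairs are columns
    mixing = rho_vectors.T
    cond = float(np.linalg.cond(mixing))
    if not np.isfinite(cond) or cond > max_condition:
        raise UnresolvablePairsError(
            f"{channel} channel mixing matrix condition number {cond:.3g} "
            f"exceeds {max_condition:.3g}"
        )
    components = np.linalg.solve(mixing, signals)
    return components, cond


# ---------------------------------------------------------------------------
# Iterative solver
# ---------------------------------------------------------------------------


def _midpoint(model: CalibrationModel) -> float:
    lo, hi = model.valid_range
    return 0.5 * (lo + hi)


def _acceptor_signals(
    on: FretAcquisition, off: FretAcquisition, cf: CorrectionFactors | None
) -> tuple[float, float, RhoMode]:
    """Mixture acceptor-channel signals in the working (raw or corrected) form.

    With correction factors the cross-talk correction is linear, so it
    commutes with the per-pair sum: correcting the mixed S_DA first and
    unmixing the sensitized emission F_c is equivalent to unmixing raw
    signals and correcting per pair.  S_AA is unaffected by donor
    switching; the off acquisition falls back to the on-state S_AA when
    its own was not acquired.
    """
    if cf is None or (cf.alpha == 0 and cf.delta == 0):
        return on.s_da, off.s_da, RhoMode.RAW
    off_use = off
    if off.s_aa is None and on.s_aa is not None:
        off_use = FretAcquisition(
            s_dd=off.s_dd, s_da=off.s_da, s_aa=on.s_aa, state=off.state, time=off.time
        )
    return (
        sensitized_emission(on, cf),
        sensitized_emission(off_use, cf),
        RhoMode.CORRECTED,
    )


def _pair_metric(
    pair: PairModel, s_dd: float, f_c: float
) -> tuple[float, bool]:
    """Current-iterate FRET metric for one pair from its recovered signals.

    Negative recovered intensities are clipped to zero here (and flagged)
    without altering the stored algebraic solution.
    """
    clipped = s_dd < 0 or f_c < 0
    s_dd = max(s_dd, 1e-300)
    f_c = max(f_c, 0.0)
    if pair.abscissa is Abscissa.THETA:
        m = fret_efficiency(f_c, s_dd, pair.gamma)
        m = min(m, THETA_CEILING)
    else:
        m = f_c / s_dd
    return m, clipped


def iterative_unmix(
    on: FretAcquisition,
    off: FretAcquisition,
    pairs: tuple[PairModel, PairModel],
    cf: CorrectionFactors | None = None,
    metric_init: tuple[float, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    singularity_threshold: float = SINGULARITY_THRESHOLD,
) -> UnmixResult:
    """Fixed-point unmixing of two pairs from one paired on/off acquisition.

    Each iteration (i) evaluates every pair's donor and acceptor
    calibration at its current metric value to obtain rho_D and rho_A,
    (ii) solves the two-pair linear system exactly, and (iii) recomputes
    the metric from the recovered signals.  The loop stops when the
    largest metric change falls below ``tol``; if the update direction
    alternates, a damping factor of 0.5 is applied.  Non-convergence is
    reported in the result (``converged=False``), not raised.
    """
    if len(pairs) != 2:
        raise PcfretError("iterative_unmix separates exactly two pairs")
    if on.state is not SwitchState.ON or off.state is not SwitchState.OFF:
        raise PcfretError("iterative_unmix needs one ON and one OFF acquisition")
    p1, p2 = pairs
    da_on, da_off, acc_mode = _acceptor_signals(on, off, cf)

    if metric_init is None:
        metric = np.array([_midpoint(p1.donor_cal), _midpoint(p2.donor_cal)])
    else:
        metric = np.asarray(metric_init, dtype=float).copy()

    prev_delta = np.zeros(2)
    clipped = [False, False]
    components_dd = np.zeros(2)
    components_da = np.zeros(2)
    converged = False
    residual = math.inf
    iterations = 0

    for iterations in range(1, max_iter + 1):
        rho_d = np.array([p.donor_cal.evaluate(m) for p, m in zip(pairs, metric)])
        rho_a = np.array([p.acceptor_cal.evaluate(m) for p, m in zip(pairs, metric)])

        dark = [p.dark_acceptor for p in pairs]
        if any(dark):
            if all(dark):
                raise UnresolvablePairsError(
                    "both pairs have dark acceptors; no acceptor-channel signal"
                )
            if abs(rho_d[0] - rho_d[1]) < singularity_threshold:
                raise UnresolvablePairsError(
                    "donor channel near-singular for dark-acceptor unmixing"
                )
            s1 = (off.s_dd - rho_d[1] * on.s_dd) / (rho_d[0] - rho_d[1])
            components_dd = np.array([s1, on.s_dd - s1])
            lit = 0 if dark[1] else 1
            components_da = np.zeros(2)
            components_da[lit] = da_on
        else:
            (dd1, dd2), (a1, a2) = solve_two_component(
                on.s_dd, off.s_dd, da_on, da_off,
                rho_d[0], rho_d[1], rho_a[0], rho_a[1],
                singularity_threshold=singularity_threshold,
            )
            components_dd = np.array([dd1, dd2])
            components_da = np.array([a1, a2])

        new_metric = metric.copy()
        for i, pair in enumerate(pairs):
            if pair.dark_acceptor:
                continue  # efficiency not observable from sensitized emission
            m, clip = _pair_metric(pair, components_dd[i], components_da[i])
            new_metric[i] = m
            clipped[i] = clipped[i] or clip

        delta = new_metric - metric
        # damp oscillating updates (sign alternated on both of the last steps)
        osc = (delta * prev_delta) < 0
        delta[osc] *= _DAMPING
        metric = metric + delta
        prev_delta = delta
        residual = float(np.max(np.abs(delta)))
        if residual < tol:
            converged = True
            break

    theta = np.empty(2)
    for i, pair in enumerate(pairs):
        if pair.dark_acceptor:
            theta[i] = math.nan
        elif pair.abscissa is Abscissa.THETA:
            theta[i] = float(np.clip(metric[i], 0.0, 1.0))
        else:
            s_dd = max(components_dd[i], 1e-300)
            f_c = max(components_da[i], 0.0)
            theta[i] = fret_efficiency(f_c, s_dd, pair.gamma)

    return UnmixResult(
        pair_ids=(p1.pair_id, p2.pair_id),
        s_dd_on=components_dd,
        s_da_on=components_da,
        theta=theta,
        metric=metric,
        iterations=iterations,
        converged=converged,
        residual=residual,
        clipped=tuple(clipped),
        acceptor_channel=acc_mode,
        time=on.time,
    )


def unmix_timeseries(
    trace: list[tuple[FretAcquisition, FretAcquisition]],
    pairs: tuple[PairModel, PairModel],
    cf: CorrectionFactors | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> list[UnmixResult]:
    """Unmix a time series of paired acquisitions with warm starts.

    The first timepoint starts from the calibration-range midpoints; each
    subsequent timepoint starts from the previous solution, which both
    speeds convergence and stabilizes the trace.  Per-timepoint solver
    flags propagate into the returned results.
    """
    results: list[UnmixResult] = []
    metric_init = None
    for on, off in trace:
        res = iterative_unmix(
            on, off, pairs, cf=cf, metric_init=metric_init,
            tol=tol, max_iter=max_iter,
        )
        results.append(res)
        metric_init = tuple(res.metric)
    return results
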
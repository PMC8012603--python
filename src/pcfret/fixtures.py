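"""Synthetic data generation for end-to-end validation.

The image fixture emulates a two-pair photochromic FRET time-lapse: per
timepoint one "on" and one "off" acquisition in the donor and acceptor
channels (the alternating violet/blue irradiation scheme), cells laid
out as rectangular ROIs over a uniform background, per-pair FRET
trajectories planted as step responses, brightness decaying with a
photobleaching time constant, and optional per-pixel Poisson noise.
Planted ground truth is stored alongside the stacks so recovery can be
asserted exactly.

Trace-level generators produce photobleaching-times-sigmoid FRET traces
and planted response-class feature sets for the time-lapse pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fret_core import PcfretError
from .simulation import PairSimSpec, expected_signals
from .timelapse import CellTrace

__all__ = [
    "FixtureSpec",
    "FixtureData",
    "generate_fixture",
    "write_fixture",
    "load_fixture",
    "default_trajectories",
    "synthetic_response_trace",
    "planted_response_classes",
]

_CHANNELS = ("s_dd_on", "s_dd_off", "s_da_on", "s_da_off")


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry, planted trajectories and noise model of an image fixture.

    ``trajectories`` has shape (n_cells, 2, n_timepoints) giving each
    cell's per-pair FRET efficiency over time; ``None`` generates
    deterministic step responses (see :func:`default_trajectories`).
    ``bleach_tau`` (seconds) scales brightness by exp(-t/tau);
    ``background`` is a uniform per-pixel offset present in every frame.
    """

    shape: tuple[int, int] = (48, 64)
    n_cells: int = 4
    pairs: tuple[PairSimSpec, PairSimSpec] = (
        PairSimSpec(brightness_n=4000.0, rho0=0.3),
        PairSimSpec(brightness_n=4000.0, rho0=1.0),
    )
    n_timepoints: int = 30
    dt: float = 30.0
    trajectories: np.ndarray | None = None
    bleach_tau: float = math.inf
    background: float = 20.0
    noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise PcfretError("n_cells must be >= 0")
        if self.n_timepoints < 1:
            raise PcfretError("n_timepoints must be >= 1")
        if self.bleach_tau <= 0:
            raise PcfretError("bleach_tau must be > 0")
        if self.trajectories is not None:
            traj = np.asarray(self.trajectories, dtype=float)
            if traj.shape != (self.n_cells, 2, self.n_timepoints):
                raise PcfretError(
                    "trajectories must have shape (n_cells, 2, n_timepoints)"
                )
            if np.any((traj < 0) | (traj >= 1)):
                raise PcfretError("planted theta must lie in [0, 1)")
            object.__setattr__(self, "trajectories", traj)


@dataclass
class FixtureData:
    """Generated stacks, masks, and planted ground truth."""

    stacks: dict[str, np.ndarray]  # (T, H, W) per channel/state
    rois: np.ndarray  # integer labels, 0 = unassigned
    background_mask: np.ndarray  # boolean, disjoint from ROIs
    times: np.ndarray  # seconds
    truth: pd.DataFrame  # columns cell, time_s, theta1, theta2


def default_trajectories(spec: FixtureSpec) -> np.ndarray:
    """Deterministic planted step responses.

    Each cell gets distinct baseline efficiencies; pair 1 steps up at a
    third of the experiment, pair 2 at two thirds, mimicking sequential
    stimulation of two pathways.
    """
    t_idx = np.arange(spec.n_timepoints)
    traj = np.empty((spec.n_cells, 2, spec.n_timepoints))
    for c in range(spec.n_cells):
        base1 = 0.05 + 0.04 * (c % 5)
        base2 = 0.10 + 0.03 * (c % 4)
        step1 = 0.20 * (t_idx >= spec.n_timepoints // 3)
        step2 = 0.15 * (t_idx >= (2 * spec.n_timepoints) // 3)
        traj[c, 0] = base1 + step1
        traj[c, 1] = base2 + step2
    return traj


def _layout_rois(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular cell ROIs on a grid, background strip along the top."""
    h, w = spec.shape
    rois = np.zeros((h, w), dtype=np.uint16)
    background = np.zeros((h, w), dtype=bool)
    background[1:5, 1 : w - 1] = True
    if spec.n_cells == 0:
        return rois, background
    cols = int(math.ceil(math.sqrt(spec.n_cells)))
    rows = int(math.ceil(spec.n_cells / cols))
    top, margin = 7, 2
    cell_h = (h - top - margin) // rows - margin
    cell_w = (w - 2 * margin) // cols - margin
    if cell_h < 2 or cell_w < 2:
        raise PcfretError(f"image {spec.shape} too small for {spec.n_cells} cells")
    for c in range(spec.n_cells):
        r, q = divmod(c, cols)
        r0 = top + r * (cell_h + margin)
        c0 = margin + q * (cell_w + margin)
        rois[r0 : r0 + cell_h, c0 : c0 + cell_w] = c + 1
    return rois, background


def generate_fixture(spec: FixtureSpec) -> FixtureData:
    """Render the forward model into image stacks plus ground truth.

    Every ROI pixel carries the cell's expected per-pixel signal (the
    per-pair brightness is interpreted per pixel) plus the uniform
    background; with ``noise=True`` each pixel is an independent Poisson
    draw.  Deterministic for a given seed.
    """
    traj = spec.trajectories if spec.trajectories is not None else default_trajectories(spec)
    rois, background = _layout_rois(spec)
    times = np.arange(spec.n_timepoints) * spec.dt
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)

    expect = {ch: np.full((spec.n_timepoints, h, w), spec.background, dtype=float)
              for ch in _CHANNELS}
    rows = []
    for c in range(spec.n_cells):
        mask = rois == c + 1
        for k, t in enumerate(times):
            decay = math.exp(-t / spec.bleach_tau)
            bleached = tuple(
                PairSimSpec(p.brightness_n * decay, p.rho0, p.gamma)
                for p in spec.pairs
            )
            dd, da = expected_signals(bleached, traj[c, :, k])
            expect["s_dd_on"][k][mask] += dd[:, 0].sum()
            expect["s_dd_off"][k][mask] += dd[:, 1].sum()
            expect["s_da_on"][k][mask] += da[:, 0].sum()
            expect["s_da_off"][k][mask] += da[:, 1].sum()
            rows.append({
                "cell": c + 1, "time_s": t,
                "theta1": traj[c, 0, k], "theta2": traj[c, 1, k],
            })
    if spec.noise:
        stacks = {ch: rng.poisson(expect[ch]).astype(float) for ch in _CHANNELS}
    else:
        stacks = expect
    truth = pd.DataFrame(rows, columns=["cell", "time_s", "theta1", "theta2"])
    return FixtureData(
        stacks=stacks, rois=rois, background_mask=background,
        times=times, truth=truth,
    )


def write_fixture(data: FixtureData, outdir) -> dict[str, Path]:
    """Write stacks as multi-page TIFF plus ROI/background masks and truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ch, stack in data.stacks.items():
        p = outdir / f"{ch}.tif"
        tifffile.imwrite(p, stack.astype(np.float32), photometric="minisblack")
        paths[ch] = p
    paths["rois"] = outdir / "rois.tif"
    tifffile.imwrite(paths["rois"], data.rois.astype(np.uint16),
                     photometric="minisblack")
    paths["background"] = outdir / "background.tif"
    tifffile.imwrite(paths["background"],
                     data.background_mask.astype(np.uint8),
                     photometric="minisblack")
    paths["truth"] = outdir / "ground_truth.csv"
    data.truth.to_csv(paths["truth"], index=False)
    paths["times"] = outdir / "times.csv"
    pd.DataFrame({"time_s": data.times}).to_csv(paths["times"], index=False)
    return paths


def load_fixture(outdir) -> FixtureData:
    outdir = Path(outdir)
    stacks = {ch: tifffile.imread(outdir / f"{ch}.tif").astype(float)
              for ch in _CHANNELS}
    # a single-frame stack reads back as 2-D
    stacks = {ch: s[None] if s.ndim == 2 else s for ch, s in stacks.items()}
    return FixtureData(
        stacks=stacks,
        rois=tifffile.imread(outdir / "rois.tif"),
        background_mask=tifffile.imread(outdir / "background.tif").astype(bool),
        times=pd.read_csv(outdir / "times.csv")["time_s"].to_numpy(dtype=float),
        truth=pd.read_csv(outdir / "ground_truth.csv"),
    )


# ---------------------------------------------------------------------------
# Trace-level fixtures
# ---------------------------------------------------------------------------


def synthetic_response_trace(
    times,
    tau: float = 1e4,
    b: float = 0.2,
    amplitude: float = 0.1,
    t0: float = 600.0,
    r: float = 30.0,
    noise: float = 0.0,
    seed: int = 0,
    roi_id: str = "sim",
) -> CellTrace:
    """A photobleaching-times-sigmoid FRET trace with relative Gaussian noise.

    theta(t) = exp(-t/tau) * (b + amplitude / (1 + exp((t0 - t)/r))),
    multiplied by (1 + noise * N(0, 1)) per sample.
    """
    t = np.asarray(times, dtype=float)
    y = np.exp(-t / tau) * (b + amplitude / (1.0 + np.exp((t0 - t) / r)))
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + noise * rng.standard_normal(t.size))
    return CellTrace(time=t, values=y, roi_id=roi_id)


def planted_response_classes(
    n_per_class: int = 20,
    centers: np.ndarray | None = None,
    spread: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated per-interval response features with planted classes.

    Returns (features, labels); features mimic maximal percent-increase
    responses of three sensors over three designated intervals, labels
    are 1-based planted class assignments.
    """
    if centers is None:
        centers = np.array([
            [80.0, 20.0, 90.0],
            [30.0, 120.0, 85.0],
            [25.0, 15.0, 10.0],
        ])
    centers = np.asarray(centers, dtype=float)
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for i, c in enumerate(centers):
        feats.append(c + spread * rng.standard_normal((n_per_class, c.size)))
        labels.extend([i + 1] * n_per_class)
    return np.vstack(feats), np.asarray(labels, dtype=int)
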
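"""File formats and validated run configuration.

Formats are deliberately plain: per-ROI acquisition tables and traces as
CSV (UTF-8, comma separator, ``.`` decimal), calibration models as JSON,
configuration as YAML.  Time is in seconds everywhere.  Image stacks are
multi-page TIFF, row-major with the origin top-left (see
:mod:`pcfret.fixtures`).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .fret_core import (
    CorrectionFactors,
    FretAcquisition,
    PcfretError,
    SwitchState,
    interpolate_saa,
)
from .photochromism import CalibrationModel
from .simulation import PairSimSpec, StudyCondition
from .unmixing import PairModel

__all__ = [
    "TRACE_COLUMNS",
    "read_trace_csv",
    "write_trace_csv",
    "paired_acquisitions",
    "read_calibration",
    "write_calibration",
    "read_pair_models",
    "write_pair_models",
    "CorrectionConfig",
    "UnmixConfig",
    "StudyConditionConfig",
    "AnalysisConfig",
    "RunConfig",
    "read_config",
]

TRACE_COLUMNS = ("time_s", "state", "s_dd", "s_da", "s_aa")


def read_trace_csv(path) -> pd.DataFrame:
    """Read a per-ROI acquisition table.

    Required columns: ``time_s, state, s_dd, s_da, s_aa``; blank ``s_aa``
    cells become NaN (channel not acquired at that timepoint), never
    zeros.  Raises a located error for missing columns or unparseable
    rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise PcfretError(f"{path}: missing required column(s) {missing}")
    for col in ("time_s", "s_dd", "s_da", "s_aa"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise PcfretError(f"{path}: column {col!r} is not numeric: {exc}") from exc
    bad = ~df["state"].isin(["on", "off"])
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise PcfretError(
            f"{path}: row {row}: state must be 'on' or 'off', "
            f"got {df['state'].iloc[row]!r}"
        )
    return df


def write_trace_csv(df: pd.DataFrame, path) -> None:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise PcfretError(f"cannot write trace: missing column(s) {missing}")
    df.loc[:, list(TRACE_COLUMNS)].to_csv(path, index=False)


def paired_acquisitions(
    df: pd.DataFrame,
) -> list[tuple[FretAcquisition, FretAcquisition]]:
    """Pair each timepoint's on and off rows into acquisition objects.

    Missing S_AA values are filled by linear interpolation over time
    (nearest-value extrapolation at the ends) when at least one S_AA
    frame was measured; otherwise S_AA stays absent throughout.
    """
    ons = df[df["state"] == "on"].sort_values("time_s").reset_index(drop=True)
    offs = df[df["state"] == "off"].sort_values("time_s").reset_index(drop=True)
    if len(ons) != len(offs):
        raise PcfretError(
            f"unpaired acquisitions: {len(ons)} on rows vs {len(offs)} off rows"
        )
    if len(ons) == 0:
        return []

    def fill(sub: pd.DataFrame) -> np.ndarray:
        saa = sub["s_aa"].to_numpy(dtype=float)
        if np.isfinite(saa).all():
            return saa
        if not np.isfinite(saa).any():
            return np.full(saa.size, np.nan)
        return interpolate_saa(sub["time_s"].to_numpy(dtype=float), saa)

    saa_on, saa_off = fill(ons), fill(offs)
    out = []
    for i in range(len(ons)):
        on = FretAcquisition(
            s_dd=ons["s_dd"].iloc[i], s_da=ons["s_da"].iloc[i],
            s_aa=None if not np.isfinite(saa_on[i]) else float(saa_on[i]),
            state=SwitchState.ON, time=float(ons["time_s"].iloc[i]),
        )
        off = FretAcquisition(
            s_dd=offs["s_dd"].iloc[i], s_da=offs["s_da"].iloc[i],
            s_aa=None if not np.isfinite(saa_off[i]) else float(saa_off[i]),
            state=SwitchState.OFF, time=float(offs["time_s"].iloc[i]),
        )
        out.append((on, off))
    return out


def read_calibration(path) -> CalibrationModel:
    return CalibrationModel.from_json(Path(path).read_text())


def write_calibration(model: CalibrationModel, path) -> None:
    Path(path).write_text(model.to_json())


def read_pair_models(path) -> list[PairModel]:
    """Read FRET-pair models (id, gamma, calibrations) from JSON."""
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise PcfretError(f"{path}: expected a JSON list of pair models")
    pairs = []
    for entry in data:
        try:
            pairs.append(PairModel(
                pair_id=entry["pair_id"],
                donor_cal=CalibrationModel.from_dict(entry["donor_cal"]),
                acceptor_cal=CalibrationModel.from_dict(entry["acceptor_cal"]),
                gamma=float(entry.get("gamma", 1.0)),
                dark_acceptor=bool(entry.get("dark_acceptor", False)),
            ))
        except KeyError as exc:
            raise PcfretError(f"{path}: pair model missing key {exc}") from exc
    return pairs


def write_pair_models(pairs: list[PairModel], path) -> None:
    data = [
        {
            "pair_id": p.pair_id,
            "gamma": p.gamma,
            "dark_acceptor": p.dark_acceptor,
            "donor_cal": p.donor_cal.to_dict(),
            "acceptor_cal": p.acceptor_cal.to_dict(),
        }
        for p in pairs
    ]
    Path(path).write_text(json.dumps(data, indent=2))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CorrectionConfig(_StrictModel):
    alpha: float = Field(0.0, ge=0)
    delta: float = Field(0.0, ge=0)
    gamma: float = Field(1.0, gt=0)

    def to_factors(self) -> CorrectionFactors:
        return CorrectionFactors(alpha=self.alpha, delta=self.delta, gamma=self.gamma)


class UnmixConfig(_StrictModel):
    tol: float = Field(1e-6, gt=0)
    max_iter: int = Field(100, ge=1)


class StudyConditionConfig(_StrictModel):
    name: str
    photons: tuple[float, float]
    rho0: tuple[float, float]
    gamma: tuple[float, float] = (1.0, 1.0)
    n_sims: int = Field(5000, ge=0)
    theta_range: tuple[float, float] = (0.0, 0.6)
    noise: bool = True
    extra_reads: int = Field(1, ge=1)

    def to_condition(self, seed: int) -> StudyCondition:
        return StudyCondition(
            name=self.name,
            pairs=(
                PairSimSpec(self.photons[0], self.rho0[0], self.gamma[0]),
                PairSimSpec(self.photons[1], self.rho0[1], self.gamma[1]),
            ),
            n_sims=self.n_sims,
            theta_range=self.theta_range,
            seed=seed,
            noise=self.noise,
            extra_reads=self.extra_reads,
        )


class AnalysisConfig(_StrictModel):
    baseline_kind: Literal["sigmoid_exp", "biexponential"] = "sigmoid_exp"
    onset_method: Literal["sigmoid_7p6", "second_derivative"] = "sigmoid_7p6"
    intervals: dict[str, tuple[float, float]] = {}
    quiet_intervals: list[tuple[float, float]] | None = None
    k_classes: int = Field(3, ge=1)

    @model_validator(mode="after")
    def _check_intervals(self):
        spans = sorted(self.intervals.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 > b0:
                raise ValueError(f"intervals [{a0},{a1}) and [{b0},{b1}) overlap")
        return self


class RunConfig(_StrictModel):
    """Top-level validated configuration for a reproducible run."""

    seed: int
    correction: CorrectionConfig = CorrectionConfig()
    unmix: UnmixConfig = UnmixConfig()
    study: list[StudyConditionConfig] = []
    analysis: AnalysisConfig = AnalysisConfig()


def read_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raise PcfretError(f"{path}: empty configuration")
    return RunConfig.model_validate(raw)
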
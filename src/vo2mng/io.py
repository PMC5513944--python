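"""Delimited-text readers and writers for the pipeline's data products.

All files are comma-separated UTF-8 with a mandatory header row; units
are embedded in the column names (``vo2_ml_min``, ``watts``).  Readers
validate headers and invariants (monotone timestamps, uniform spacing,
two-level protocols) and report offending content.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .freq import GainProfile, HarmonicDecomposition
from .series import BreathSeries, UniformSeries, WorkRateSeries
from .timedomain import ExpFit

__all__ = [
    "BREATH_COLUMNS",
    "SERIES_COLUMNS",
    "PROTOCOL_COLUMNS",
    "read_breaths_csv",
    "write_breaths_csv",
    "read_series_csv",
    "write_series_csv",
    "read_protocol_csv",
    "write_protocol_csv",
    "write_gain_table_csv",
    "write_expfit_json",
    "read_expfit_json",
]

BREATH_COLUMNS = ("t_s", "vo2_ml_min")
SERIES_COLUMNS = ("t_s", "vo2_ml_min")
PROTOCOL_COLUMNS = ("time_s", "watts")


def _read_table(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if tuple(df.columns[: len(columns)]) != columns:
        raise ValueError(
            f"{path}: expected header {list(columns)}, found {list(df.columns)}"
        )
    bad = df[columns[0]].isna() | df[columns[1]].isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    return df


def read_breaths_csv(path: str | Path) -> BreathSeries:
    df = _read_table(path, BREATH_COLUMNS)
    try:
        return BreathSeries(times=df["t_s"].to_numpy(), vo2=df["vo2_ml_min"].to_numpy())
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_breaths_csv(path: str | Path, breaths: BreathSeries) -> None:
    pd.DataFrame({"t_s": breaths.times, "vo2_ml_min": breaths.vo2}).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> UniformSeries:
    df = _read_table(path, SERIES_COLUMNS)
    t = df["t_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dts = np.diff(t)
    if np.any(dts <= 0) or np.max(np.abs(dts - dts[0])) > 1e-6:
        raise ValueError(f"{path}: timestamps are not uniformly increasing")
    return UniformSeries(t0=float(t[0]), dt=float(dts[0]), values=df["vo2_ml_min"].to_numpy())


def write_series_csv(path: str | Path, series: UniformSeries) -> None:
    pd.DataFrame({"t_s": series.times, "vo2_ml_min": series.values}).to_csv(path, index=False)


def read_protocol_csv(path: str | Path, n_periods: int = 1) -> WorkRateSeries:
    df = _read_table(path, PROTOCOL_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    w = df["watts"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dts = np.diff(t)
    if np.any(dts <= 0) or np.max(np.abs(dts - dts[0])) > 1e-6:
        raise ValueError(f"{path}: timestamps are not uniformly increasing")
    levels = np.unique(w)
    if levels.size != 2:
        raise ValueError(f"{path}: expected exactly two work-rate levels, found {levels}")
    return WorkRateSeries(
        dt=float(dts[0]), values=w, n_periods=n_periods,
        low=float(levels[0]), high=float(levels[1]),
    )


def write_protocol_csv(path: str | Path, protocol: WorkRateSeries) -> None:
    pd.DataFrame({"time_s": protocol.times, "watts": protocol.values}).to_csv(path, index=False)


def write_gain_table_csv(
    path: str | Path,
    profile: GainProfile,
    input_dec: HarmonicDecomposition,
    output_dec: HarmonicDecomposition,
) -> None:
    """Per-harmonic table: frequency, amplitudes, gain, normalized gain."""
    h = profile.harmonics
    pd.DataFrame(
        {
            "h": h,
            "freq_hz": h * input_dec.f1,
            "input_amp_w": input_dec.amp[: h.size],
            "output_amp_ml_min": output_dec.amp[: h.size],
            "gain_ml_min_w": profile.gains,
            "normalized_gain_pct": profile.normalized_pct,
        }
    ).to_csv(path, index=False)


def write_expfit_json(path: str | Path, fit: ExpFit) -> None:
    Path(path).write_text(json.dumps(asdict(fit), indent=2) + "\n")


def read_expfit_json(path: str | Path) -> ExpFit:
    return ExpFit(**json.loads(Path(path).read_text()))
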
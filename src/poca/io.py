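"""Domain containers and plain-text readers/writers.

A recording is a delimited numeric table (first column ``time_s``, one
column per channel) plus a YAML sidecar declaring the sampling rate, the
channel roles (e.g. lL2/rL2/lL5/rL5) and the stimulation window.  Peak
tables and rhythm reports are CSV; models and metrics are JSON.  All
round-trips are lossless to double precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .config import PEAK_FEATURES

#: column order of a serialized peak table
PEAK_TABLE_COLUMNS: tuple[str, ...] = (
    ("channel", "peak_index") + PEAK_FEATURES + ("label", "prediction")
)


@dataclass
class Recording:
    """Multichannel extracellular recording.

    ``signal`` has one row per sample and one column per channel; time is
    seconds with t = 0 at the first sample.  ``stim_onset``/``stim_offset``
    are absent (None) when the recording contains no stimulation.
    """

    signal: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    stim_onset: float | None = None
    stim_offset: float | None = None
    protocol_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim == 1:
            self.signal = self.signal[:, None]
        self.channel_names = tuple(self.channel_names)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signal.shape[0] < 2:
            raise ValueError("recording must contain at least 2 samples")
        if self.signal.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match signal columns")
        if self.signal.shape[1] < 1:
            raise ValueError("recording needs at least one channel")
        if (
            self.stim_onset is not None
            and self.stim_offset is not None
            and not self.stim_onset < self.stim_offset
        ):
            raise ValueError("stim_onset must precede stim_offset")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class FilteredRecording(Recording):
    """Recording after resampling/low-pass filtering.

    ``provenance`` records the working rate, cutoff and decimation factors
    that produced it.
    """

    provenance: dict = field(default_factory=dict)


@dataclass
class GroundTruthLabels:
    """Expert (or generator) per-peak labels.

    ``events`` has columns ``channel``, ``time`` (s) and ``label``
    (True = locomotor, False = non-locomotor); times are strictly
    increasing within a channel.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"channel", "time", "label"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"label table missing columns {sorted(missing)}")
        for ch, g in self.events.groupby("channel", sort=False):
            t = g["time"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"label times not strictly increasing in {ch!r}")

    def for_channel(self, channel: str) -> pd.DataFrame:
        return self.events[self.events["channel"] == channel]


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if df.columns[0] != "time_s":
        raise ValueError(
            f"{path}: first column must be 'time_s', found {df.columns[0]!r}"
        )
    bad = df.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        raise ValueError(f"{path}: missing/NaN cell at table row {row}")
    return df


def read_recording(signal_path: str | Path, meta_path: str | Path) -> Recording:
    """Load a delimited signal table and its metadata sidecar.

    The sidecar declares ``fs``, ``channels`` (ordered roles), and
    optionally ``stim_onset``, ``stim_offset`` and ``protocol_id``.  The
    sampling rate inferred from the time column must agree with the
    declared one within 0.1%.
    """
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "fs" not in meta or "channels" not in meta:
        raise ValueError(f"{meta_path}: sidecar must declare 'fs' and 'channels'")
    fs = float(meta["fs"])
    channels = [str(c) for c in meta["channels"]]

    df = _read_table(signal_path)
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{signal_path}: time column is not strictly increasing")
    missing = [c for c in channels if c not in df.columns]
    if missing:
        raise ValueError(f"{signal_path}: channel columns missing: {missing}")

    fs_inferred = (len(t) - 1) / (t[-1] - t[0])
    if abs(fs_inferred - fs) / fs > 1e-3:
        raise ValueError(
            f"fs mismatch: sidecar declares {fs} Hz but time column implies "
            f"{fs_inferred:.6g} Hz"
        )

    stim_onset = meta.get("stim_onset")
    stim_offset = meta.get("stim_offset")
    return Recording(
        signal=df[channels].to_numpy(float),
        fs=fs,
        channel_names=tuple(channels),
        stim_onset=None if stim_onset is None else float(stim_onset),
        stim_offset=None if stim_offset is None else float(stim_offset),
        protocol_id=str(meta.get("protocol_id", "")),
    )


def write_recording(
    rec: Recording, signal_path: str | Path, meta_path: str | Path
) -> None:
    """Write a recording as a signal table + sidecar (inverse of read)."""
    df = pd.DataFrame({"time_s": rec.times})
    for i, name in enumerate(rec.channel_names):
        df[name] = rec.signal[:, i]
    sep = "\t" if Path(signal_path).suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(signal_path, sep=sep, index=False, float_format="%.17g")
    meta: dict = {"fs": float(rec.fs), "channels": list(rec.channel_names)}
    if rec.stim_onset is not None:
        meta["stim_onset"] = float(rec.stim_onset)
    if rec.stim_offset is not None:
        meta["stim_offset"] = float(rec.stim_offset)
    if rec.protocol_id:
        meta["protocol_id"] = rec.protocol_id
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------


def new_peak_table(rows: Sequence[dict] | None = None) -> pd.DataFrame:
    """Empty (or row-filled) peak table with the canonical column layout."""
    df = pd.DataFrame(list(rows) if rows else [], columns=list(PEAK_TABLE_COLUMNS))
    return _coerce_peak_table(df)


def _coerce_peak_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in PEAK_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA if col in ("label", "prediction") else np.nan
    df["channel"] = df["channel"].astype(str)
    df["peak_index"] = df["peak_index"].astype("int64")
    for col in ("StimCK", "FreqCK", "nSynCK"):
        df[col] = df[col].astype(bool)
    for col in ("label", "prediction"):
        df[col] = df[col].astype("boolean")
    ordered = [c for c in PEAK_TABLE_COLUMNS] + [
        c for c in df.columns if c not in PEAK_TABLE_COLUMNS
    ]
    return df[ordered]


def write_peak_table(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a peak table to CSV (missing label/prediction → empty cell)."""
    df = _coerce_peak_table(table)
    df.to_csv(path, index=False, float_format="%.17g")


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read back a peak table written by :func:`write_peak_table`."""
    df = pd.read_csv(path, dtype={"channel": str})
    if len(df) == 0:
        return new_peak_table()
    for col in ("label", "prediction"):
        if col in df.columns:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False}
            )
    return _coerce_peak_table(df)
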
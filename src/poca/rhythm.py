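"""Episode construction and the 12 locomotor-rhythm features.

Predicted locomotor peaks that are closely spaced (gap below a merge
threshold, 1/0.15 Hz ≈ 6.67 s by default) are merged into episodes; the
rhythm of each channel is then summarized by 12 features:

Num    — number of locomotor oscillations
Dur    — rhythm duration (s): sum of episode spans (first-to-last-peak
         span selectable via config)
mPer   — mean within-episode inter-peak period (s)
PerCV  — coefficient of variation of those periods
Dep    — depolarization level (signal units)
AUC    — area of the filtered trace above the baseline median over the
         episodes (signal·s), negative parts clipped at zero
Duty   — duty cycle, mWid / mPer
mWid, WidCV — mean/CV of locomotor peak widths
mPro, ProCV — mean/CV of locomotor peak prominences
mLocDev     — mean local deviation of locomotor peaks

With no locomotor peak all features are emitted as NaN (undefined, not
zero); with a single one the period-based features are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RHYTHM_FEATURES, PocaConfig
from .io import FilteredRecording
from .peaks import ChannelContext


@dataclass
class Episode:
    """A maximal run of closely spaced locomotor peaks."""

    start: float
    end: float
    members: list[int]

    @property
    def n_peaks(self) -> int:
        return len(self.members)


def build_episodes(times: np.ndarray, merge_gap: float = 6.67) -> list[Episode]:
    """Merge sorted locomotor peak times into episodes.

    Consecutive peaks with a gap strictly below ``merge_gap`` share an
    episode; a gap at or above it starts a new one.
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        return []
    if np.any(np.diff(times) < 0):
        raise ValueError("peak times must be sorted")
    episodes: list[Episode] = []
    start = 0
    for j in range(1, len(times) + 1):
        if j == len(times) or times[j] - times[j - 1] >= merge_gap:
            members = list(range(start, j))
            episodes.append(
                Episode(start=float(times[start]), end=float(times[j - 1]), members=members)
            )
            start = j
    return episodes


def _cv(values: np.ndarray, ddof: int) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) <= ddof:
        return np.nan
    mean = values.mean()
    if mean == 0:
        return np.nan
    return float(values.std(ddof=ddof) / mean)


def _episode_auc(
    x: np.ndarray, fs: float, episodes: list[Episode], baseline: float
) -> float:
    total = 0.0
    n = len(x)
    for ep in episodes:
        i0 = int(round(ep.start * fs))
        i1 = min(n - 1, int(round(ep.end * fs)))
        if i1 <= i0:
            continue
        seg = np.clip(x[i0 : i1 + 1] - baseline, 0.0, None)
        total += float(np.trapezoid(seg, dx=1.0 / fs))
    return total


def channel_rhythm(
    ch_table: pd.DataFrame,
    pred: np.ndarray,
    x: np.ndarray,
    fs: float,
    ctx: ChannelContext,
    config: PocaConfig | None = None,
) -> tuple[dict, list[Episode]]:
    """Rhythm features of one channel given its peak table and predictions."""
    cfg = config or PocaConfig()
    pred = np.asarray(pred, dtype=bool)
    if len(pred) != len(ch_table):
        raise ValueError("prediction length must match peak table rows")

    feats: dict = {f: np.nan for f in RHYTHM_FEATURES}
    loco = ch_table[pred]
    feats["Num"] = float(len(loco))
    feats["Dep"] = np.nan if ctx.dep_level is None else float(ctx.dep_level)
    if len(loco) == 0:
        return feats, []

    times = loco["Time"].to_numpy(dtype=float)
    episodes = build_episodes(times, cfg.merge_gap_s)

    if cfg.dur_mode == "episodes":
        feats["Dur"] = float(sum(ep.end - ep.start for ep in episodes))
    else:
        feats["Dur"] = float(times[-1] - times[0])

    intervals = np.concatenate(
        [np.diff(times[ep.members]) for ep in episodes if ep.n_peaks > 1]
    ) if any(ep.n_peaks > 1 for ep in episodes) else np.array([])
    if len(intervals):
        feats["mPer"] = float(intervals.mean())
        feats["PerCV"] = _cv(intervals, cfg.cv_ddof)

    feats["AUC"] = _episode_auc(x, fs, episodes, ctx.baseline_median)

    wid = loco["Wid"].to_numpy(dtype=float)
    pro = loco["Pro"].to_numpy(dtype=float)
    feats["mWid"] = float(wid.mean())
    feats["WidCV"] = _cv(wid, cfg.cv_ddof)
    feats["mPro"] = float(pro.mean())
    feats["ProCV"] = _cv(pro, cfg.cv_ddof)
    feats["mLocDev"] = float(loco["LocDev"].to_numpy(dtype=float).mean())
    if np.isfinite(feats["mPer"]) and feats["mPer"] > 0:
        feats["Duty"] = feats["mWid"] / feats["mPer"]
    return feats, episodes


def rhythm_report(
    table: pd.DataFrame,
    pred: np.ndarray,
    filt: FilteredRecording,
    contexts: list[ChannelContext],
    config: PocaConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-channel rhythm features and an interval table of episodes.

    Returns (report, episodes) where ``report`` has one row per channel
    with the 12 rhythm features and ``episodes`` has columns channel,
    start_s, end_s, n_peaks.
    """
    cfg = config or PocaConfig()
    pred = np.asarray(pred, dtype=bool)
    if len(pred) != len(table):
        raise ValueError("prediction length must match peak table rows")

    rows = []
    ep_rows = []
    for c, name in enumerate(filt.channel_names):
        mask = (table["channel"] == name).to_numpy()
        feats, episodes = channel_rhythm(
            table[mask],
            pred[mask],
            filt.signal[:, c],
            filt.fs,
            contexts[c],
            cfg,
        )
        rows.append({"channel": name, **feats})
        for ep in episodes:
            ep_rows.append(
                {
                    "channel": name,
                    "start_s": ep.start,
                    "end_s": ep.end,
                    "n_peaks": ep.n_peaks,
                }
            )
    report = pd.DataFrame(rows, columns=["channel", *RHYTHM_FEATURES])
    episodes_df = pd.DataFrame(
        ep_rows, columns=["channel", "start_s", "end_s", "n_peaks"]
    )
    return report, episodes_df
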
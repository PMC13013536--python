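"""Candidate oscillation detection and the 12 per-peak features.

This is the heart of the peak-based framework: every local maximum of the
band-limited trace is a candidate oscillation, and each candidate is
characterized by 12 features —

* four basic ones: time of the peak (Time), absolute amplitude (Amp),
  prominence in a dynamic reference window (Pro), and temporal width at
  half prominence (Wid);
* three relative-prominence ratios: Pro2Dep (vs. the slow depolarization
  level), Pro2Base (vs. the mean prominence of pre-stimulation baseline
  peaks), Pro2Wid (prominence per second of width);
* LocDev, the ratio of a peak's prominence to the mean prominence of its
  (up to) four nearest temporal neighbors — a regional contrast feature;
* SynIndex, the percentage of synchronous samples in a 0.4-s window around
  the peak; and the boolean checks StimCK (after stimulation onset),
  FreqCK (local cycle frequency inside the locomotion band) and nSynCK
  (SynIndex below 50%).

Prominence is computed dynamically: within a ±window reference span the
nearest strictly-higher candidate on each side bounds a search interval,
the lowest sample of each interval is that side's minimum, and the higher
of the two minima is the reference level subtracted from the peak
amplitude.  Width is the distance between the two half-prominence
crossings, linearly interpolated between samples and searched only inside
the corresponding interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .config import PocaConfig
from .io import FilteredRecording, new_peak_table
from .synchrony import PhaseSet


@dataclass
class ChannelContext:
    """Slow-signal context a channel's relative features are measured against.

    ``dep_level`` is the depolarization amplitude (signal units) above the
    pre-stimulation baseline; ``base_pro`` the mean prominence of baseline
    candidates; ``baseline_median`` the median of the filtered trace over
    the baseline window (the area-under-curve baseline).
    """

    dep_level: float | None
    base_pro: float
    baseline_window: tuple[float, float]
    stim_onset: float | None
    baseline_median: float
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------


def detect_channel_candidates(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima of one channel (strictly increasing).

    A plateau (run of equal samples bounded by lower ones) yields a single
    candidate at the run's first sample.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return np.array([], dtype=int)
    peaks, props = find_peaks(x, plateau_size=(1, None))
    return props["left_edges"].astype(int)


def detect_candidates(filt: FilteredRecording) -> list[np.ndarray]:
    """Per-channel candidate peak indices."""
    return [detect_channel_candidates(filt.signal[:, c]) for c in range(filt.n_channels)]


# ---------------------------------------------------------------------------
# dynamic prominence / width
# ---------------------------------------------------------------------------


def _half_crossing_left(
    x: np.ndarray, fs: float, idx: int, bound: int, half: float
) -> tuple[float, bool]:
    """Time of the half-level crossing left of the peak.

    Scans from the peak toward ``bound``; the crossing lies between the
    nearest sample at or below the half level and its right neighbor
    (linear interpolation).  Returns (time, clamped-at-interval-end flag).
    """
    seg = x[bound:idx]
    below = np.flatnonzero(seg <= half)
    if len(below) == 0:
        return bound / fs, True
    k = bound + below.max()
    if x[k] == half:
        return k / fs, False
    frac = (half - x[k]) / (x[k + 1] - x[k])
    return (k + frac) / fs, False


def _half_crossing_right(
    x: np.ndarray, fs: float, idx: int, bound: int, half: float
) -> tuple[float, bool]:
    seg = x[idx + 1 : bound + 1]
    below = np.flatnonzero(seg <= half)
    if len(below) == 0:
        return bound / fs, True
    k = idx + 1 + below.min()
    if x[k] == half:
        return k / fs, False
    frac = (x[k - 1] - half) / (x[k - 1] - x[k])
    return (k - 1 + frac) / fs, False


def prominence_and_width(
    x: np.ndarray,
    fs: float,
    peak_index: int,
    candidates: np.ndarray,
    window_s: float = 6.67,
) -> tuple[float, float, bool]:
    """Dynamic windowed prominence and half-prominence width of one peak.

    Returns (Pro, Wid, flagged) where ``flagged`` marks a width clamped at
    an interval end because a half-level crossing was never reached.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    win = int(np.floor(window_s * fs + 1e-9))
    lo = max(0, peak_index - win)
    hi = min(n - 1, peak_index + win)

    left = candidates[(candidates < peak_index) & (candidates >= lo)]
    left_higher = left[x[left] > x[peak_index]]
    lb = int(left_higher.max()) if len(left_higher) else lo
    right = candidates[(candidates > peak_index) & (candidates <= hi)]
    right_higher = right[x[right] > x[peak_index]]
    rb = int(right_higher.min()) if len(right_higher) else hi

    left_min = x[lb : peak_index + 1].min()
    right_min = x[peak_index : rb + 1].min()
    ref = max(left_min, right_min)
    pro = float(x[peak_index] - ref)

    half = x[peak_index] - pro / 2.0
    t_left, fl = _half_crossing_left(x, fs, peak_index, lb, half)
    t_right, fr = _half_crossing_right(x, fs, peak_index, rb, half)
    wid = float(t_right - t_left)
    return pro, wid, bool(fl or fr)


# ---------------------------------------------------------------------------
# depolarization level
# ---------------------------------------------------------------------------


def depolarization_level(
    x: np.ndarray,
    fs: float,
    stim_onset: float,
    baseline_window: tuple[float, float],
    smooth_s: float = 10.0,
) -> float:
    """Slow-envelope depolarization amplitude after stimulation onset.

    The envelope is a centered moving average over ``smooth_s`` seconds;
    the level is its post-onset maximum minus its baseline-window median,
    floored at 1e-6 of the signal range so that Pro2Dep stays finite.
    """
    x = np.asarray(x, dtype=float)
    size = max(1, int(round(smooth_s * fs)))
    env = uniform_filter1d(x, size=size, mode="nearest")
    t = np.arange(len(x)) / fs
    post = env[t > stim_onset]
    if len(post) == 0:
        raise ValueError("no samples after stim_onset")
    b0, b1 = baseline_window
    base = env[(t >= b0) & (t < b1)]
    if len(base) == 0:
        raise ValueError("baseline window contains no samples")
    dep = float(post.max() - np.median(base))
    floor = 1e-6 * float(np.ptp(x))
    return max(dep, floor)


def channel_context(
    x: np.ndarray,
    fs: float,
    stim_onset: float | None,
    candidates: np.ndarray,
    pro: np.ndarray,
    config: PocaConfig,
) -> ChannelContext:
    """Build the per-channel context (Dep, baseline prominence, medians)."""
    flags: list[str] = []
    duration = (len(x) - 1) / fs
    if stim_onset is not None:
        baseline_window = (0.0, float(stim_onset))
    else:
        baseline_window = (0.0, duration)
        flags.append("no_stimulation: baseline = whole recording")

    times = candidates / fs
    b0, b1 = baseline_window
    base_mask = (times >= b0) & (times < b1)
    if base_mask.any():
        base_pro = float(pro[base_mask].mean())
    elif len(pro):
        base_pro = float(np.percentile(pro, 10))
        flags.append("no_baseline_candidates: base_pro = 10th percentile of Pro")
    else:
        base_pro = 1.0
        flags.append("no_candidates: base_pro undefined, set to 1")
    if base_pro <= 0:
        base_pro = max(base_pro, 1e-6 * float(np.ptp(x)) or 1e-12)
        flags.append("nonpositive base_pro floored")

    dep: float | None = None
    if stim_onset is not None:
        dep = depolarization_level(
            x, fs, stim_onset, baseline_window, config.dep_smooth_s
        )
    else:
        flags.append("no_stimulation: Dep undefined, Pro2Dep = 0")

    t = np.arange(len(x)) / fs
    base_samples = x[(t >= b0) & (t < b1)]
    baseline_median = float(np.median(base_samples)) if len(base_samples) else 0.0

    return ChannelContext(
        dep_level=dep,
        base_pro=base_pro,
        baseline_window=baseline_window,
        stim_onset=None if stim_onset is None else float(stim_onset),
        baseline_median=baseline_median,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# full feature extraction
# ---------------------------------------------------------------------------


def _local_deviation(pro: np.ndarray, j: int, n_neighbors: int) -> tuple[float, bool]:
    half = n_neighbors // 2
    idx = [k for k in range(j - half, j + half + 1) if k != j and 0 <= k < len(pro)]
    if not idx:
        return 1.0, True
    mean = float(pro[idx].mean())
    if mean <= 0:
        return 1.0, True
    return float(pro[j] / mean), False


def _cycle_frequency(times: np.ndarray, j: int) -> float | None:
    gaps = []
    if j > 0:
        gaps.append(times[j] - times[j - 1])
    if j < len(times) - 1:
        gaps.append(times[j + 1] - times[j])
    if not gaps:
        return None
    return 1.0 / float(np.mean(gaps))


def compute_features(
    filt: FilteredRecording,
    phases: PhaseSet | None,
    config: PocaConfig | None = None,
    contexts: list[ChannelContext] | None = None,
) -> pd.DataFrame:
    """Detect candidates on every channel and extract the 12 peak features.

    ``phases`` may be None for single-channel recordings; SynIndex is then
    NaN and nSynCK False (flagged).  Returns the canonical peak table with
    per-channel contexts stashed in ``df.attrs["contexts"]`` and any
    degradation notes in ``df.attrs["flags"]``.
    """
    cfg = config or PocaConfig()
    fs = filt.fs
    rows: list[dict] = []
    flags: list[str] = []
    ctx_out: list[ChannelContext] = []

    syn_half = int(round(cfg.synindex_window_s / 2.0 * fs))
    lo_f, hi_f = cfg.band

    for c, name in enumerate(filt.channel_names):
        x = filt.signal[:, c]
        cand = detect_channel_candidates(x)
        times = cand / fs

        pw = [
            prominence_and_width(x, fs, i, cand, cfg.window_s) for i in cand
        ]
        pro = np.array([p for p, _, _ in pw])
        wid = np.array([w for _, w, _ in pw])
        wid_flagged = [f for _, _, f in pw]

        if contexts is not None:
            ctx = contexts[c]
        else:
            ctx = channel_context(x, fs, filt.stim_onset, cand, pro, cfg)
        ctx_out.append(ctx)
        flags.extend(f"{name}: {msg}" for msg in ctx.flags)

        if len(cand) == 1:
            flags.append(f"{name}: single candidate, LocDev=1 and FreqCK=False")

        for j, i in enumerate(cand):
            t_peak = times[j]
            amp = float(x[i])
            p = float(pro[j])
            w = float(wid[j])
            if wid_flagged[j]:
                flags.append(f"{name}: width clamped at interval end (t={t_peak:.3f})")

            pro2dep = p / ctx.dep_level if ctx.dep_level is not None else 0.0
            pro2base = p / ctx.base_pro
            pro2wid = p / w if w > 0 else np.inf
            locdev, ld_flag = _local_deviation(pro, j, cfg.locdev_neighbors)

            if phases is not None:
                s = phases.sync[max(0, i - syn_half) : i + syn_half + 1, c]
                syn_index = 100.0 * float(s.mean()) if len(s) else 0.0
                nsynck = syn_index < 50.0
            else:
                syn_index = np.nan
                nsynck = False

            stimck = filt.stim_onset is not None and t_peak > filt.stim_onset
            f_est = _cycle_frequency(times, j)
            freqck = f_est is not None and lo_f <= f_est <= hi_f

            rows.append(
                {
                    "channel": name,
                    "peak_index": int(i),
                    "Time": float(t_peak),
                    "Amp": amp,
                    "Pro": p,
                    "Wid": w,
                    "Pro2Dep": float(pro2dep),
                    "Pro2Base": float(pro2base),
                    "Pro2Wid": float(pro2wid),
                    "LocDev": float(locdev),
                    "SynIndex": syn_index,
                    "StimCK": bool(stimck),
                    "FreqCK": bool(freqck),
                    "nSynCK": bool(nsynck),
                    "label": pd.NA,
                    "prediction": pd.NA,
                }
            )

    if phases is None:
        flags.append("single-channel recording: SynIndex/nSynCK unavailable")

    table = new_peak_table(rows)
    table.attrs["contexts"] = ctx_out
    table.attrs["flags"] = flags
    return table
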
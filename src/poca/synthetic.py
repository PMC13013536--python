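"""Synthetic fictive-locomotion recordings with ground-truth peak labels.

The generator emulates the phenomenology of an electrically induced
locomotor episode in an isolated neonatal-rodent spinal cord: low-amplitude
baseline oscillations with a common phase across channels; after the
stimulation onset a rapid depolarization (logistic rise) onto which
high-prominence locomotor oscillations ride, out of phase across channels
(left-right and flexor-extensor alternation, 180° by default); then an
exponential repolarization back to baseline.  White Gaussian noise is
added on top.  Every analytic oscillation crest is emitted with its label
(baseline crest → False, locomotor crest → True), so each pipeline stage
can be scored without any recorded data.

Oscillators are sinusoidal and the locomotor episode is gated by a
raised-cosine ramp; crests where the gate is below half amplitude are not
listed as ground-truth events (they are too attenuated to constitute an
oscillation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GroundTruthLabels, Recording

DEFAULT_ROLES = ("lL2", "rL2", "lL5", "rL5")

#: left-right and flexor-extensor alternation: homologous roots are
#: antiphase, diagonal roots in phase.
DEFAULT_PHASE_MAP = {"lL2": 0.0, "rL2": 180.0, "lL5": 180.0, "rL5": 0.0}


@dataclass
class SimConfig:
    """Parameters of a synthetic locomotor recording.

    Amplitudes are in arbitrary analog units; the depolarization amplitude
    and locomotor amplitude are of comparable magnitude, with baseline
    oscillations several times smaller, as in real ventral-root traces.
    """

    n_channels: int = 4
    fs_raw: float = 2000.0
    duration: float = 120.0
    stim_onset: float = 20.0
    stim_duration: float = 80.0
    baseline_freq: float = 0.3
    baseline_amp: float = 0.2
    locomotor_freq: float = 0.4
    locomotor_amp: float = 1.0
    dep_amp: float = 1.0
    dep_rise_s: float = 5.0
    episode_duration: float = 30.0
    decay_tau_s: float = 5.0
    gate_ramp_s: float = 2.0
    baseline_attenuation: float = 0.3
    phase_map: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_MAP))
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_amp < self.locomotor_amp:
            raise ValueError("need 0 < baseline_amp < locomotor_amp")
        if not 0.15 <= self.locomotor_freq <= 1.5:
            raise ValueError("locomotor_freq must lie in the 0.15-1.5 Hz band")
        if self.episode_end > self.stim_onset + self.stim_duration:
            raise ValueError("episode must fit inside the stimulation window")
        if self.episode_start >= self.episode_end:
            raise ValueError("episode_duration must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.duration < self.episode_end:
            raise ValueError("episode must fit inside the recording")

    @property
    def episode_start(self) -> float:
        return self.stim_onset + self.dep_rise_s

    @property
    def episode_end(self) -> float:
        return self.episode_start + self.episode_duration

    @property
    def channel_names(self) -> tuple[str, ...]:
        base = list(DEFAULT_ROLES)
        while len(base) < self.n_channels:
            base.append(f"ch{len(base)}")
        return tuple(base[: self.n_channels])


@dataclass
class SimOutput:
    """Generated recording, ground-truth crest labels, and event metadata."""

    recording: Recording
    labels: GroundTruthLabels
    config: SimConfig

    def true_events(self, channel: str) -> np.ndarray:
        ev = self.labels.for_channel(channel)
        return ev.loc[ev["label"].astype(bool), "time"].to_numpy(dtype=float)


def _gate(t: np.ndarray, start: float, end: float, ramp: float) -> np.ndarray:
    """Raised-cosine gate: 0 outside [start, end], unity plateau inside."""
    g = np.zeros_like(t)
    inside = (t >= start) & (t <= end)
    g[inside] = 1.0
    up = inside & (t < start + ramp)
    g[up] = np.sin(np.pi * (t[up] - start) / (2 * ramp)) ** 2
    down = inside & (t > end - ramp)
    g[down] = np.sin(np.pi * (end - t[down]) / (2 * ramp)) ** 2
    return g


def _gate_scalar(t: float, start: float, end: float, ramp: float) -> float:
    return float(_gate(np.array([t]), start, end, ramp)[0])


def generate(cfg: SimConfig) -> SimOutput:
    """Generate one synthetic multichannel recording (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs_raw)) + 1
    t = np.arange(n) / cfg.fs_raw
    ep0, ep1 = cfg.episode_start, cfg.episode_end

    # slow depolarization: logistic rise around the onset, exponential decay
    rise = 1.0 / (1.0 + np.exp(-(t - (cfg.stim_onset + cfg.dep_rise_s / 2.0)) * (8.0 / cfg.dep_rise_s)))
    decay = np.where(t > ep1, np.exp(-(t - ep1) / cfg.decay_tau_s), 1.0)
    dep = cfg.dep_amp * rise * decay

    gate = _gate(t, ep0, ep1, cfg.gate_ramp_s)
    base_factor = 1.0 - (1.0 - cfg.baseline_attenuation) * gate

    names = cfg.channel_names
    signal = np.empty((n, len(names)))
    events: list[dict] = []
    for c, name in enumerate(names):
        phi = np.deg2rad(cfg.phase_map.get(name, 0.0))
        baseline = cfg.baseline_amp * np.cos(2 * np.pi * cfg.baseline_freq * t)
        loco = (
            cfg.locomotor_amp
            * gate
            * np.cos(2 * np.pi * cfg.locomotor_freq * (t - ep0) + phi)
        )
        noise = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0
        signal[:, c] = baseline * base_factor + dep + loco + noise

        # analytic baseline crests outside the episode -> False events
        k = 1
        while k / cfg.baseline_freq < cfg.duration:
            tc = k / cfg.baseline_freq
            if not ep0 <= tc <= ep1:
                events.append({"channel": name, "time": tc, "label": False})
            k += 1
        # analytic locomotor crests with gate >= 0.5 -> True events
        for k in range(-1, int(np.ceil(cfg.locomotor_freq * cfg.episode_duration)) + 2):
            tc = ep0 + (k - phi / (2 * np.pi)) / cfg.locomotor_freq
            if ep0 <= tc <= ep1 and _gate_scalar(tc, ep0, ep1, cfg.gate_ramp_s) >= 0.5:
                events.append({"channel": name, "time": tc, "label": True})

    ev = pd.DataFrame(events, columns=["channel", "time", "label"])
    # stable per-channel ordering matching the channel layout
    ev["__c"] = ev["channel"].map({n_: i for i, n_ in enumerate(names)})
    ev = ev.sort_values(["__c", "time"], kind="stable").drop(columns="__c")
    ev = ev.reset_index(drop=True)

    rec = Recording(
        signal=signal,
        fs=cfg.fs_raw,
        channel_names=names,
        stim_onset=cfg.stim_onset,
        stim_offset=cfg.stim_onset + cfg.stim_duration,
        protocol_id=f"synthetic-seed{cfg.seed}",
    )
    return SimOutput(recording=rec, labels=GroundTruthLabels(ev), config=cfg)


def match_labels(
    gt: GroundTruthLabels, table: pd.DataFrame, tol: float
) -> tuple[pd.DataFrame, dict]:
    """Label detected candidates from ground-truth events.

    Greedy one-to-one matching by absolute time distance within ``tol``
    seconds, per channel; each matched candidate inherits the event's
    label, unmatched candidates are labeled False.  Returns the labeled
    table and a coverage report counting unmatched True events (misses).
    """
    table = table.copy()
    labels = np.zeros(len(table), dtype=bool)
    misses = 0
    n_true = 0
    for ch, g in table.groupby("channel", sort=False):
        ev = gt.for_channel(str(ch))
        ev_times = ev["time"].to_numpy(dtype=float)
        ev_labels = ev["label"].to_numpy(dtype=bool)
        n_true += int(ev_labels.sum())
        cand_times = g["Time"].to_numpy(dtype=float)
        cand_pos = g.index.to_numpy()

        pairs = []
        for ei, et in enumerate(ev_times):
            d = np.abs(cand_times - et)
            for ci in np.flatnonzero(d <= tol):
                pairs.append((d[ci], ei, ci))
        pairs.sort()
        used_e: set[int] = set()
        used_c: set[int] = set()
        for d, ei, ci in pairs:
            if ei in used_e or ci in used_c:
                continue
            used_e.add(ei)
            used_c.add(ci)
            labels[table.index.get_loc(cand_pos[ci])] = ev_labels[ei]
        misses += int(sum(1 for ei in range(len(ev_times)) if ev_labels[ei] and ei not in used_e))
    table["label"] = pd.array(labels, dtype="boolean")
    coverage = {"true_events": n_true, "missed_true_events": misses}
    return table, coverage
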
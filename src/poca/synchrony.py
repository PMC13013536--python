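"""Instantaneous phase and the boolean cross-channel synchronicity signal.

Locomotor output alternates between left/right and flexor/extensor roots, so
during a locomotor episode the channels are out of phase, while spontaneous
baseline activity is phase-synchronous across channels.  Each channel's
instantaneous phase is the argument of the analytic signal (Hilbert
transform) of the band-limited trace; a sample is "synchronous" when its
circular phase distance to another channel is below a threshold (45° by
default).

Phase differences are evaluated on the circle, i.e. folded into [0°, 180°],
so offsets of +350° and −10° are equivalent.  The quantifier over the other
channels is configurable: ``"all"`` (default — synchronous with every other
channel, which is what distinguishes the alternating locomotor state when
homologous and diagonal roots form in-phase synergy pairs) or ``"any"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .io import FilteredRecording


@dataclass
class PhaseSet:
    """Per-sample, per-channel instantaneous phase and synchronicity.

    ``phase`` is wrapped to (−π, π]; ``sync`` is boolean with the same
    shape.  Both index channels identically to the source recording.
    """

    phase: np.ndarray
    sync: np.ndarray
    fs: float


def instantaneous_phase(filt: FilteredRecording) -> np.ndarray:
    """Instantaneous phase (radians) of every channel.

    Each channel is mean-removed before the analytic-signal construction so
    that slow DC offsets (depolarization) do not bias the phase.
    """
    x = np.asarray(filt.signal, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("need at least one channel")
    centered = x - x.mean(axis=0, keepdims=True)
    if np.any(np.ptp(centered, axis=0) == 0):
        bad = int(np.flatnonzero(np.ptp(centered, axis=0) == 0)[0])
        raise ValueError(
            f"degenerate channel: phase undefined (channel {bad} is constant)"
        )
    analytic = hilbert(centered, axis=0)
    return np.angle(analytic)


def circular_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Absolute circular distance between phases, in radians within [0, π]."""
    return np.abs(np.angle(np.exp(1j * (a - b))))


def synchronicity_signal(
    phase: np.ndarray,
    threshold_deg: float = 45.0,
    quantifier: str = "all",
) -> np.ndarray:
    """Boolean synchronicity signal per sample per channel.

    A sample of channel c is True when its circular phase distance to
    another channel is strictly below ``threshold_deg``; ``quantifier``
    chooses whether one other channel suffices ("any") or every other
    channel must agree ("all").
    """
    phase = np.asarray(phase, dtype=float)
    n, c = phase.shape
    if c < 2:
        raise ValueError("synchronicity undefined for N_chan = 1")
    if quantifier not in ("any", "all"):
        raise ValueError("quantifier must be 'any' or 'all'")
    thr = np.deg2rad(threshold_deg)
    sync = np.zeros((n, c), dtype=bool)
    for ci in range(c):
        diffs = np.empty((n, c - 1))
        k = 0
        for cj in range(c):
            if cj == ci:
                continue
            diffs[:, k] = circular_difference(phase[:, ci], phase[:, cj])
            k += 1
        within = diffs < thr
        sync[:, ci] = within.any(axis=1) if quantifier == "any" else within.all(axis=1)
    return sync


def compute_phase_set(
    filt: FilteredRecording,
    threshold_deg: float = 45.0,
    quantifier: str = "all",
) -> PhaseSet:
    """Phase + synchronicity for a filtered recording (needs ≥ 2 channels)."""
    phase = instantaneous_phase(filt)
    sync = synchronicity_signal(phase, threshold_deg, quantifier)
    return PhaseSet(phase=phase, sync=sync, fs=filt.fs)
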
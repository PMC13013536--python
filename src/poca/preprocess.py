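"""Resampling to the working rate and isolation of the locomotion band.

The slow locomotor rhythm of an isolated spinal cord lives well below 1.5 Hz,
so recordings are decimated to a common 500 Hz working rate (with anti-alias
protection) and low-pass filtered with a zero-phase 4th-order Butterworth.
Zero-phase filtering matters: every downstream feature is anchored to peak
timestamps, which a causal filter would shift.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import FilteredRecording, Recording


def resample(rec: Recording, target_fs: float = 500.0) -> Recording:
    """Downsample a recording to ``target_fs`` Hz.

    Integer ratios use FIR decimation; non-integer ratios use polyphase FIR
    resampling.  Upsampling is refused: the working rate is meant to be at
    or below the acquisition rate.
    """
    if rec.fs < target_fs - 1e-9:
        raise ValueError(
            f"cannot upsample: recording at {rec.fs} Hz < target {target_fs} Hz"
        )
    if abs(rec.fs - target_fs) <= 1e-9 * target_fs:
        return Recording(
            signal=rec.signal.copy(),
            fs=rec.fs,
            channel_names=rec.channel_names,
            stim_onset=rec.stim_onset,
            stim_offset=rec.stim_offset,
            protocol_id=rec.protocol_id,
        )
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    if up == 1:
        out = sps.decimate(rec.signal, down, ftype="fir", zero_phase=True, axis=0)
    else:
        out = sps.resample_poly(rec.signal, up, down, axis=0)
    return Recording(
        signal=out,
        fs=rec.fs * up / down,
        channel_names=rec.channel_names,
        stim_onset=rec.stim_onset,
        stim_offset=rec.stim_offset,
        protocol_id=rec.protocol_id,
    )


def lowpass(rec: Recording, cutoff: float = 1.5) -> FilteredRecording:
    """Zero-phase low-pass at ``cutoff`` Hz (4th-order Butterworth, filtfilt).

    Edge transients are tamed with odd-reflection padding of about three
    cutoff periods; the first/last couple of seconds remain edge-affected
    and are best ignored by phase-sensitive checks.
    """
    nyq = rec.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({nyq} Hz)")
    sos = sps.butter(4, cutoff, btype="low", fs=rec.fs, output="sos")
    padlen = min(rec.n_samples - 1, int(3 * rec.fs / cutoff))
    out = sps.sosfiltfilt(sos, rec.signal, axis=0, padtype="odd", padlen=padlen)
    return FilteredRecording(
        signal=out,
        fs=rec.fs,
        channel_names=rec.channel_names,
        stim_onset=rec.stim_onset,
        stim_offset=rec.stim_offset,
        protocol_id=rec.protocol_id,
        provenance={"lp_cutoff": float(cutoff), "filter": "butter4_sosfiltfilt"},
    )


def preprocess(
    rec: Recording, working_fs: float = 500.0, lp_cutoff: float = 1.5
) -> FilteredRecording:
    """Resample then low-pass; the standard entry into the pipeline."""
    res = resample(rec, working_fs)
    filt = lowpass(res, lp_cutoff)
    filt.provenance["working_fs"] = float(working_fs)
    filt.provenance["source_fs"] = float(rec.fs)
    return filt
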
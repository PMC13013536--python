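"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written as plain loops, straight from the verbal
definitions, and share no code with the package.
"""

from __future__ import annotations

import numpy as np


def local_maxima_oracle(x) -> list[int]:
    """Local maxima by explicit scan; plateaus yield their first sample."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return out


def prominence_width_oracle(x, fs, idx, window_s=6.67):
    """Dynamic windowed prominence/width, loop-by-loop from the definition.

    Within +/- window_s of the peak the nearest strictly higher local
    maximum on each side bounds a search interval (window edge if none);
    the lowest value of each interval is its minimum, the higher minimum is
    the reference level, prominence is peak minus reference.  Width spans
    the two half-prominence crossings (linear interpolation), searched
    only inside the corresponding interval and clamped at its end when the
    signal never reaches the half level.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    cands = set(local_maxima_oracle(x))
    win = int(np.floor(window_s * fs + 1e-9))
    lo, hi = max(0, idx - win), min(n - 1, idx + win)

    lb = lo
    for k in range(idx - 1, lo - 1, -1):
        if k in cands and x[k] > x[idx]:
            lb = k
            break
    rb = hi
    for k in range(idx + 1, hi + 1):
        if k in cands and x[k] > x[idx]:
            rb = k
            break

    lmin = min(x[k] for k in range(lb, idx + 1))
    rmin = min(x[k] for k in range(idx, rb + 1))
    ref = max(lmin, rmin)
    pro = x[idx] - ref
    half = x[idx] - pro / 2.0

    t_left = lb / fs
    for k in range(idx - 1, lb - 1, -1):
        if x[k] <= half:
            if x[k] == half:
                t_left = k / fs
            else:
                t_left = (k + (half - x[k]) / (x[k + 1] - x[k])) / fs
            break
    t_right = rb / fs
    for k in range(idx + 1, rb + 1):
        if x[k] <= half:
            if x[k] == half:
                t_right = k / fs
            else:
                t_right = (k - 1 + (x[k - 1] - half) / (x[k - 1] - x[k])) / fs
            break
    return pro, t_right - t_left


def analytic_signal_oracle(x) -> np.ndarray:
    """Analytic signal via an explicit DFT one-sided spectrum doubling."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    X = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return np.fft.ifft(X * h)


def threshold_scan_oracle(x, y):
    """Best achievable F1 of the rule (value > tau) by exhaustive scan."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=bool)
    best_f1, best_tau = -1.0, None
    for tau in [-np.inf] + sorted(set(x.tolist())):
        pred = x > tau
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        fn = int(np.sum(~pred & y))
        f1 = 2 * tp / (2 * tp + fp + fn) if tp > 0 else 0.0
        if f1 > best_f1:
            best_f1, best_tau = f1, tau
    return best_f1, best_tau


def smooth_random_signal(rng, n, fs=500.0):
    """Band-limited random trace with a realistic number of local maxima."""
    freqs = rng.uniform(0.1, 2.0, size=5)
    amps = rng.uniform(0.2, 1.5, size=5)
    phases = rng.uniform(0, 2 * np.pi, size=5)
    t = np.arange(n) / fs
    x = sum(a * np.cos(2 * np.pi * f * t + p) for a, f, p in zip(amps, freqs, phases))
    drift = rng.normal(0, 0.02, n).cumsum()
    return x + drift
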
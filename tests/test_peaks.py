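import numpy as np
import pandas as pd
import pytest

from poca import (
    FilteredRecording,
    PocaConfig,
    compute_features,
    depolarization_level,
    detect_channel_candidates,
    prominence_and_width,
)
from poca.synchrony import PhaseSet

from _oracles import local_maxima_oracle, prominence_width_oracle, smooth_random_signal


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, expected",
    [
        ([0, 1, 2, 3, 4], []),  # monotone ramp: no maxima
        ([0, 1, 0, 2, 0], [1, 3]),
        ([0, 2, 2, 0], [1]),  # plateau -> first sample
        ([0, 1, 1, 2, 0], [3]),  # rising step is not a maximum
    ],
)
def test_detect_candidates_examples(x, expected):
    np.testing.assert_array_equal(detect_channel_candidates(np.array(x, float)), expected)


def test_detect_matches_scan_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = np.round(rng.normal(size=200), 1)  # ties make plateaus likely
        got = detect_channel_candidates(x)
        np.testing.assert_array_equal(got, local_maxima_oracle(x))


# ---------------------------------------------------------------------------
# prominence / width
# ---------------------------------------------------------------------------


def test_prominence_listed_samples():
    x = np.array([0, 1, 0, 3, 0, 2, 0], dtype=float)
    cand = detect_channel_candidates(x)
    # peak of height 2 at index 5: nearest higher peak is the 3 at index 3
    pro, wid, _ = prominence_and_width(x, 1.0, 5, cand, window_s=10.0)
    assert pro == pytest.approx(2.0)
    # peak of height 3: no higher peak, intervals run to the window edges
    pro3, _, _ = prominence_and_width(x, 1.0, 3, cand, window_s=10.0)
    assert pro3 == pytest.approx(3.0)


def test_prominence_triangle_geometry():
    # symmetric triangle of height 4 on a zero baseline
    x = np.array([0, 1, 2, 3, 4, 3, 2, 1, 0], dtype=float)
    cand = detect_channel_candidates(x)
    pro, wid, flagged = prominence_and_width(x, 1.0, 4, cand, window_s=100.0)
    assert pro == pytest.approx(4.0)
    assert wid == pytest.approx(4.0)  # crossings at half height 2.0
    assert not flagged


def test_prominence_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    for trial in range(30):
        n = int(rng.integers(300, 3000))
        x = smooth_random_signal(rng, n)
        cand = detect_channel_candidates(x)
        for idx in cand[:: max(1, len(cand) // 10)]:
            pro, wid, _ = prominence_and_width(x, 500.0, idx, cand)
            o_pro, o_wid = prominence_width_oracle(x, 500.0, idx)
            assert pro == pytest.approx(o_pro, abs=1e-9)
            assert wid == pytest.approx(o_wid, abs=1e-9)


def test_window_constant_when_no_higher_peak_inside():
    # a dominant peak over an exactly-zero floor: with no higher peak in any
    # tested window and both interval minima pinned at the floor, Pro must
    # not depend on the window size
    fs = 500.0
    x = _spiky_signal([10.0], [1.0], fs, 20.0)
    for t_side in (9.0, 11.0):
        side = _spiky_signal([t_side], [0.1], fs, 20.0)
        x = np.maximum(x, side)
    cand = detect_channel_candidates(x)
    main = cand[np.argmax(x[cand])]
    pros = [
        prominence_and_width(x, fs, main, cand, window_s=w)[0]
        for w in (3.0, 6.67, 15.0)
    ]
    assert max(pros) - min(pros) < 1e-12


def test_amplitude_shift_covariance():
    rng = np.random.default_rng(5)
    x = smooth_random_signal(rng, 2000)
    cand = detect_channel_candidates(x)
    shifted = x + 17.3
    assert np.array_equal(detect_channel_candidates(shifted), cand)
    for idx in cand[:5]:
        p0, w0, _ = prominence_and_width(x, 500.0, idx, cand)
        p1, w1, _ = prominence_and_width(shifted, 500.0, idx, cand)
        assert p1 == pytest.approx(p0, abs=1e-9)
        assert w1 == pytest.approx(w0, abs=1e-9)


def test_time_reversal_symmetry():
    rng = np.random.default_rng(6)
    x = smooth_random_signal(rng, 1501)
    # use a plateau-free signal so reversal maps maxima exactly
    cand = detect_channel_candidates(x)
    rev = x[::-1].copy()
    cand_rev = detect_channel_candidates(rev)
    np.testing.assert_array_equal(sorted(len(x) - 1 - cand_rev), cand)
    for idx in cand[:5]:
        p0, w0, _ = prominence_and_width(x, 500.0, idx, cand)
        p1, w1, _ = prominence_and_width(rev, 500.0, len(x) - 1 - idx, cand_rev)
        assert p1 == pytest.approx(p0, abs=1e-9)
        assert w1 == pytest.approx(w0, abs=1e-9)


# ---------------------------------------------------------------------------
# depolarization
# ---------------------------------------------------------------------------


def test_dep_step_height():
    fs = 500.0
    t = np.arange(0, 60, 1 / fs)
    x = np.where(t > 20, 1.0, 0.0)
    dep = depolarization_level(x, fs, 20.0, (0.0, 20.0), smooth_s=10.0)
    assert dep == pytest.approx(1.0, abs=0.02)


def test_dep_constant_signal_floored():
    fs = 100.0
    x = np.full(int(60 * fs), 2.0)
    dep = depolarization_level(x, fs, 20.0, (0.0, 20.0))
    assert 0 <= dep <= 1e-6  # epsilon floor of a zero-range signal


def test_dep_triangular_envelope():
    # triangular envelope peaking at 2.0; the smoothed apex has the
    # closed form  peak - (a+b)*T/8  for slopes a, b and window T
    fs = 500.0
    t = np.arange(0, 100, 1 / fs)
    x = np.interp(t, [0, 20, 50, 80, 100], [0, 0, 2.0, 0, 0])
    dep = depolarization_level(x, fs, 20.0, (0.0, 20.0), smooth_s=10.0)
    a = b = 2.0 / 30.0
    expected = 2.0 - (a + b) * 10.0 / 8.0
    assert dep == pytest.approx(expected, abs=0.01)


def test_dep_trapezoid_recovers_full_height():
    # a plateau wider than the smoother keeps the full 2.0 level
    fs = 500.0
    t = np.arange(0, 100, 1 / fs)
    x = np.interp(t, [0, 20, 35, 65, 80, 100], [0, 0, 2.0, 2.0, 0, 0])
    dep = depolarization_level(x, fs, 20.0, (0.0, 20.0), smooth_s=10.0)
    assert dep == pytest.approx(2.0, abs=0.02)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def _mini_recording(x, fs=10.0, stim_onset=None):
    return FilteredRecording(
        signal=np.asarray(x, float)[:, None],
        fs=fs,
        channel_names=("lL2",),
        stim_onset=stim_onset,
    )


def _spiky_signal(times, pros, fs, duration):
    """Sum of narrow triangles of given heights at given times."""
    n = int(duration * fs) + 1
    x = np.zeros(n)
    w = int(0.2 * fs)
    for tc, h in zip(times, pros):
        i = int(round(tc * fs))
        for k in range(-w, w + 1):
            if 0 <= i + k < n:
                x[i + k] = max(x[i + k], h * (1 - abs(k) / w))
    return x


def test_synindex_endpoints_and_nsynck():
    fs = 10.0
    x = _spiky_signal([5.0], [1.0], fs, 10.0)
    filt = _mini_recording(x, fs)
    n = filt.n_samples
    for value, expected_idx, expected_check in [(True, 100.0, False), (False, 0.0, True)]:
        sync = np.full((n, 1), value)
        phases = PhaseSet(phase=np.zeros((n, 1)), sync=sync, fs=fs)
        table = compute_features(filt, phases)
        assert table["SynIndex"].iloc[0] == expected_idx
        assert bool(table["nSynCK"].iloc[0]) == expected_check


def test_freqck_from_neighbor_intervals():
    fs = 20.0
    # candidates 1 s apart -> 1 Hz, inside the band
    x = _spiky_signal([1.0, 2.0, 3.0], [1, 1, 1], fs, 4.0)
    table = compute_features(_mini_recording(x, fs), None)
    assert bool(table["FreqCK"].iloc[1])
    # candidates 0.1 s apart -> 10 Hz, outside the band
    fs2 = 200.0
    x2 = _spiky_signal([1.0, 1.1, 1.2], [1, 1, 1], fs2, 2.0)
    # narrower spikes for the tight spacing
    n = int(2.0 * fs2) + 1
    x2 = np.zeros(n)
    for tc in (1.0, 1.1, 1.2):
        i = int(tc * fs2)
        x2[i - 5 : i + 6] = np.concatenate([np.linspace(0, 1, 6), np.linspace(1, 0, 6)[1:]])
    table2 = compute_features(_mini_recording(x2, fs2), None)
    mid = table2.iloc[(table2["Time"] - 1.1).abs().idxmin()]
    assert not bool(mid["FreqCK"])


def test_locdev_hand_oracle():
    fs = 20.0
    x = _spiky_signal([2, 4, 6, 8, 10], [1, 1, 2, 1, 1], fs, 12.0)
    table = compute_features(_mini_recording(x, fs), None)
    assert len(table) == 5
    locdev = table["LocDev"].to_numpy()
    # middle peak: 2 / mean(1,1,1,1) = 2
    assert locdev[2] == pytest.approx(2.0, rel=1e-6)
    # first peak: neighbors are peaks 2 and 3 with Pro 1 and 2 -> 1/1.5
    assert locdev[0] == pytest.approx(1 / 1.5, rel=1e-6)


def test_single_candidate_flags():
    fs = 20.0
    x = _spiky_signal([5.0], [1.0], fs, 10.0)
    table = compute_features(_mini_recording(x, fs), None)
    assert len(table) == 1
    assert table["LocDev"].iloc[0] == 1.0
    assert not bool(table["FreqCK"].iloc[0])


def test_stimck_and_no_stim_behavior():
    fs = 20.0
    x = _spiky_signal([2.0, 8.0], [1.0, 1.0], fs, 10.0)
    with_stim = compute_features(_mini_recording(x, fs, stim_onset=5.0), None)
    assert with_stim["StimCK"].tolist() == [False, True]
    assert (with_stim["Pro2Dep"] > 0).all()
    no_stim = compute_features(_mini_recording(x, fs), None)
    assert no_stim["StimCK"].tolist() == [False, False]
    np.testing.assert_array_equal(no_stim["Pro2Dep"], 0.0)


def test_baseline_prominence_fallback():
    fs = 20.0
    # stimulation starts before any candidate: no baseline peaks
    x = _spiky_signal([4.0, 6.0, 8.0], [1, 1, 1], fs, 10.0)
    table = compute_features(_mini_recording(x, fs, stim_onset=1.0), None)
    assert np.isfinite(table["Pro2Base"]).all()
    assert any("no_baseline_candidates" in f for f in table.attrs["flags"])
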
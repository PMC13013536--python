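import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poca import (
    ProminenceKMeans,
    RBFPeakClassifier,
    ThresholdClassifier,
    fit_model,
    load_model,
    new_peak_table,
    normalize_features,
    predict_model,
    save_model,
)

from _oracles import threshold_scan_oracle


def _table_with(channel_values: dict[str, dict]) -> pd.DataFrame:
    """Build a minimal peak table; channel -> {feature: values}."""
    rows = []
    for ch, feats in channel_values.items():
        n = len(next(iter(feats.values())))
        for i in range(n):
            row = {
                "channel": ch,
                "peak_index": i,
                "Time": float(i),
                "Amp": 0.0,
                "Pro": 1.0,
                "Wid": 1.0,
                "Pro2Dep": 0.0,
                "Pro2Base": 0.0,
                "Pro2Wid": 0.0,
                "LocDev": 0.0,
                "SynIndex": 0.0,
                "StimCK": False,
                "FreqCK": False,
                "nSynCK": False,
            }
            for f, vals in feats.items():
                row[f] = vals[i]
            rows.append(row)
    return new_peak_table(rows)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_minmax_normalization_per_channel():
    table = _table_with({"a": {"Pro": [1.0, 3.0, 5.0]}, "b": {"Pro": [10.0, 30.0]}})
    normed, norm = normalize_features(table)
    np.testing.assert_allclose(
        normed.loc[normed["channel"] == "a", "Pro"], [0.0, 0.5, 1.0]
    )
    np.testing.assert_allclose(normed.loc[normed["channel"] == "b", "Pro"], [0.0, 1.0])
    assert norm["a"]["Pro"] == (1.0, 5.0)


def test_constant_feature_maps_to_zero():
    table = _table_with({"a": {"Pro": [2.0, 2.0, 2.0]}})
    normed, _ = normalize_features(table)
    np.testing.assert_array_equal(normed["Pro"], 0.0)


def test_booleans_map_to_unit_values():
    table = _table_with({"a": {"StimCK": [True, False]}})
    normed, _ = normalize_features(table)
    assert normed["StimCK"].tolist() == [1.0, 0.0]


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


def test_threshold_scan_picks_smallest_optimal_tau():
    x = np.array([0.1, 0.2, 0.8, 0.9])
    y = np.array([False, False, True, True])
    clf = ThresholdClassifier().fit(x[:, None], y)
    assert clf.f1_ == 1.0
    assert clf.tau_ == pytest.approx(0.2)  # smallest scan value achieving F1=1
    np.testing.assert_array_equal(clf.predict(x[:, None]), y)


def test_threshold_strict_inequality():
    clf = ThresholdClassifier()
    clf.tau_ = 0.5
    assert not clf.predict(np.array([[0.5]]))[0]
    assert clf.predict(np.array([[0.5 + 1e-12]]))[0]
    assert clf.predict(np.empty((0, 1))).shape == (0,)


def test_threshold_anticorrelated_feature_capped():
    x = np.array([0.9, 0.8, 0.2, 0.1])
    y = np.array([False, False, True, True])
    clf = ThresholdClassifier().fit(x[:, None], y)
    assert clf.f1_ <= 0.8  # inverted feature cannot reach F1=1 with ">"


def test_threshold_degenerate_cases():
    with pytest.raises(ValueError, match="degenerate training labels"):
        ThresholdClassifier().fit(np.array([[1.0], [2.0]]), np.array([True, True]))
    clf = ThresholdClassifier().fit(
        np.array([[1.0], [1.0], [1.0], [1.0]]),
        np.array([True, True, False, False]),
    )
    assert clf.degenerate_
    # all-True prediction (tau = -inf) gives F1 = 2/3 on this balanced set
    assert clf.f1_ == pytest.approx(2 / 3)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.data())
def test_threshold_matches_exhaustive_scan_oracle(data):
    n = data.draw(st.integers(3, 60))
    x = np.array(data.draw(st.lists(
        st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n
    )))
    y = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
    if y.all() or not y.any():
        y[0] = not y[0]
    clf = ThresholdClassifier().fit(x[:, None], y)
    oracle_f1, _ = threshold_scan_oracle(x, y)
    assert clf.f1_ == pytest.approx(oracle_f1, abs=1e-12)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------


def test_svm_separates_xor():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    y = np.array([True, True, False, False])
    clf = RBFPeakClassifier(C=1.0, gamma=1.0).fit(X, y)
    np.testing.assert_array_equal(clf.predict(X), y)


def test_svm_separable_1d():
    X = np.linspace(0, 1, 20)[:, None]
    y = X[:, 0] > 0.5
    clf = RBFPeakClassifier().fit(X, y)
    np.testing.assert_array_equal(clf.predict(X), y)


def test_svm_conflicting_duplicates_cannot_be_separated():
    X = np.zeros((10, 2))
    y = np.arange(10) % 2 == 0
    clf = RBFPeakClassifier().fit(X, y)
    pred = clf.predict(X)
    assert not np.array_equal(pred, y)


def test_svm_kernel_expansion_reproduces_predictions():
    # direct summation over the stored support vectors/coefficients
    # must reproduce the solver's predictions
    rng = np.random.default_rng(8)
    X = rng.normal(size=(80, 3))
    y = (X[:, 0] + 0.3 * rng.normal(size=80)) > 0
    if y.all() or not y.any():
        y[0] = not y[0]
    clf = RBFPeakClassifier().fit(X, y)
    X_new = rng.normal(size=(40, 3))
    manual = clf.decision_function(X_new) > 0
    np.testing.assert_array_equal(manual, clf._svc.decision_function(X_new) > 0)


# ---------------------------------------------------------------------------
# 2-means
# ---------------------------------------------------------------------------


def test_kmeans_orients_by_prominence():
    rng = np.random.default_rng(9)
    lo = rng.normal(0.1, 0.02, size=(30, 2))
    hi = rng.normal(0.9, 0.02, size=(30, 2))
    X = np.vstack([lo, hi])
    pro = X[:, 0]
    clf = ProminenceKMeans().fit(X, prominence=pro)
    pred = clf.predict(X)
    assert not pred[:30].any()
    assert pred[30:].all()


def test_kmeans_equidistant_point_is_false():
    clf = ProminenceKMeans()
    clf.mu0_ = np.array([0.0])
    clf.mu1_ = np.array([1.0])
    assert not clf.predict(np.array([[0.5]]))[0]


def test_kmeans_degenerate_points_rejected():
    with pytest.raises(ValueError, match="degenerate clustering"):
        ProminenceKMeans().fit(np.ones((5, 2)), prominence=np.ones(5))


def test_kmeans_permutation_invariant_centroids():
    rng = np.random.default_rng(10)
    X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(1, 0.1, (20, 2))])
    pro = X[:, 0]
    a = ProminenceKMeans().fit(X, prominence=pro)
    perm = rng.permutation(len(X))
    b = ProminenceKMeans().fit(X[perm], prominence=pro[perm])
    np.testing.assert_array_equal(a.mu0_, b.mu0_)
    np.testing.assert_array_equal(a.mu1_, b.mu1_)


# ---------------------------------------------------------------------------
# table-level API and serialization
# ---------------------------------------------------------------------------


def _labeled_toy_table():
    rng = np.random.default_rng(12)
    n = 40
    pro = np.concatenate([rng.uniform(0.1, 0.4, n // 2), rng.uniform(1.5, 2.0, n // 2)])
    lab = np.concatenate([np.zeros(n // 2, bool), np.ones(n // 2, bool)])
    table = _table_with({"a": {"Pro": pro.tolist(), "Wid": (pro * 2).tolist()}})
    table["label"] = pd.array(lab, dtype="boolean")
    return table, lab


@pytest.mark.parametrize("approach", ["threshold", "svm", "kmeans"])
def test_fit_predict_roundtrip_through_json(tmp_path, approach):
    table, lab = _labeled_toy_table()
    cfg = None
    from poca import PocaConfig

    cfg = PocaConfig(svm_features=("Pro", "Wid"), threshold_feature="Pro")
    model = fit_model(table, approach, cfg)
    pred = predict_model(model, table)
    assert np.mean(pred == lab) >= 0.95
    save_model(model, tmp_path / "m.json")
    back = load_model(tmp_path / "m.json")
    np.testing.assert_array_equal(predict_model(back, table), pred)


def test_shuffled_rows_give_identical_per_peak_predictions():
    table, lab = _labeled_toy_table()
    from poca import PocaConfig

    cfg = PocaConfig(svm_features=("Pro", "Wid"))
    rng = np.random.default_rng(13)
    perm = rng.permutation(len(table))
    shuffled = table.iloc[perm].reset_index(drop=True)
    for approach in ("threshold", "svm", "kmeans"):
        m0 = fit_model(table, approach, cfg)
        m1 = fit_model(shuffled, approach, cfg)
        p0 = predict_model(m0, table)
        p1 = predict_model(m1, shuffled)
        np.testing.assert_array_equal(p0[perm], p1)
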
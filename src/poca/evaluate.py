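"""Classification metrics, agreement and dataset-shift statistics.

Covers: confusion-count metrics (sensitivity, precision, accuracy, F1 with
its harmonic-mean identity), ICC(2,1) absolute-agreement intraclass
correlation for method-vs-reference rhythm features, a histogram KL
divergence for comparing feature distributions across protocols, and
per-feature class-discrimination diagnostics (chi-square for the boolean
checks, Student's t otherwise, plus a mixed Pearson/Spearman correlation
matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import BOOLEAN_FEATURES, PEAK_FEATURES


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN counts of a binary prediction vs. ground truth."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between truth and prediction")
    return ConfusionCounts(
        TP=int(np.sum(y_pred & y_true)),
        FP=int(np.sum(y_pred & ~y_true)),
        TN=int(np.sum(~y_pred & ~y_true)),
        FN=int(np.sum(~y_pred & y_true)),
    )


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """SEN, PRE, ACC, F1 with zero-denominator conventions.

    SEN and PRE are 0 when their denominator is 0; F1 = 2TP/(2TP+FP+FN)
    and is 0 when TP = 0; ACC requires a non-empty total.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    sen = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    pre = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    acc = (tp + tn) / counts.total
    f1 = 2 * tp / (2 * tp + fp + fn) if tp > 0 else 0.0
    return {"SEN": sen, "PRE": pre, "ACC": acc, "F1": f1}


def aggregate_metrics(per_unit: list[dict]) -> dict:
    """Mean ± sd of each metric over recording-channels."""
    if not per_unit:
        raise ValueError("nothing to aggregate")
    out = {}
    for key in ("SEN", "PRE", "ACC", "F1"):
        vals = np.array([m[key] for m in per_unit], dtype=float)
        out[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    out["n"] = len(per_unit)
    return out


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------


def icc_agreement(x, y) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``x`` are the method's values and ``y`` the reference's, paired by
    subject.  Computed from the two-way ANOVA mean squares:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    with n subjects and k = 2 raters.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two 1-D paired arrays")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("ICC needs at least 3 paired values")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("degenerate ratings: zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((data - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# ---------------------------------------------------------------------------
# dataset shift
# ---------------------------------------------------------------------------


def kl_divergence(
    p_sample, q_sample, bins: int = 100, eps: float = 1e-10
) -> float:
    """KL(P‖Q) in nats between two samples via shared-grid histograms.

    Both samples are binned on one equal-width grid spanning the pooled
    range; probabilities are ε-smoothed and renormalized so the divergence
    is finite, non-negative, and ~0 for identical samples.
    """
    p_sample = np.asarray(p_sample, dtype=float)
    q_sample = np.asarray(q_sample, dtype=float)
    if len(p_sample) == 0 or len(q_sample) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([p_sample, q_sample])
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        raise ValueError("zero-width support: pooled sample is constant")
    edges = np.linspace(lo, hi, bins + 1)
    p_hist, _ = np.histogram(p_sample, bins=edges)
    q_hist, _ = np.histogram(q_sample, bins=edges)
    p = p_hist / p_hist.sum() + eps
    q = q_hist / q_hist.sum() + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


# ---------------------------------------------------------------------------
# feature diagnostics
# ---------------------------------------------------------------------------


def _is_binary(v: np.ndarray) -> bool:
    u = np.unique(v[np.isfinite(v)])
    return len(u) <= 2 and np.all(np.isin(u, (0.0, 1.0)))


def feature_diagnostics(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-discrimination statistics and the feature correlation matrix.

    Boolean checks get a chi-square test of association with the label;
    continuous features a two-sample Student's t-test of class means.  The
    correlation matrix covers the 12 features plus the label, Spearman
    when both variables are binary and Pearson otherwise.  Zero-variance
    entries are NaN.
    """
    lab = table["label"]
    if lab.isna().any():
        raise ValueError("diagnostics need fully labeled peaks")
    y = lab.to_numpy(dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    rows = []
    for feat in PEAK_FEATURES:
        v = table[feat].to_numpy(dtype=float)
        if feat in BOOLEAN_FEATURES:
            ct = pd.crosstab(v.astype(bool), y)
            if ct.shape == (2, 2):
                chi2, p, _, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
                rows.append({"feature": feat, "test": "chi2", "stat": chi2, "p": p})
            else:
                rows.append(
                    {"feature": feat, "test": "chi2", "stat": np.nan, "p": np.nan}
                )
        else:
            a, b = v[y], v[~y]
            finite = np.isfinite(a).all() and np.isfinite(b).all()
            if finite and (a.std() > 0 or b.std() > 0):
                t, p = stats.ttest_ind(a, b, equal_var=True)
            else:
                t, p = (0.0, 1.0) if finite else (np.nan, np.nan)
            rows.append({"feature": feat, "test": "t", "stat": t, "p": p})
    tests = pd.DataFrame(rows)

    names = list(PEAK_FEATURES) + ["label"]
    cols = {f: table[f].to_numpy(dtype=float) for f in PEAK_FEATURES}
    cols["label"] = y.astype(float)
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            va, vb = cols[a], cols[b]
            ok = np.isfinite(va) & np.isfinite(vb)
            va, vb = va[ok], vb[ok]
            if len(va) < 3 or va.std() == 0 or vb.std() == 0:
                r = np.nan
            elif _is_binary(va) and _is_binary(vb):
                r = stats.spearmanr(va, vb).statistic
            else:
                r = stats.pearsonr(va, vb).statistic
            corr.iloc[i, j] = corr.iloc[j, i] = r
    for name in names:
        v = cols[name]
        if not np.isfinite(v).any() or np.nanstd(v) == 0:
            corr.loc[name, name] = np.nan
    return tests, corr
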
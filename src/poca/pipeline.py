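"""End-to-end pipeline and the experiment harness.

`analyze_recording` chains preprocessing → synchronicity → candidate
detection → feature extraction; `run_pipeline` adds classification, rhythm
characterization, metrics and file output with a run manifest.  The harness
functions implement recording-level four-fold cross-validation, exhaustive
feature-subset search ranked by mean validation F1, and a training-size
learning curve with repeated seeded draws.  Folds always partition whole
recordings, never individual peaks, so no peak of a validation recording is
ever seen at training time.
"""

from __future__ import annotations

import itertools
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import fit_model, predict_model, save_model
from .config import PocaConfig
from .evaluate import aggregate_metrics, confusion_counts, confusion_metrics
from .io import FilteredRecording, GroundTruthLabels, Recording, write_peak_table
from .peaks import ChannelContext, compute_features
from .preprocess import preprocess
from .rhythm import rhythm_report
from .synchrony import PhaseSet, compute_phase_set
from .synthetic import match_labels


@dataclass
class AnalysisResult:
    """Everything the deterministic front half of the pipeline produces."""

    filt: FilteredRecording
    phases: PhaseSet | None
    table: pd.DataFrame

    @property
    def contexts(self) -> list[ChannelContext]:
        return self.table.attrs["contexts"]


def analyze_recording(rec: Recording, config: PocaConfig | None = None) -> AnalysisResult:
    """Preprocess, compute phase/synchronicity and extract peak features."""
    cfg = config or PocaConfig()
    filt = preprocess(rec, cfg.working_fs, cfg.lp_cutoff)
    phases = (
        compute_phase_set(filt, cfg.sync_threshold_deg, cfg.sync_quantifier)
        if filt.n_channels >= 2
        else None
    )
    table = compute_features(filt, phases, cfg)
    return AnalysisResult(filt=filt, phases=phases, table=table)


def metrics_by_channel(table: pd.DataFrame, pred: np.ndarray) -> list[dict]:
    """Per recording-channel confusion metrics of a labeled, predicted table."""
    pred = np.asarray(pred, dtype=bool)
    out = []
    keys = [k for k in ("recording", "channel") if k in table.columns]
    for key, g in table.groupby(keys, sort=False):
        y = g["label"].to_numpy(dtype=bool)
        p = pred[table.index.get_indexer(g.index)]
        m = confusion_metrics(confusion_counts(y, p))
        m["unit"] = key if isinstance(key, str) else "/".join(map(str, key))
        out.append(m)
    return out


def run_pipeline(
    rec: Recording,
    config: PocaConfig | None = None,
    out_dir: str | Path | None = None,
    model: dict | None = None,
    gt: GroundTruthLabels | None = None,
    match_tol: float | None = None,
    seed: int = 0,
) -> dict:
    """Run the five pipeline stages on one recording.

    Requires either a fitted ``model`` or ground-truth ``gt`` labels (a
    default model is then trained on this recording).  When ``out_dir`` is
    given, writes peak_table.csv, rhythm_report.csv, episodes.csv,
    metrics.json (when labels exist), model.json and manifest.json.
    """
    cfg = config or PocaConfig()
    if model is None and gt is None:
        raise ValueError("need a fitted model or ground-truth labels to train one")

    result = analyze_recording(rec, cfg)
    table = result.table
    coverage = None
    if gt is not None:
        tol = 0.625 if match_tol is None else match_tol
        table, coverage = match_labels(gt, table, tol)
        table.attrs.update(result.table.attrs)
    if model is None:
        model = fit_model(table, cfg.approach, cfg)

    pred = predict_model(model, table)
    table["prediction"] = pd.array(pred, dtype="boolean")
    report, episodes = rhythm_report(table, pred, result.filt, result.contexts, cfg)

    metrics = None
    if gt is not None:
        per_unit = metrics_by_channel(table, pred)
        metrics = {"per_channel": per_unit, "aggregate": aggregate_metrics(per_unit)}

    out = {
        "table": table,
        "prediction": pred,
        "rhythm": report,
        "episodes": episodes,
        "model": model,
        "metrics": metrics,
        "coverage": coverage,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_peak_table(table, out_dir / "peak_table.csv")
        report.to_csv(out_dir / "rhythm_report.csv", index=False, float_format="%.17g")
        episodes.to_csv(out_dir / "episodes.csv", index=False, float_format="%.17g")
        save_model(model, out_dir / "model.json")
        if metrics is not None:
            with open(out_dir / "metrics.json", "w") as fh:
                json.dump(metrics, fh, indent=1)
        manifest = {
            "config": cfg.to_dict(),
            "config_digest": cfg.digest(),
            "seed": seed,
            "poca_version": __version__,
            "python": platform.python_version(),
            "n_peaks": int(len(table)),
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    return out


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------


def _tag_recording(table: pd.DataFrame, rec_id: str) -> pd.DataFrame:
    t = table.copy()
    t.insert(0, "recording", rec_id)
    return t


def make_folds(ids: list[str], n_folds: int, seed: int) -> list[list[str]]:
    """Random, even, recording-level partition into ``n_folds`` groups."""
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} recordings, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("recording ids must be unique (leakage)")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    return [perm[k::n_folds] for k in range(n_folds)]


def _fit_eval(
    train_tables: list[pd.DataFrame],
    val_tables: list[pd.DataFrame],
    approach: str,
    cfg: PocaConfig,
) -> tuple[list[dict], list[dict]]:
    train = pd.concat(train_tables, ignore_index=True)
    model = fit_model(train, approach, cfg)
    train_metrics = metrics_by_channel(train, predict_model(model, train))
    val_metrics = []
    for vt in val_tables:
        val_metrics.extend(metrics_by_channel(vt, predict_model(model, vt)))
    return train_metrics, val_metrics


def cross_validate(
    labeled_tables: dict[str, pd.DataFrame],
    approach: str = "svm",
    n_folds: int = 4,
    seed: int = 0,
    config: PocaConfig | None = None,
) -> dict:
    """Recording-level k-fold cross-validation.

    ``labeled_tables`` maps recording id -> labeled peak table.  Each fold
    serves once as validation while the others train; metrics are
    aggregated as mean ± sd over recording-channels.
    """
    cfg = config or PocaConfig()
    ids = list(labeled_tables)
    folds = make_folds(ids, n_folds, seed)
    tagged = {rid: _tag_recording(labeled_tables[rid], rid) for rid in ids}

    fold_results = []
    all_train, all_val = [], []
    for k, val_ids in enumerate(folds):
        train_ids = [rid for rid in ids if rid not in val_ids]
        assert not set(train_ids) & set(val_ids)
        tm, vm = _fit_eval(
            [tagged[r] for r in train_ids],
            [tagged[r] for r in val_ids],
            approach,
            cfg,
        )
        fold_results.append(
            {
                "fold": k,
                "validation_ids": val_ids,
                "train": aggregate_metrics(tm),
                "validation": aggregate_metrics(vm),
            }
        )
        all_train.extend(tm)
        all_val.extend(vm)

    return {
        "approach": approach,
        "n_folds": n_folds,
        "folds": fold_results,
        "train": aggregate_metrics(all_train),
        "validation": aggregate_metrics(all_val),
        "mean_validation_f1": float(
            np.mean([f["validation"]["F1"]["mean"] for f in fold_results])
        ),
    }


def subset_search(
    labeled_tables: dict[str, pd.DataFrame],
    feature_pool: tuple[str, ...],
    n_folds: int = 4,
    seed: int = 0,
    config: PocaConfig | None = None,
    max_subsets: int | None = None,
) -> pd.DataFrame:
    """Evaluate every non-empty subset of ``feature_pool`` by CV mean F1.

    Returns a DataFrame ranked by mean validation F1 (descending), one row
    per subset.  ``max_subsets`` caps the enumeration for large pools.
    """
    cfg = config or PocaConfig()
    if not feature_pool:
        raise ValueError("feature pool must not be empty")
    subsets = []
    for r in range(1, len(feature_pool) + 1):
        subsets.extend(itertools.combinations(feature_pool, r))
    if max_subsets is not None:
        subsets = subsets[:max_subsets]
    rows = []
    for sub in subsets:
        res = cross_validate(
            labeled_tables,
            approach="svm",
            n_folds=n_folds,
            seed=seed,
            config=cfg.replace(svm_features=tuple(sub)),
        )
        rows.append(
            {
                "features": "+".join(sub),
                "n_features": len(sub),
                "mean_validation_f1": res["mean_validation_f1"],
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["mean_validation_f1", "n_features"], ascending=[False, True], kind="stable"
    )
    return df.reset_index(drop=True)


def learning_curve(
    train_pool: dict[str, pd.DataFrame],
    test_tables: dict[str, pd.DataFrame],
    sizes: list[int],
    repeats: int = 10,
    approach: str = "svm",
    seed: int = 0,
    config: PocaConfig | None = None,
) -> pd.DataFrame:
    """Held-out metrics versus training-set size, with repeated draws.

    For each size, ``repeats`` random draws (without replacement) from the
    training pool are trained and evaluated on the fixed test set; the
    mean ± sd of held-out F1/ACC over repeats is reported per size.
    """
    cfg = config or PocaConfig()
    ids = list(train_pool)
    rng = np.random.default_rng(seed)
    tagged_pool = {rid: _tag_recording(train_pool[rid], rid) for rid in ids}
    tagged_test = [_tag_recording(t, rid) for rid, t in test_tables.items()]

    rows = []
    for size in sizes:
        if size < 1 or size > len(ids):
            raise ValueError(f"training size {size} outside pool of {len(ids)}")
        f1s, accs = [], []
        for _ in range(repeats):
            chosen = [ids[i] for i in rng.choice(len(ids), size=size, replace=False)]
            try:
                tm, vm = _fit_eval(
                    [tagged_pool[r] for r in chosen], tagged_test, approach, cfg
                )
            except ValueError:
                # a tiny draw may contain a single class; skip that draw
                continue
            agg = aggregate_metrics(vm)
            f1s.append(agg["F1"]["mean"])
            accs.append(agg["ACC"]["mean"])
        rows.append(
            {
                "size": size,
                "repeats": len(f1s),
                "f1_mean": float(np.mean(f1s)) if f1s else np.nan,
                "f1_sd": float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0,
                "acc_mean": float(np.mean(accs)) if accs else np.nan,
                "acc_sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
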
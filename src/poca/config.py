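"""Run configuration shared by every pipeline stage.

All tunable parameters of the analysis live in one flat dataclass so that a
run is a pure function of (inputs, config, seed).  Values can be loaded from
a YAML file and overridden programmatically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: Canonical names of the 12 per-peak features, in table column order.
PEAK_FEATURES: tuple[str, ...] = (
    "Time",
    "Amp",
    "Pro",
    "Wid",
    "Pro2Dep",
    "Pro2Base",
    "Pro2Wid",
    "LocDev",
    "SynIndex",
    "StimCK",
    "FreqCK",
    "nSynCK",
)

#: The three boolean checks among the 12 features.
BOOLEAN_FEATURES: tuple[str, ...] = ("StimCK", "FreqCK", "nSynCK")

#: Continuous features (everything that is min-max normalized per channel).
CONTINUOUS_FEATURES: tuple[str, ...] = tuple(
    f for f in PEAK_FEATURES if f not in BOOLEAN_FEATURES
)

#: Names of the 12 rhythm features, in report column order.
RHYTHM_FEATURES: tuple[str, ...] = (
    "Num",
    "Dur",
    "mPer",
    "PerCV",
    "Dep",
    "AUC",
    "Duty",
    "mWid",
    "WidCV",
    "mPro",
    "ProCV",
    "mLocDev",
)


@dataclass
class PocaConfig:
    """Parameters of the peak-based oscillation analysis.

    Attributes
    ----------
    working_fs : float
        Sampling rate (Hz) every recording is brought to before filtering.
    lp_cutoff : float
        Low-pass corner (Hz) isolating the slow locomotion band.
    band : tuple of float
        Locomotion bandwidth (Hz); used by the FreqCK feature and to size
        the prominence reference window (1 / band[0]).
    sync_threshold_deg : float
        Circular phase-difference threshold (degrees) below which two
        channels count as synchronous at a sample.
    sync_quantifier : str
        ``"all"`` (default): a sample is synchronous only when every other
        channel is within the threshold; ``"any"``: one other channel
        suffices.  With the usual four-root montage the homologous and
        diagonal roots form two synergy groups whose members stay mutually
        in phase even during locomotion, so the existential reading would
        report synchronicity everywhere; the universal reading is the one
        that distinguishes the alternating locomotor state.
    window_s : float
        Half-width (s) of the dynamic prominence reference window.
    synindex_window_s : float
        Full width (s) of the window over which SynIndex counts synchronous
        samples around a peak.
    locdev_neighbors : int
        Number of temporal neighbor peaks (total, split evenly left/right)
        entering the local-deviation feature.
    dep_smooth_s : float
        Moving-average window (s) for the slow envelope used to estimate
        the depolarization level.
    merge_gap_s : float
        Maximum gap (s) between consecutive locomotor peaks inside one
        episode.
    dur_mode : str
        ``"episodes"``: rhythm duration sums per-episode spans;
        ``"span"``: first-to-last locomotor peak.
    cv_ddof : int
        Delta degrees of freedom for coefficient-of-variation estimates.
    approach : str
        Default classifier: ``"threshold"``, ``"svm"`` or ``"kmeans"``.
    threshold_feature : str
        Feature used by the single-feature thresholding classifier.
    svm_features : tuple of str
        Feature subset of the RBF-SVM classifier.
    svm_C, svm_gamma
        Soft-margin penalty and kernel width; ``svm_gamma=None`` uses
        1 / (n_features * mean feature variance).
    kmeans_restarts, kmeans_seed
        Lloyd's-algorithm restarts and RNG seed for the 2-means classifier.
    """

    working_fs: float = 500.0
    lp_cutoff: float = 1.5
    band: tuple[float, float] = (0.15, 1.5)
    sync_threshold_deg: float = 45.0
    sync_quantifier: str = "all"
    window_s: float = 6.67
    synindex_window_s: float = 0.4
    locdev_neighbors: int = 4
    dep_smooth_s: float = 10.0
    merge_gap_s: float = 6.67
    dur_mode: str = "episodes"
    cv_ddof: int = 1
    approach: str = "svm"
    threshold_feature: str = "Pro"
    svm_features: tuple[str, ...] = (
        "Pro",
        "Wid",
        "Time",
        "SynIndex",
        "FreqCK",
        "LocDev",
    )
    svm_C: float = 1.0
    svm_gamma: float | None = None
    kmeans_restarts: int = 10
    kmeans_seed: int = 0

    def __post_init__(self) -> None:
        if self.working_fs <= 0:
            raise ValueError("working_fs must be positive")
        if not 0 < self.lp_cutoff < self.working_fs / 2:
            raise ValueError("lp_cutoff must lie in (0, working_fs/2)")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")
        if self.sync_quantifier not in ("any", "all"):
            raise ValueError("sync_quantifier must be 'any' or 'all'")
        if self.dur_mode not in ("episodes", "span"):
            raise ValueError("dur_mode must be 'episodes' or 'span'")
        if self.approach not in ("threshold", "svm", "kmeans"):
            raise ValueError("approach must be threshold|svm|kmeans")
        unknown = set(self.svm_features) - set(PEAK_FEATURES)
        if unknown:
            raise ValueError(f"unknown svm features: {sorted(unknown)}")
        if self.threshold_feature not in PEAK_FEATURES:
            raise ValueError(f"unknown threshold feature {self.threshold_feature!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["svm_features"] = list(self.svm_features)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PocaConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        if "svm_features" in d:
            d["svm_features"] = tuple(d["svm_features"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PocaConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def replace(self, **changes) -> "PocaConfig":
        return dataclasses.replace(self, **changes)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
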
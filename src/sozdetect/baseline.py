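"""Manual-feature baseline: discrete-wavelet features + tree ensembles.

Each 1-s window is decomposed with a db4 discrete wavelet transform into an
approximation band and L detail bands; five summary statistics per subband
(mean, standard deviation, energy, maximum, minimum) form the feature
vector, fed to a Random Forest or Extra Trees classifier.  This is the
classical epilepsy-EEG recipe and serves as the comparison point for the
CNN; the exact feature set behind published baseline numbers varies, so the
defaults here are declared and configurable rather than a reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split

from .evaluation import MetricsReport, confusion, metrics

__all__ = ["DwtFeatureSpec", "dwt_features", "dwt_feature_matrix", "train_baseline"]

_STATS = {
    "mean": np.mean,
    "std": np.std,
    "energy": lambda c: float(np.sum(np.square(c))),
    "max": np.max,
    "min": np.min,
}


@dataclass(frozen=True)
class DwtFeatureSpec:
    wavelet: str = "db4"
    levels: int = 4
    statistics: tuple[str, ...] = ("mean", "std", "energy", "max", "min")

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        unknown = set(self.statistics) - set(_STATS)
        if unknown:
            raise ValueError(f"unknown statistics: {sorted(unknown)}")

    @property
    def feature_length(self) -> int:
        return (self.levels + 1) * len(self.statistics)


def dwt_features(window: np.ndarray, spec: DwtFeatureSpec | None = None) -> np.ndarray:
    """Per-subband statistics, approximation band first, then details coarse->fine."""
    spec = spec or DwtFeatureSpec()
    window = np.asarray(window, dtype=float)
    max_level = pywt.dwt_max_level(len(window), spec.wavelet)
    if max_level < spec.levels:
        raise ValueError(
            f"window of {len(window)} samples supports at most {max_level} "
            f"{spec.wavelet} levels; {spec.levels} requested"
        )
    coeffs = pywt.wavedec(window, spec.wavelet, level=spec.levels)
    feats = [
        float(_STATS[stat](band)) for band in coeffs for stat in spec.statistics
    ]
    return np.asarray(feats)


def dwt_feature_matrix(
    windows: np.ndarray, spec: DwtFeatureSpec | None = None
) -> np.ndarray:
    return np.stack([dwt_features(w, spec) for w in np.asarray(windows)])


def train_baseline(
    features: np.ndarray,
    labels: np.ndarray,
    classifier: str = "random_forest",
    seed: int = 0,
    n_estimators: int = 100,
    test_fraction: float = 0.2,
):
    """Fit a tree ensemble on DWT features with the stratified 80/20 split.

    Returns (fitted classifier, MetricsReport on the held-out 20%).
    """
    makers = {
        "random_forest": RandomForestClassifier,
        "extra_trees": ExtraTreesClassifier,
    }
    if classifier not in makers:
        raise ValueError(
            f"unknown classifier {classifier!r}; choose from {sorted(makers)}"
        )
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    X_tr, X_te, y_tr, y_te = train_test_split(
        features, labels, test_size=test_fraction, stratify=labels,
        random_state=seed,
    )
    clf = makers[classifier](n_estimators=n_estimators, random_state=seed)
    clf.fit(X_tr, y_tr)
    report = metrics(confusion(clf.predict(X_te), y_te))
    return clf, report
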
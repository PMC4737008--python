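"""SVM classification of feature tables with repeated stratified k-fold CV.

The two groups (trained = 1, baseline = 0) are classified from epoch-level
feature vectors with a polynomial-kernel support vector machine; accuracy is
reported as mean +/- SD over stratified 10-fold cross-validation (288 train /
32 test per fold at the study size of 320 epochs). Features are z-scored using
training-fold statistics only, and optional feature selection is likewise
refit inside each training fold so no test information leaks into it.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .connectivity import build_feature_table
from .preprocess import EpochSet
from .wavelets import decompose_epochs

Selector = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclasses.dataclass
class CVResult:
    """Per-fold accuracies and their summary for one measurement/feature set."""

    per_fold_accuracy: List[float]
    measurement: str = ""
    k_features: Optional[int] = None
    seed: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.per_fold_accuracy, ddof=1)) if len(self.per_fold_accuracy) > 1 else 0.0

    @property
    def mean_pct(self) -> float:
        return 100.0 * self.mean_accuracy

    @property
    def sd_pct(self) -> float:
        return 100.0 * self.sd_accuracy


def kfold_split(
    labels: np.ndarray, k: int = 10, seed: int = 0
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified, disjoint, exhaustive k-fold split; deterministic given seed."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if k > len(labels):
        raise ValueError(f"k={k} exceeds {len(labels)} samples")
    if k == len(labels):  # leave-one-out; stratification is vacuous
        idx = np.arange(len(labels))
        return [(np.delete(idx, i), np.array([i])) for i in idx]
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members < {k} folds")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in cv.split(np.zeros(len(labels)), labels)]


def _make_svc(kernel: str, degree: int, C: float) -> SVC:
    return SVC(kernel=kernel, degree=degree, C=C, gamma="scale", coef0=1.0)


def train_eval(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "poly",
    degree: int = 3,
    C: float = 1.0,
    folds: int = 10,
    seed: int = 0,
    selector: Optional[Selector] = None,
    measurement: str = "",
    splits: Optional[Sequence[Tuple[np.ndarray, np.ndarray]]] = None,
) -> CVResult:
    """Stratified k-fold CV accuracy of the SVM on a feature matrix.

    ``selector(X_train, y_train) -> column indices`` runs inside each training
    fold (e.g. VIP top-k) before standardization and fitting. Pre-computed
    ``splits`` allow paired comparisons across measurements on identical folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if splits is None:
        splits = kfold_split(y, k=folds, seed=seed)
    accs: List[float] = []
    k_features = X.shape[1]
    for tr, te in splits:
        Xtr, Xte = X[tr], X[te]
        if selector is not None:
            cols = np.asarray(selector(Xtr, y[tr]))
            Xtr, Xte = Xtr[:, cols], Xte[:, cols]
            k_features = len(cols)
        scaler = StandardScaler().fit(Xtr)
        clf = _make_svc(kernel, degree, C)
        clf.fit(scaler.transform(Xtr), y[tr])
        accs.append(float(np.mean(clf.predict(scaler.transform(Xte)) == y[te])))
    return CVResult(per_fold_accuracy=accs, measurement=measurement,
                    k_features=k_features, seed=seed)


def compare_measurements(
    epochset: EpochSet,
    measurements: Sequence[str] = ("energy", "overall", "alpha", "beta", "delta", "theta"),
    kernel: str = "poly",
    degree: int = 3,
    C: float = 1.0,
    folds: int = 10,
    seed: int = 0,
    band_cache: Optional[Dict[str, np.ndarray]] = None,
) -> pd.DataFrame:
    """CV accuracy per measurement on identical folds (paired comparison).

    Returns a table (measurement, mean_accuracy_pct, sd_accuracy_pct), one row
    per requested measurement, mirroring the energy-vs-correlation and
    per-band comparisons of the original analysis.
    """
    bands_needed = [m for m in measurements if m in ("delta", "theta", "alpha", "beta")]
    if bands_needed and band_cache is None:
        band_cache = decompose_epochs(epochset, bands=tuple(dict.fromkeys(bands_needed)))
    splits = kfold_split(epochset.labels, k=folds, seed=seed)
    rows = []
    for m in measurements:
        table = build_feature_table(epochset, m, band_cache=band_cache)
        res = train_eval(table.X, table.labels, kernel=kernel, degree=degree, C=C,
                         splits=splits, measurement=m, seed=seed)
        rows.append(
            {
                "measurement": m,
                "mean_accuracy_pct": res.mean_pct,
                "sd_accuracy_pct": res.sd_pct,
            }
        )
    return pd.DataFrame(rows)
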
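"""Per-epoch brain networks: correlation matrices, 171-pair feature vectors,
and the per-channel energy baseline.

Every electrode is a network node; the edge weight between nodes i and j is
the Pearson correlation R[i, j] = C[i, j] / sqrt(C[i, i] C[j, j]) of their
epoch time series, where C is the channel covariance matrix. R is symmetric
with unit diagonal, so its strict upper triangle — 171 values for 19 channels
— is the feature vector of the epoch. Signed correlations are kept as
features; absolute values are taken only when summarising group means.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .montage import feature_names
from .preprocess import EpochSet
from .wavelets import decompose_epochs

MEASUREMENTS = ("energy", "overall", "delta", "theta", "alpha", "beta")


@dataclasses.dataclass
class CorrelationMatrix:
    """Pearson matrix R with its covariance matrix C (both n_channels square)."""

    R: np.ndarray
    C: np.ndarray


@dataclasses.dataclass
class FeatureTable:
    """n_samples x n_features matrix with per-feature channel-pair annotations.

    ``annotations`` has one row per feature: 1-based ``index``, ``lead_pair``
    label ('F7-T3' style, or the bare channel name for energy features) and the
    ``measurement`` name.
    """

    X: np.ndarray
    labels: np.ndarray
    annotations: pd.DataFrame
    measurement: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.shape[0] != len(self.labels):
            raise ValueError("labels length must match number of rows")
        if self.X.shape[1] != len(self.annotations):
            raise ValueError("annotations must have one row per feature")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.annotations["lead_pair"]))
        df.insert(0, "group", self.labels)
        return df

    def write_csv(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: Path | str, measurement: str = "overall") -> "FeatureTable":
        df = pd.read_csv(path)
        labels = df.pop("group").to_numpy()
        ann = pd.DataFrame(
            {
                "index": np.arange(1, df.shape[1] + 1),
                "lead_pair": df.columns,
                "measurement": measurement,
            }
        )
        return cls(X=df.to_numpy(), labels=labels, annotations=ann, measurement=measurement)


def pearson_matrix(epoch: np.ndarray) -> CorrelationMatrix:
    """Correlation matrix of one epoch (channels x samples).

    Zero-variance channels get a zero row/column with unit diagonal (their
    correlation with anything is undefined); a warning is issued.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[1] < 2:
        raise ValueError("epoch must be (n_channels, n_samples) with n_samples >= 2")
    C = np.cov(epoch)
    var = np.diag(C).copy()
    dead = var <= 0
    if dead.any():
        warnings.warn(f"{dead.sum()} zero-variance channel(s); correlations set to 0",
                      stacklevel=2)
        var[dead] = 1.0
    denom = np.sqrt(np.outer(var, var))
    R = C / denom
    R[dead, :] = 0.0
    R[:, dead] = 0.0
    np.fill_diagonal(R, np.where(dead, 1.0, np.diag(R)))
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    return CorrelationMatrix(R=R, C=C)


def vectorize(corr: CorrelationMatrix) -> np.ndarray:
    """Flatten the strict upper triangle row-major; element k-1 (0-based) is the
    feature with 1-based index k of the pair-index map."""
    n = corr.R.shape[0]
    iu = np.triu_indices(n, k=1)
    return corr.R[iu]


def unvectorize(vec: np.ndarray, n: int) -> np.ndarray:
    """Scatter a pair-feature vector back into a symmetric matrix (unit diagonal)."""
    R = np.eye(n)
    iu = np.triu_indices(n, k=1)
    R[iu] = vec
    R[(iu[1], iu[0])] = vec
    return R


def energy_features(epoch: np.ndarray) -> np.ndarray:
    """Per-channel signal energy: mean squared amplitude over the epoch."""
    epoch = np.asarray(epoch, dtype=float)
    return np.mean(epoch ** 2, axis=-1)


def build_feature_table(
    epochset: EpochSet,
    measurement: str,
    band_cache: Optional[Dict[str, np.ndarray]] = None,
) -> FeatureTable:
    """One feature row per epoch.

    measurement:
      * ``energy``  — 19 per-channel mean-square amplitudes (the non-network
        baseline);
      * ``overall`` — 171 pairwise correlations of the bandpassed signal
        itself (the signal before wavelet decomposition);
      * ``delta|theta|alpha|beta`` — 171 pairwise correlations of the mapped
        DWT subband reconstructions.

    ``band_cache`` (from :func:`eegconn.wavelets.decompose_epochs`) avoids
    re-decomposing when several band tables are built from one EpochSet.
    """
    if measurement not in MEASUREMENTS:
        raise ValueError(f"unknown measurement {measurement!r}; choose from {MEASUREMENTS}")

    montage = epochset.montage
    if measurement == "energy":
        X = np.stack([energy_features(ep) for ep in epochset.epochs]) \
            if epochset.n_epochs else np.empty((0, len(montage)))
        ann = pd.DataFrame(
            {
                "index": np.arange(1, len(montage) + 1),
                "lead_pair": list(montage),
                "measurement": measurement,
            }
        )
        return FeatureTable(X=X, labels=epochset.labels, annotations=ann,
                            measurement=measurement)

    if measurement == "overall":
        data = epochset.epochs
    else:
        if band_cache is not None and measurement in band_cache:
            data = band_cache[measurement]
        else:
            data = decompose_epochs(epochset, bands=(measurement,))[measurement]

    rows = [vectorize(pearson_matrix(data[e])) for e in range(data.shape[0])]
    n_pairs = len(montage) * (len(montage) - 1) // 2
    X = np.stack(rows) if rows else np.empty((0, n_pairs))
    ann = pd.DataFrame(
        {
            "index": np.arange(1, n_pairs + 1),
            "lead_pair": list(feature_names(montage)),
            "measurement": measurement,
        }
    )
    return FeatureTable(X=X, labels=epochset.labels, annotations=ann,
                        measurement=measurement)
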
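"""Partial least squares by SIMPLS, with VIP feature scoring and selection.

PLS decomposes the column-centred feature matrix X (n x d) and label vector
Y (n x 1) into latent structures

    X = T P' + E,        Y = U Q' + F,

choosing each weight vector so that the covariance of the latent score pair
(t_k, u_k) is maximal, subject to orthogonality of the X-scores. SIMPLS
(de Jong 1993) achieves this by deflating the cross-product s = X'Y directly;
for a single response it coincides exactly with the classical PLS1 solution.

Feature importance uses the Variable Importance in Projection score

    VIP_j = sqrt( d * sum_k rho_k^2 w_jk^2 / sum_k rho_k^2 ),

where w_k are the unit-norm X-weight vectors, rho_k = u_k' t_k is the
regression weight of latent component k, and d is the number of features.
With unit-norm weights the scores satisfy sum_j VIP_j^2 = d, so VIP > 1 marks
a feature contributing more than average. Only the ranking matters downstream
and it is invariant to the square root and the factor d.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

_RANK_TOL = 1e-10


@dataclasses.dataclass
class PLSModel:
    """Fitted SIMPLS decomposition (all matrices on centred data).

    T, U: n x p latent scores (T orthonormal); P (d x p), Q (1 x p): loadings;
    W: d x p unit-norm weight vectors; rho[k] = u_k' t_k; E, F: residuals.
    """

    T: np.ndarray
    U: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    W: np.ndarray
    rho: np.ndarray
    E: np.ndarray
    F: np.ndarray
    x_mean: np.ndarray
    y_mean: float

    @property
    def n_components(self) -> int:
        return self.T.shape[1]

    @property
    def n_features(self) -> int:
        return self.W.shape[0]


@dataclasses.dataclass
class VIPRanking:
    """Per-feature VIP scores with the descending-order permutation.

    ``order`` holds 0-based feature positions sorted by descending score,
    ties broken by ascending feature index.
    """

    scores: np.ndarray
    order: np.ndarray

    def top(self, k: int) -> np.ndarray:
        if k > len(self.order):
            raise ValueError(f"k={k} exceeds {len(self.order)} features")
        return self.order[:k]


def center(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Column-centre; returns (centred, column means)."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    return X - mean, mean


def simpls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a single-response SIMPLS model.

    X and y may be uncentred; column means are removed and stored. The sign of
    each component is fixed by forcing the largest-magnitude entry of its
    weight vector positive, making the fit fully deterministic. If the
    cross-product deflates to (numerical) zero before ``n_components``
    components are extracted, the model is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n, d = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on the number of samples")
    if n < 2:
        raise ValueError("need at least 2 samples")
    p_max = min(n - 1, d)
    if n_components > p_max:
        warnings.warn(
            f"n_components={n_components} exceeds min(n-1, d)={p_max}; truncating",
            stacklevel=2,
        )
        n_components = p_max
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    Xc, x_mean = center(X)
    y_mean = float(y.mean())
    yc = y - y_mean

    s = Xc.T @ yc  # deflated cross-product
    T = np.zeros((n, n_components))
    U = np.zeros((n, n_components))
    P = np.zeros((d, n_components))
    Q = np.zeros((1, n_components))
    W = np.zeros((d, n_components))
    rho = np.zeros(n_components)
    V = np.zeros((d, n_components))  # orthonormal basis of extracted loadings

    k = 0
    s0 = np.linalg.norm(s)
    for k_iter in range(n_components):
        if np.linalg.norm(s) <= _RANK_TOL * max(s0, 1.0):
            warnings.warn(
                f"cross-product exhausted after {k_iter} components; truncating",
                stacklevel=2,
            )
            break
        r = s.copy()  # for univariate y the dominant direction of s s' is s itself
        t = Xc @ r
        t -= t.mean()
        t_norm = np.linalg.norm(t)
        t /= t_norm
        r /= t_norm
        p_load = Xc.T @ t
        q = float(yc @ t)
        u = yc * q
        if k_iter > 0:
            u -= T[:, :k_iter] @ (T[:, :k_iter].T @ u)

        # deterministic sign: largest-|entry| weight element positive
        w_unit = r / np.linalg.norm(r)
        sign = 1.0 if w_unit[np.argmax(np.abs(w_unit))] >= 0 else -1.0
        t, u, p_load, q, w_unit = sign * t, sign * u, sign * p_load, sign * q, sign * w_unit

        T[:, k_iter], U[:, k_iter] = t, u
        P[:, k_iter], Q[0, k_iter], W[:, k_iter] = p_load, q, w_unit
        rho[k_iter] = float(u @ t)

        v = p_load.copy()
        if k_iter > 0:
            v -= V[:, :k_iter] @ (V[:, :k_iter].T @ p_load)
        v /= np.linalg.norm(v)
        V[:, k_iter] = v
        s = s - v * (v @ s)
        k = k_iter + 1

    T, U, P, Q, W, rho = T[:, :k], U[:, :k], P[:, :k], Q[:, :k], W[:, :k], rho[:k]
    E = Xc - T @ P.T
    F = yc - T @ Q[0]
    return PLSModel(T=T, U=U, P=P, Q=Q, W=W, rho=rho, E=E, F=F,
                    x_mean=x_mean, y_mean=y_mean)


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Fitted-response prediction ŷ = y_mean + (X - x_mean) B with B from the
    SIMPLS regression coefficients."""
    Xc = np.asarray(X, dtype=float) - model.x_mean
    # regression coefficients B = W (P'W)^-1 Q'
    B = model.W @ np.linalg.solve(model.P.T @ model.W, model.Q.T)
    return model.y_mean + Xc @ B[:, 0]


def vip_scores(model: PLSModel) -> VIPRanking:
    """VIP score per feature plus the descending ranking."""
    d = model.n_features
    rho2 = model.rho ** 2
    total = rho2.sum()
    if total <= 0:
        warnings.warn("all regression weights zero (Y orthogonal to X); VIP = 0",
                      stacklevel=2)
        scores = np.zeros(d)
    else:
        scores = np.sqrt(d * (model.W ** 2 @ rho2) / total)
    # stable sort on negated scores -> ties broken by ascending feature index
    order = np.argsort(-scores, kind="stable")
    return VIPRanking(scores=scores, order=order)


def select_top(
    ranking: VIPRanking,
    k: int,
    annotations: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Top-k features as a table (rank, 0-based position, 1-based index,
    lead_pair, vip_score)."""
    top = ranking.top(k)
    out = pd.DataFrame(
        {
            "rank": np.arange(1, k + 1),
            "position": top,
            "feature_index": top + 1,
            "vip_score": ranking.scores[top],
        }
    )
    if annotations is not None:
        ann = annotations.reset_index(drop=True)
        out["feature_index"] = ann.loc[top, "index"].to_numpy()
        out["lead_pair"] = ann.loc[top, "lead_pair"].to_numpy()
    return out


def rank_features(X: np.ndarray, y: np.ndarray, n_components: int = 5) -> VIPRanking:
    """Convenience: centre, fit SIMPLS, return the VIP ranking."""
    return vip_scores(simpls_fit(X, y, n_components))


def sweep_k(
    X: np.ndarray,
    y: np.ndarray,
    ks: Sequence[int],
    n_components: int = 5,
    folds: int = 10,
    seed: int = 0,
    leaky: bool = False,
    **svm_kwargs,
) -> pd.DataFrame:
    """Cross-validated accuracy as a function of the number of selected features.

    For each k the VIP ranking is recomputed on the training folds only and the
    classifier sees just the top-k features (``leaky=True`` instead ranks once
    on the whole dataset, reproducing the simpler historical workflow).
    Returns a table (k, mean_accuracy_pct, sd_accuracy_pct).
    """
    from .classify import train_eval  # local import to avoid a cycle

    if not len(ks):
        raise ValueError("ks must be nonempty")
    ranking_full = rank_features(X, y, n_components) if leaky else None
    rows = []
    for k in ks:
        if k > X.shape[1]:
            raise ValueError(f"k={k} exceeds {X.shape[1]} features")
        if leaky:
            sel = ranking_full.top(k)
            res = train_eval(X[:, sel], y, folds=folds, seed=seed, **svm_kwargs)
        else:
            res = train_eval(
                X, y, folds=folds, seed=seed,
                selector=lambda Xtr, ytr, k=k: rank_features(Xtr, ytr, n_components).top(k),
                **svm_kwargs,
            )
        rows.append({"k": k, "mean_accuracy_pct": res.mean_pct, "sd_accuracy_pct": res.sd_pct})
    return pd.DataFrame(rows)
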
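"""Model/Results interface tying the analysis together.

`ConnectivityModel` holds one measurement's feature table (built from epochs
or recordings); `fit()` runs the full protocol — cross-validated SVM accuracy,
SIMPLS fit with VIP feature ranking, and per-feature group comparison of the
selected correlations — and returns a `ConnectivityResults` with a summary()
table. Typical use::

    from eegconn import simulate, preprocess, ConnectivityModel

    recs = simulate.simulate_dataset(simulate.study_config(seed=1))
    epochs = preprocess.assemble_dataset(recs)
    res = ConnectivityModel.from_epochs(epochs, measurement="overall").fit(seed=1)
    print(res.summary())
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import CVResult, train_eval
from .compare import compare_selected
from .connectivity import FeatureTable, build_feature_table
from .pls import PLSModel, VIPRanking, rank_features, simpls_fit, sweep_k, vip_scores
from .preprocess import EpochSet


class ConnectivityModel:
    """Group-discrimination analysis of one connectivity measurement.

    Parameters
    ----------
    table : FeatureTable
        Epoch-level features (correlation pairs or channel energies) with
        group labels (1 = trained, 0 = baseline).
    n_components : int
        Number of PLS latent components for VIP scoring (default 5).
    """

    def __init__(self, table: FeatureTable, n_components: int = 5):
        self.table = table
        self.n_components = n_components

    @classmethod
    def from_epochs(
        cls,
        epochs: EpochSet,
        measurement: str = "overall",
        n_components: int = 5,
        band_cache: Optional[Dict[str, np.ndarray]] = None,
    ) -> "ConnectivityModel":
        return cls(build_feature_table(epochs, measurement, band_cache=band_cache),
                   n_components=n_components)

    @classmethod
    def from_recordings(
        cls,
        recordings,
        measurement: str = "overall",
        n_components: int = 5,
        **preprocess_kwargs,
    ) -> "ConnectivityModel":
        from .preprocess import assemble_dataset

        return cls.from_epochs(assemble_dataset(recordings, **preprocess_kwargs),
                               measurement=measurement, n_components=n_components)

    def fit(
        self,
        k_select: int = 10,
        folds: int = 10,
        seed: int = 0,
        kernel: str = "poly",
        degree: int = 3,
        C: float = 1.0,
        alpha: float = 0.05,
        ks: Optional[Sequence[int]] = None,
    ) -> "ConnectivityResults":
        """Run CV classification, PLS-VIP ranking/selection and group comparison.

        ``ks`` optionally adds a leakage-free accuracy sweep over feature
        counts (e.g. (6, 8, 10, 12, 14)).
        """
        X, y = self.table.X, self.table.labels
        cv_full = train_eval(X, y, kernel=kernel, degree=degree, C=C,
                             folds=folds, seed=seed,
                             measurement=self.table.measurement)
        pls_model = simpls_fit(X, y, self.n_components)
        ranking = vip_scores(pls_model)
        k_select = min(k_select, self.table.n_features)
        cv_selected = train_eval(
            X, y, kernel=kernel, degree=degree, C=C, folds=folds, seed=seed,
            selector=lambda Xtr, ytr: rank_features(Xtr, ytr, self.n_components).top(k_select),
            measurement=f"{self.table.measurement}_top{k_select}",
        )
        comparison = compare_selected(self.table, ranking, k=k_select, alpha=alpha)
        sweep = None
        if ks is not None:
            sweep = sweep_k(X, y, ks, n_components=self.n_components, folds=folds,
                            seed=seed, kernel=kernel, degree=degree, C=C)
        return ConnectivityResults(
            model=self, pls=pls_model, ranking=ranking, cv_full=cv_full,
            cv_selected=cv_selected, comparison=comparison, sweep=sweep,
            k_select=k_select, seed=seed,
        )


@dataclasses.dataclass
class ConnectivityResults:
    """Fit artefacts: PLS decomposition, VIP ranking, CV accuracies,
    per-feature group comparison, optional k sweep."""

    model: ConnectivityModel
    pls: PLSModel
    ranking: VIPRanking
    cv_full: CVResult
    cv_selected: CVResult
    comparison: pd.DataFrame
    sweep: Optional[pd.DataFrame]
    k_select: int
    seed: int

    @property
    def accuracy_pct(self) -> float:
        """Mean CV accuracy (%) on all features."""
        return self.cv_full.mean_pct

    @property
    def accuracy_selected_pct(self) -> float:
        """Mean CV accuracy (%) with per-fold VIP top-k selection."""
        return self.cv_selected.mean_pct

    def summary(self) -> str:
        t = self.model.table
        lines = [
            "Interregional EEG correlation analysis",
            "=" * 54,
            f"measurement:        {t.measurement}",
            f"samples (epochs):   {t.X.shape[0]}  "
            f"(group 1: {int((t.labels == 1).sum())}, group 0: {int((t.labels == 0).sum())})",
            f"features:           {t.n_features}",
            f"PLS components:     {self.pls.n_components}",
            f"CV accuracy (all features):   {self.cv_full.mean_pct:6.2f} +/- {self.cv_full.sd_pct:.2f} %",
            f"CV accuracy (top {self.k_select:>2} by VIP): {self.cv_selected.mean_pct:6.2f} +/- {self.cv_selected.sd_pct:.2f} %",
            "",
            f"Top {self.k_select} features by VIP (group means are mean |r|):",
        ]
        cols = ["rank", "feature_index", "lead_pair", "vip_score",
                "mean_abs_r_group1", "mean_abs_r_group0", "p_value", "direction",
                "retained"]
        lines.append(
            self.comparison[cols].to_string(
                index=False,
                formatters={
                    "vip_score": "{:.3f}".format,
                    "mean_abs_r_group1": "{:.3f}".format,
                    "mean_abs_r_group0": "{:.3f}".format,
                    "p_value": "{:.2e}".format,
                },
            )
        )
        if self.sweep is not None:
            lines += ["", "Accuracy vs number of selected features:",
                      self.sweep.to_string(index=False,
                                           float_format="{:.2f}".format)]
        return "\n".join(lines)

    def plot_selected_edges(self, ax=None):
        """Bar chart of trained vs baseline mean |r| for the selected edges."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        c = self.comparison
        x = np.arange(len(c))
        ax.bar(x - 0.2, c["mean_abs_r_group1"], width=0.4, label="trained")
        ax.bar(x + 0.2, c["mean_abs_r_group0"], width=0.4, label="baseline")
        ax.set_xticks(x, c["lead_pair"], rotation=45, ha="right")
        ax.set_ylabel("mean |r|")
        ax.set_title(f"Selected {self.model.table.measurement} correlations")
        ax.legend()
        return ax
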
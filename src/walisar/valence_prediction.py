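"""Latent-variable prediction of odor valence from receptor-neuron activity.

An odor panel is a matrix of per-odor firing rates across ORN classes
together with a behavioral valence score per odor.  Because the panel has
far more odors than ORN classes and the classes are internally
correlated, the feature space is first reduced by a supervised latent
projection (PLS-DA: partial least squares against class membership, with
classes derived from the valence sign), and valence is then regressed on
the latent-variable (LV) scores with linear or kernel regressors.
Generalisation error comes from shuffled-split cross-validation in which
the latent projection is refit inside every training split, so held-out
odors never influence the projection.  Odors can be re-weighted by the
absolute correlation between their firing profile and the per-ORN
single-class valences, emphasising odors whose activity pattern is
consistent with the single-channel screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR

__all__ = [
    "OdorPanel",
    "LatentModel",
    "exploratory_structure",
    "fit_latent_model",
    "regress_valence",
    "cross_validate",
    "correlation_weights",
    "learning_curve",
]


@dataclass
class OdorPanel:
    """Odors × ORN firing rates with per-odor valence and weights."""

    firing: pd.DataFrame  # rows odors, columns ORN classes (spikes/s)
    valence: pd.Series
    class_label: pd.Series | None = None
    sample_weight: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.firing) != len(self.valence):
            raise ValueError("firing rows and valence length must match")
        if self.class_label is None:
            self.class_label = pd.Series(
                np.where(self.valence >= 0, "attractive", "aversive"),
                index=self.firing.index, name="class_label",
            )
        if self.sample_weight is None:
            self.sample_weight = pd.Series(1.0, index=self.firing.index,
                                           name="sample_weight")
        if (self.sample_weight < 0).any():
            raise ValueError("sample weights must be nonnegative")


@dataclass
class LatentModel:
    """Fitted supervised latent projection plus per-odor LV scores."""

    n_components: int
    pls: PLSRegression
    scores: np.ndarray  # odors × n_components
    classes: np.ndarray

    def transform(self, firing: np.ndarray) -> np.ndarray:
        return self.pls.transform(np.asarray(firing, dtype=float))


def exploratory_structure(panel: OdorPanel):
    """Pearson correlation among ORN classes + average-linkage cluster tree.

    Returns ``(corr, tree)`` where ``tree`` is a scipy linkage matrix on
    correlation distance (1 − r).  Constant ORN columns yield undefined
    correlations and are flagged with a warning (NaNs retained in the
    matrix; such columns are excluded from the tree).
    """
    if len(panel.firing) < 3:
        raise ValueError("need at least 3 odors")
    corr = panel.firing.corr()
    const = corr.isna().all(axis=1)
    if const.any():
        warnings.warn(f"constant ORN columns with undefined correlations: "
                      f"{list(corr.index[const])}")
    ok = corr.loc[~const, ~const]
    dist = squareform(np.clip(1.0 - ok.to_numpy(), 0.0, 2.0), checks=False)
    tree = linkage(dist, method="average")
    return corr, tree


def fit_latent_model(panel: OdorPanel, n_components: int = 8) -> LatentModel:
    """Supervised latent projection (PLS-DA, class-indicator form).

    Columns are mean-centred and unit-scaled inside the PLS fit; the
    response is the one-hot class-membership matrix, so components
    maximise covariance with class separation.
    """
    if n_components < 1 or n_components > panel.firing.shape[1]:
        raise ValueError("n_components must be in [1, n ORN classes]")
    classes = np.unique(panel.class_label)
    if classes.size < 2:
        raise ValueError("PLS-DA needs at least two classes")
    Y = pd.get_dummies(panel.class_label).to_numpy(dtype=float)
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(panel.firing.to_numpy(dtype=float), Y)
    scores = pls.transform(panel.firing.to_numpy(dtype=float))
    return LatentModel(n_components=n_components, pls=pls,
                       scores=scores, classes=classes)


def _make_regressor(name: str):
    if name == "linear":
        return LinearRegression()
    kernels = {"svr_linear": "linear", "svr_poly": "poly", "svr_rbf": "rbf"}
    if name in kernels:
        return SVR(kernel=kernels[name])
    raise ValueError(f"unknown regressor {name!r}")


def adjusted_r2(r2: float, n: int, p: int) -> float:
    if n <= p + 1:
        raise ValueError("adjusted R² undefined for n <= p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def regress_valence(
    model: LatentModel,
    panel: OdorPanel,
    regressor: str = "linear",
    weights_on: bool = False,
):
    """Regress valence on LV scores; returns (fitted regressor, adjusted R²)."""
    reg = _make_regressor(regressor)
    y = panel.valence.to_numpy(dtype=float)
    w = panel.sample_weight.to_numpy(dtype=float) if weights_on else None
    reg.fit(model.scores, y, sample_weight=w)
    pred = reg.predict(model.scores)
    ss_res = np.sum((y - pred) ** 2) if w is None else np.sum(w * (y - pred) ** 2)
    if w is None:
        ss_tot = np.sum((y - y.mean()) ** 2)
    else:
        ybar = np.average(y, weights=w)
        ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    return reg, adjusted_r2(r2, y.size, model.n_components)


def cross_validate(
    panel: OdorPanel,
    n_components: int = 8,
    regressor: str = "linear",
    weights_on: bool = False,
    folds: int = 10,
    test_size: float = 0.1,
    seed: int = 0,
    max_redraws: int = 20,
):
    """Shuffled-split cross-validated RMSE with no projection leakage.

    ``folds`` random train/test splits (default ten 90/10 splits); the
    latent projection *and* the regressor are refit on each training
    split only.  A split whose training part lacks a class is redrawn a
    bounded number of times.
    """
    n = len(panel.firing)
    if n < folds:
        raise ValueError("need at least as many odors as folds")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_size * n)))
    X = panel.firing
    rmses = []
    for _ in range(folds):
        for _attempt in range(max_redraws):
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if np.unique(panel.class_label.iloc[train_idx]).size >= 2:
                break
        else:
            raise RuntimeError("could not draw a training split with both classes")
        sub = OdorPanel(
            firing=X.iloc[train_idx],
            valence=panel.valence.iloc[train_idx],
            class_label=panel.class_label.iloc[train_idx],
            sample_weight=panel.sample_weight.iloc[train_idx],
        )
        lm = fit_latent_model(sub, n_components=n_components)
        reg = _make_regressor(regressor)
        w = sub.sample_weight.to_numpy(dtype=float) if weights_on else None
        reg.fit(lm.scores, sub.valence.to_numpy(dtype=float), sample_weight=w)
        pred = reg.predict(lm.transform(X.iloc[test_idx].to_numpy(dtype=float)))
        err = panel.valence.iloc[test_idx].to_numpy(dtype=float) - pred
        rmses.append(float(np.sqrt(np.mean(err ** 2))))
    rmses = np.asarray(rmses)
    return rmses, float(rmses.mean()), float(rmses.std(ddof=1))


def correlation_weights(firing: pd.DataFrame, orn_valences) -> pd.Series:
    """Per-odor |Pearson r| between its firing profile and the ORN valences.

    ``orn_valences`` holds one single-class valence per ORN column (from
    the single-channel screen).  Odors whose activity pattern tracks the
    screen valences get weight near 1; orthogonal patterns get near 0.
    """
    v = np.asarray(orn_valences, dtype=float)
    if v.size != firing.shape[1]:
        raise ValueError("need one valence per ORN column")
    weights = np.zeros(len(firing))
    for i, (_, row) in enumerate(firing.iterrows()):
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"constant firing profile for odor {firing.index[i]!r}; "
                          "weight set to 0")
            continue
        weights[i] = abs(stats.pearsonr(x, v).statistic)
    return pd.Series(weights, index=firing.index, name="sample_weight")


def learning_curve(
    panel: OdorPanel,
    train_sizes,
    n_components: int = 8,
    regressor: str = "linear",
    seed: int = 0,
    n_repeats: int = 5,
    val_fraction: float = 0.2,
) -> pd.DataFrame:
    """Train/validation RMSE at increasing training-set sizes.

    At each size, repeats draw a random validation share and a training
    subset of that size; the latent projection and regressor are refit
    per draw.  Widening train–validation gaps at small sizes indicate
    overfitting.
    """
    n = len(panel.firing)
    n_val = max(1, int(round(val_fraction * n)))
    if max(train_sizes) > n - n_val:
        raise ValueError("train size exceeds available odors after validation share")
    rng = np.random.default_rng(seed)
    rows = []
    for size in train_sizes:
        for rep in range(n_repeats):
            for _ in range(20):
                perm = rng.permutation(n)
                val_idx, pool = perm[:n_val], perm[n_val:]
                train_idx = pool[:size]
                if np.unique(panel.class_label.iloc[train_idx]).size >= 2:
                    break
            sub = OdorPanel(
                firing=panel.firing.iloc[train_idx],
                valence=panel.valence.iloc[train_idx],
                class_label=panel.class_label.iloc[train_idx],
            )
            k = min(n_components, len(train_idx) - 1, sub.firing.shape[1])
            lm = fit_latent_model(sub, n_components=k)
            reg = _make_regressor(regressor)
            reg.fit(lm.scores, sub.valence.to_numpy(dtype=float))
            tr_pred = reg.predict(lm.scores)
            tr_rmse = float(np.sqrt(np.mean(
                (sub.valence.to_numpy(dtype=float) - tr_pred) ** 2)))
            va_pred = reg.predict(lm.transform(
                panel.firing.iloc[val_idx].to_numpy(dtype=float)))
            va_rmse = float(np.sqrt(np.mean(
                (panel.valence.iloc[val_idx].to_numpy(dtype=float) - va_pred) ** 2)))
            rows.append(dict(train_size=size, repeat=rep,
                             train_rmse=tr_rmse, val_rmse=va_rmse))
    return pd.DataFrame(rows)
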
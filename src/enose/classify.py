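"""Classifier suite, cross-validated evaluation, and PCA projection.

Five scikit-learn models are compared for odor discrimination: Gaussian
naive Bayes, L2 logistic regression, a 100-tree Gini random forest, a small
MLP, and an RBF-kernel SVM.  Two named hyperparameter variants ship:

* ``default`` — the scikit-learn library defaults,
* ``compact``  — the MLP with one hidden layer of 5 relu units trained
  by lbfgs (the compact edge-friendly network); identical to the default
  for the other models.

Evaluation is stratified 5-fold cross-validation reporting plain mean
accuracy.  When SMOTE balancing is requested, synthetic rows are by default
generated inside each training fold only, so no synthetic point derived
from a test row ever reaches training (``smote_mode="pooled"`` reproduces
augment-then-split instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .augment import SmoteConfig, smote_augment
from .indicators import TABLE_ORDER, build_feature_table, feature_matrix

MODEL_NAMES = ("naive_bayes", "logistic_regression", "random_forest",
               "mlp", "svm")

#: Display names used in rendered accuracy tables.
MODEL_LABELS = {
    "naive_bayes": "Naive Bayes",
    "logistic_regression": "Logistic regress.",
    "random_forest": "Random forest",
    "mlp": "MLP Classifier",
    "svm": "SVM Classifier",
}


@dataclass(frozen=True)
class ModelSpec:
    name: str
    variant: str = "default"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.name!r}; valid names: {MODEL_NAMES}"
            )
        if self.variant not in ("default", "compact"):
            raise ValueError(
                f"unknown variant {self.variant!r}; use 'default' "
                f"or 'compact'"
            )


def make_classifier(spec: ModelSpec, seed: int = 0):
    """Build the configured scikit-learn estimator (stochastic ones seeded)."""
    name, variant = spec.name, spec.variant
    if name == "naive_bayes":
        est = GaussianNB(priors=None, var_smoothing=1e-9)
    elif name == "logistic_regression":
        est = LogisticRegression(
            penalty="l2", C=1.0, solver="lbfgs", max_iter=100,
            random_state=seed,
        )
    elif name == "random_forest":
        est = RandomForestClassifier(
            n_estimators=100, criterion="gini", max_features="sqrt",
            bootstrap=True, random_state=seed,
        )
    elif name == "mlp":
        if variant == "compact":
            est = MLPClassifier(
                hidden_layer_sizes=(5,), activation="relu", solver="lbfgs",
                max_iter=200, random_state=seed,
            )
        else:
            est = MLPClassifier(
                hidden_layer_sizes=(100,), activation="relu", solver="adam",
                alpha=1e-4, learning_rate_init=1e-3, max_iter=200,
                random_state=seed,
            )
    elif name == "svm":
        est = SVC(
            C=1.0, kernel="rbf", degree=3, gamma="scale",
            decision_function_shape="ovr", random_state=seed,
        )
    est.set_params(**spec.hyperparameters)
    return est


def evaluate_cv(
    table: pd.DataFrame,
    spec: ModelSpec,
    folds: int = 5,
    seed: int = 0,
    smote: SmoteConfig | None = None,
    smote_mode: str = "fold",
) -> float:
    """Stratified K-fold mean accuracy of one model on one feature table.

    Folds are computed over the real rows; pre-existing synthetic rows join
    every training fold but never a test fold (``smote_mode="fold"``,
    default) or are pooled into the split (``smote_mode="pooled"``).  A
    fresh :class:`SmoteConfig` triggers per-fold augmentation of the
    training rows.
    """
    if smote_mode not in ("fold", "pooled"):
        raise ValueError("smote_mode must be 'fold' or 'pooled'")
    prov = table["provenance"].to_numpy()
    if smote_mode == "pooled":
        real = table
        extra = table.iloc[0:0]
    else:
        real = table.loc[prov == "real"]
        extra = table.loc[prov == "synthetic"]

    y = real["label"].to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        small = counts[counts < folds]
        raise ValueError(
            f"classes with fewer than {folds} rows: "
            f"{small.to_dict()}; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    X = feature_matrix(real)
    accs = []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        train = real.iloc[tr]
        if not extra.empty:
            train = pd.concat([train, extra], ignore_index=True)
        if smote is not None:
            train = smote_augment(
                train, cfg=SmoteConfig(
                    smote.k_neighbors, smote.target_ratio,
                    smote.seed + k,
                )
            )
        est = make_classifier(spec, seed=seed)
        est.fit(feature_matrix(train), train["label"].to_numpy())
        accs.append(float(np.mean(est.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def build_indicator_table(
    signals: list,
    indicators=TABLE_ORDER,
    specs=None,
    folds: int = 5,
    seed: int = 0,
    smote: SmoteConfig | None = None,
) -> pd.DataFrame:
    """Model-by-indicator mean-CV-accuracy table with Average row/column.

    Rows are models, columns the session-granularity indicators (partial
    exposure means first) plus their arithmetic row mean; a final row holds
    per-indicator column means.
    """
    specs = specs or [ModelSpec(n) for n in MODEL_NAMES]
    tables = {}
    for ind in indicators:
        try:
            tables[ind] = build_feature_table(signals, ind, "session")
        except ValueError as exc:
            raise ValueError(f"indicator {ind}: {exc}") from exc
    rows = {}
    for spec in specs:
        row = {}
        for ind in indicators:
            try:
                row[ind] = evaluate_cv(
                    tables[ind], spec, folds=folds, seed=seed, smote=smote
                )
            except ValueError as exc:
                raise ValueError(f"({spec.name}, {ind}): {exc}") from exc
        rows[MODEL_LABELS.get(spec.name, spec.name)] = row
    df = pd.DataFrame(rows).T[list(indicators)]
    df["Average"] = df.mean(axis=1)
    df.loc["Average"] = df.mean(axis=0)
    return df


def pca_project(table: pd.DataFrame, n_components: int = 2):
    """Scores and explained variance of mean-centred PCA on a feature table.

    Returns ``(scores, explained_variance, components)`` with orthonormal
    component loadings and non-increasing explained variance.
    """
    X = feature_matrix(table)
    if n_components > X.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds feature count {X.shape[1]}"
        )
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds data rank {rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_, pca.components_
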
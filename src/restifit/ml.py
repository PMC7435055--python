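"""Unsupervised and supervised analysis of the cohort feature table.

PCA of the standardized 13-parameter table surfaces correlations among
the fitted features (biplot material); random-forest regression then
predicts each cellular-behavior parameter (repair rate, detachment
time, drift speed, exfoliation rate, maximal distance) from the eight
actin parameters, and impurity-based (Gini) variable importance —
rescaled so the top predictor scores 100 — ranks which aspects of actin
dynamics carry the information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .fitting import PARAM_NAMES
from .synthetic import ACTIN_PARAMS, BEHAVIOR_PARAMS

__all__ = [
    "PCAResult",
    "SplitConfig",
    "ImportanceResult",
    "run_pca",
    "fit_forest",
    "importance_report",
]

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Scores (organoid × PC), loadings (feature × PC) and variance ratios."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


@dataclass(frozen=True)
class SplitConfig:
    """Train/validation split and forest settings."""

    validation_fraction: float = 0.25
    n_estimators: int = 100
    seed: int = 0


@dataclass
class ImportanceResult:
    """Forest fit quality and scaled Gini importances for one response."""

    response: str
    r2_train: float
    r2_validation: float
    importances: dict[str, float]
    n_train: int
    n_validation: int


def _complete_rows(cohort: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    sub = cohort[columns].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        logger.info("dropped %d rows with missing values", dropped)
    return complete


def run_pca(
    cohort: pd.DataFrame,
    parameters: tuple[str, ...] = PARAM_NAMES,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the standardized feature table.

    All features are scaled to zero mean and unit variance first;
    constant columns carry no information and are dropped with a
    warning.  Scores and loadings are indexed for direct biplotting.
    """
    cols = [p for p in parameters if p in cohort.columns]
    data = _complete_rows(cohort, cols)
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows for PCA")
    keep = [c for c in data.columns if data[c].nunique() > 1]
    if len(keep) < len(data.columns):
        logger.warning(
            "dropping constant feature columns %s", sorted(set(data.columns) - set(keep))
        )
    data = data[keep]
    X = StandardScaler().fit_transform(data.to_numpy())
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    comps = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=data.index, columns=comps),
        loadings=pd.DataFrame(pca.components_.T, index=keep, columns=comps),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def _split_indices(n: int, config: SplitConfig):
    return train_test_split(
        np.arange(n),
        test_size=config.validation_fraction,
        random_state=config.seed,
        shuffle=True,
    )


def fit_forest(
    cohort: pd.DataFrame,
    response: str,
    split: SplitConfig | None = None,
    predictors: tuple[str, ...] = ACTIN_PARAMS,
    _indices: tuple[np.ndarray, np.ndarray] | None = None,
) -> ImportanceResult:
    """Random-forest regression of one behavior parameter on actin features.

    The pooled cohort (all treatment groups plus controls) is split into
    training and validation sets; the forest (100 trees, unlimited
    depth, fixed seed) reports R² on both splits and per-predictor Gini
    importance scaled so the maximum equals 100.
    """
    split = split or SplitConfig()
    if response not in cohort.columns:
        raise ValueError(f"unknown response {response!r}")
    cols = list(predictors) + [response]
    data = _complete_rows(cohort, cols)
    n_min = max(8, int(np.ceil(2.0 / max(split.validation_fraction, 1e-9))))
    if len(data) < n_min:
        raise ValueError(f"need at least {n_min} complete rows, got {len(data)}")
    X = data[list(predictors)].to_numpy()
    y = data[response].to_numpy()
    idx_train, idx_val = (
        _indices if _indices is not None else _split_indices(len(data), split)
    )
    forest = RandomForestRegressor(
        n_estimators=split.n_estimators, random_state=split.seed
    )
    forest.fit(X[idx_train], y[idx_train])
    raw = forest.feature_importances_
    top = raw.max()
    scaled = raw / top * 100.0 if top > 0 else raw
    return ImportanceResult(
        response=response,
        r2_train=float(forest.score(X[idx_train], y[idx_train])),
        r2_validation=float(forest.score(X[idx_val], y[idx_val])),
        importances=dict(zip(predictors, scaled.astype(float))),
        n_train=len(idx_train),
        n_validation=len(idx_val),
    )


def importance_report(
    cohort: pd.DataFrame,
    split: SplitConfig | None = None,
    responses: tuple[str, ...] = BEHAVIOR_PARAMS,
    predictors: tuple[str, ...] = ACTIN_PARAMS,
) -> list[ImportanceResult]:
    """`fit_forest` for every behavior parameter with one shared split."""
    split = split or SplitConfig()
    cols = list(predictors) + list(responses)
    data = _complete_rows(cohort, cols)
    indices = _split_indices(len(data), split)
    return [
        fit_forest(data, response, split, predictors, _indices=indices)
        for response in responses
    ]


def importance_frame(results: list[ImportanceResult]) -> pd.DataFrame:
    """Long-format table of the importance report (for CSV export)."""
    rows = []
    for res in results:
        for predictor, score in res.importances.items():
            rows.append(
                {
                    "response": res.response,
                    "predictor": predictor,
                    "importance": score,
                    "r2_train": res.r2_train,
                    "r2_validation": res.r2_validation,
                }
            )
    return pd.DataFrame(rows)
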
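"""Random-forest selection of time-discriminatory biomarker taxa.

Family-level relative abundances are regressed against successional time
(era encoded as its age midpoint in years) with a random-forest regressor.
Importance is permutation importance (mean increase in MSE when a family's
values are shuffled), the regression analog of the classic %IncMSE measure.
A cross-validated feature-elimination curve (iteratively retaining the top
fraction of families by importance) locates the point where prediction
error stabilizes, and the top-k families are reported as biomarkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold

from .containers import ERA_AGE_BINS, CommunityMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "era_midpoint_response",
    "ImportanceRanking",
    "CvCurve",
    "fit_importance",
    "cv_feature_curve",
    "select_biomarkers",
]


def era_midpoint_response(samples: pd.DataFrame) -> pd.Series:
    """Encode each sample's era as its age midpoint in years (ordinal)."""
    mid = {era: 0.5 * (lo + hi) for era, (lo, hi) in ERA_AGE_BINS.items()}
    return samples["era"].map(mid).astype(float)


@dataclass
class ImportanceRanking:
    """Families ordered by descending time-discriminatory importance."""

    ranking: pd.DataFrame  # family, importance (descending)
    method: str
    n_trees: int
    seed: int | None

    @property
    def families(self) -> list:
        return list(self.ranking["family"])


@dataclass
class CvCurve:
    """Cross-validation MSE along a descending feature-count ladder."""

    curve: pd.DataFrame  # n_features (descending), cv_mse
    folds: int
    seed: int | None


def _forest(n_trees: int, seed: int | None) -> RandomForestRegressor:
    # regression defaults of the classic implementation: mtry = p/3
    return RandomForestRegressor(
        n_estimators=n_trees, max_features=1.0 / 3.0, random_state=seed
    )


def _xy(m_family: CommunityMatrix, response) -> tuple[pd.DataFrame, np.ndarray]:
    x = m_family.relative().data
    if isinstance(response, pd.Series):
        y = response.loc[x.index].to_numpy(dtype=float)
    else:
        y = np.asarray(response, dtype=float)
        if y.shape[0] != len(x):
            raise ValidationError("response length does not match sample count")
    if np.unique(y).size < 2:
        raise ValidationError("response is constant; nothing to discriminate")
    return x, y


def _rank_frame(x: pd.DataFrame, y: np.ndarray, n_trees: int,
                seed: int | None, n_repeats: int) -> pd.DataFrame:
    model = _forest(n_trees, seed).fit(x.to_numpy(), y)
    imp = permutation_importance(
        model, x.to_numpy(), y,
        scoring="neg_mean_squared_error",
        n_repeats=n_repeats, random_state=seed,
    )
    return (
        pd.DataFrame({"family": x.columns, "importance": imp.importances_mean})
        .sort_values(["importance", "family"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


def fit_importance(
    m_family: CommunityMatrix,
    response,
    n_trees: int = 500,
    seed: int | None = None,
    n_repeats: int = 10,
) -> ImportanceRanking:
    """Fit the forest and rank families by permutation importance.

    Importance is the mean increase in MSE over ``n_repeats`` shuffles of
    each family's column, evaluated on the fitted data (deterministic given
    ``seed``).  Noise families collapse toward zero; duplicating a noise
    family does not displace real signal.
    """
    x, y = _xy(m_family, response)
    ranking = _rank_frame(x, y, n_trees, seed, n_repeats)
    return ImportanceRanking(ranking, "permutation (mean increase in MSE)",
                             n_trees, seed)


def cv_feature_curve(
    m_family: CommunityMatrix,
    response,
    folds: int = 10,
    step: float = 0.5,
    n_trees: int = 500,
    seed: int | None = None,
) -> CvCurve:
    """Feature-elimination curve of k-fold cross-validation error.

    Starting from all families, the feature set is repeatedly reduced to the
    top ``step`` fraction by importance (re-ranked at each stage on the
    retained set), recording the k-fold CV mean squared error at each
    feature count.  The ladder is strictly decreasing down to one family.
    """
    x, y = _xy(m_family, response)
    if folds > len(x):
        raise ValidationError("more folds than samples")
    if not (0 < step < 1):
        raise ValidationError("step must be in (0, 1)")
    features = list(x.columns)
    rows = []
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(x))
    while True:
        xs = x[features].to_numpy()
        sq_err = np.empty(len(x))
        for train, test in splits:
            model = _forest(n_trees, seed).fit(xs[train], y[train])
            sq_err[test] = (model.predict(xs[test]) - y[test]) ** 2
        rows.append((len(features), float(sq_err.mean())))
        if len(features) == 1:
            break
        ranking = _rank_frame(x[features], y, n_trees, seed, n_repeats=5)
        n_keep = max(1, int(np.floor(len(features) * step)))
        features = list(ranking["family"])[:n_keep]
    curve = pd.DataFrame(rows, columns=["n_features", "cv_mse"])
    assert curve["n_features"].is_monotonic_decreasing
    return CvCurve(curve, folds, seed)


def select_biomarkers(
    ranking: ImportanceRanking,
    curve: CvCurve | None = None,
    k: int | str = 13,
    tolerance: float = 0.05,
) -> list:
    """Top-k biomarker families, or ``k="auto"`` from the CV curve.

    Auto selection returns the smallest ladder point whose CV error is
    within ``tolerance`` (relative) of the curve minimum — the point where
    the error curve has stabilized.
    """
    families = ranking.families
    if k == "auto":
        if curve is None:
            raise ValidationError("auto selection needs a CV curve")
        c = curve.curve.sort_values("n_features")
        best = c["cv_mse"].min()
        ok = c[c["cv_mse"] <= best * (1.0 + tolerance)]
        k = int(ok["n_features"].iloc[0])
        logger.info("select_biomarkers: auto k=%d (cv stabilization)", k)
    k = int(k)
    if k < 1 or k > len(families):
        raise ValidationError(f"k={k} outside [1, {len(families)}]")
    return families[:k]
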
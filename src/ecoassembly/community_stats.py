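"""Supporting community statistics around the null-model core.

Bray–Curtis dissimilarity, alpha diversity (observed richness, Chao1,
Shannon in nats, Faith's PD), NMDS ordination, PERMANOVA, Mantel tests of
turnover against environmental variable groups, alpha–environment
correlations, and the era genus-sharing partition.  Permutation tests are
delegated to scikit-bio (seeded); NMDS to scikit-learn's non-metric MDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import chao1 as _chao1
from skbio.diversity.alpha import faith_pd as _faith_pd
from skbio.stats.distance import mantel as _mantel
from skbio.stats.distance import permanova as _permanova
from sklearn.manifold import MDS

from .containers import CommunityMatrix, PairwiseMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ENV_GROUPS",
    "TestResult",
    "OrdinationResult",
    "bray_curtis",
    "alpha_diversity",
    "nmds",
    "permanova",
    "mantel_test",
    "env_distance",
    "env_group_mantel",
    "correlate_alpha_env",
    "era_genus_sharing",
]

#: Environmental variable groups used throughout the turnover Mantel tests.
#: "soil_fertility" is the integrated fertility proxy; "redox" reflects the
#: Fe/Mn redox state; "nutrient" membership is a package default (the three
#: fertility-positive macronutrient variables), configurable by the caller.
DEFAULT_ENV_GROUPS: dict[str, tuple[str, ...]] = {
    "all": ("SOC", "TN", "TP", "Fe", "Mn", "pH", "Na", "Ca", "Cu", "K", "Mg", "Zn"),
    "soil_fertility": ("TN", "TP", "Na", "Ca", "Cu", "K", "Mg", "Zn", "SOC"),
    "nutrient": ("SOC", "TN", "TP"),
    "redox": ("Fe", "Mn"),
}


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    permutations: int

    def __str__(self) -> str:
        return (f"{self.statistic_name}={self.statistic:.4g}, "
                f"p={self.p_value:.4g} ({self.permutations} permutations)")


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples × axes, centered
    stress: float
    n_restarts: int
    converged: bool


# ---------------------------------------------------------------------------

def bray_curtis(m: CommunityMatrix) -> PairwiseMatrix:
    """Bray–Curtis dissimilarity BC(j,k) = Σ|x_j − x_k| / Σ(x_j + x_k)."""
    x = m.values()
    return PairwiseMatrix(m.sample_ids, squareform(pdist(x, metric="braycurtis")),
                          "bray_curtis")


def alpha_diversity(m: CommunityMatrix, tree: TreeNode | None = None) -> pd.DataFrame:
    """Observed richness, Chao1, Shannon (nats) and Faith's PD per sample.

    Chao1 uses the classic estimator S_obs + F1²/(2 F2) (F2 = 0 falls back
    to S_obs + F1(F1−1)/2), appropriate for rarefied counts.  Faith's PD is
    the total branch length of the minimal subtree connecting a sample's
    taxa to the root (tree required; column omitted otherwise).
    """
    if m.kind != "counts":
        raise ValidationError("alpha diversity expects (rarefied) counts")
    counts = m.values().round().astype(np.int64)
    taxa = [str(t) for t in m.taxon_ids]
    rows = {}
    rows["observed_otus"] = (counts > 0).sum(axis=1)
    rows["chao1"] = [_chao1(c, bias_corrected=False) for c in counts]
    shannon = []
    for c in counts:
        p = c[c > 0] / c.sum()
        shannon.append(float(-(p * np.log(p)).sum()))
    rows["shannon"] = shannon
    if tree is not None:
        rows["faith_pd"] = [
            float(_faith_pd(c, taxa=taxa, tree=tree)) for c in counts
        ]
    return pd.DataFrame(rows, index=m.sample_ids)


def nmds(
    d: PairwiseMatrix,
    k: int = 2,
    n_restarts: int = 10,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Kruskal stress-1 minimized over ``n_restarts`` random starts; the best
    configuration is returned centered at the origin.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=n_restarts,
        init="random",
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
    )
    coords = model.fit_transform(d.matrix)
    coords = coords - coords.mean(axis=0)
    converged = bool(model.n_iter_ < 500)
    if not converged:
        logger.warning("nmds: best restart hit the iteration cap; best effort")
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.sample_ids, columns=cols),
        stress=float(model.stress_),
        n_restarts=n_restarts,
        converged=converged,
    )


def permanova(
    d: PairwiseMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> TestResult:
    """PERMANOVA pseudo-F with a free permutation test of group labels."""
    groups = pd.Series(list(groups), index=d.sample_ids)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if (sizes < 2).any():
        raise ValidationError(f"group {sizes.idxmin()!r} has fewer than 2 samples")
    dm = DistanceMatrix(d.matrix, ids=[str(s) for s in d.sample_ids])
    res = _permanova(dm, groups.to_numpy(), permutations=n_perm, seed=seed)
    return TestResult("pseudo-F", float(res["test statistic"]),
                      float(res["p-value"]), n_perm)


def mantel_test(
    d1: PairwiseMatrix,
    d2: PairwiseMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "pearson",
) -> TestResult:
    """Mantel correlation between two sample-pair matrices (two-sided).

    Signed deviation matrices (βNTI) are accepted: the statistic is the
    correlation of the vectorized upper triangles under sample-label
    permutation, which does not require metric distances.
    """
    if d1.sample_ids != d2.sample_ids:
        raise ValidationError("Mantel test needs matching sample sets")
    a = np.nan_to_num(d1.matrix.copy())
    b = np.nan_to_num(d2.matrix.copy())
    np.fill_diagonal(a, 0.0)
    np.fill_diagonal(b, 0.0)
    for name, mat in ((d1.name, a), (d2.name, b)):
        iu = np.triu_indices(mat.shape[0], 1)
        if np.ptp(mat[iu]) == 0:
            raise ValidationError(f"constant {name} matrix in Mantel test")
    r, p, _ = _mantel(a, b, method=method, permutations=n_perm,
                      alternative="two-sided", seed=seed)
    return TestResult("mantel_r", float(r), float(p), n_perm)


def env_distance(
    env: pd.DataFrame,
    variables,
    standardize: bool = True,
) -> PairwiseMatrix:
    """Euclidean between-sample distance over (z-scored) env variables."""
    missing = [v for v in variables if v not in env.columns]
    if missing:
        raise ValidationError(f"env variables not found: {missing}")
    x = env[list(variables)].to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning("env_distance: dropping constant variable(s) %s",
                           [v for v, k in zip(variables, keep) if not k])
        if not keep.any():
            raise ValidationError("all env variables are constant")
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    return PairwiseMatrix(list(env.index), squareform(pdist(x)), "env_distance")


def env_group_mantel(
    turnover: PairwiseMatrix,
    env: pd.DataFrame,
    groups: dict[str, tuple[str, ...]] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mantel test of a turnover matrix against each env variable group.

    Returns a table (group, variables, mantel_r, p_value) matching the
    ENV-All / fertility / nutrient / redox layout of the study's tables.
    """
    groups = groups or DEFAULT_ENV_GROUPS
    env = env.loc[[str(s) for s in turnover.sample_ids]]
    rows = []
    for name, variables in groups.items():
        if not variables:
            raise ValidationError(f"env group {name!r} is empty")
        ed = env_distance(env, variables)
        ed = PairwiseMatrix(turnover.sample_ids, ed.matrix, "env_distance")
        res = mantel_test(turnover, ed, n_perm=n_perm, seed=seed)
        rows.append((name, ",".join(variables), res.statistic, res.p_value))
    return pd.DataFrame(rows, columns=["group", "variables", "mantel_r", "p_value"])


def _stars(p: float) -> str:
    return "**" if p < 0.01 else ("*" if p < 0.05 else "")


def correlate_alpha_env(
    alpha: pd.DataFrame,
    env: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate each alpha-diversity index with each env variable.

    Long format: (index, variable, r, p_value, significance) with the
    study's significance stars (* p<0.05, ** p<0.01).  Constant columns
    yield NaN with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown method {method!r}")
    env = env.loc[alpha.index]
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for idx in alpha.columns:
        a = alpha[idx].to_numpy(float)
        for var in env.columns:
            e = env[var].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(e) == 0:
                logger.warning("correlate_alpha_env: constant column %s/%s", idx, var)
                rows.append((idx, var, np.nan, np.nan, ""))
                continue
            r, p = fn(a, e)
            rows.append((idx, var, float(r), float(p), _stars(float(p))))
    return pd.DataFrame(rows, columns=["index", "variable", "r", "p_value", "significance"])


def era_genus_sharing(
    m_genus: CommunityMatrix,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """How many successional eras each genus occurs in.

    A genus is present in an era if it has count > 0 in at least one of that
    era's samples.  Returns one row per occupancy level (eras_present
    descending) with the number and percentage of genera; percentages sum
    to 100.
    """
    samples = samples.loc[[str(s) for s in m_genus.sample_ids]]
    eras = samples["era"].unique()
    presence = pd.DataFrame(
        {era: (m_genus.data.loc[samples.index[samples["era"] == era]] > 0).any(axis=0)
         for era in eras}
    )
    n_eras_present = presence.sum(axis=1)
    n_eras_present = n_eras_present[n_eras_present > 0]
    counts = n_eras_present.value_counts().reindex(
        range(len(eras), 0, -1), fill_value=0
    )
    out = pd.DataFrame(
        {
            "eras_present": counts.index,
            "n_genera": counts.to_numpy(),
            "pct_genera": 100.0 * counts.to_numpy() / counts.sum(),
        }
    ).reset_index(drop=True)
    return out
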
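"""Phylogenetic-signal verification via Mantel correlograms.

Interpreting the beta nearest taxon index as evidence of selection
presupposes phylogenetic niche conservatism: close relatives must occupy
similar environments.  This module estimates per-taxon niche optima
(abundance-weighted environmental means), builds between-taxon niche and
phylogenetic distance matrices, and relates them with a Mantel correlogram
(permutation tests, progressive Bonferroni correction across distance
classes).  Sign convention follows the standard correlogram: positive r in a
distance class means taxa in that class are more similar in niche than
expected, so significant positive r in the shortest class = conserved niches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .containers import CommunityMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "cophenetic_matrix",
    "taxon_niche_values",
    "niche_distance_matrix",
    "mantel_correlogram",
    "CorrelogramResult",
    "has_short_range_signal",
]


def cophenetic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (cophenetic) distance matrix of a tree."""
    return tree.tip_tip_distances()


def taxon_niche_values(m: CommunityMatrix, env: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon niche optima: abundance-weighted mean of each env variable.

    optimum(i, v) = sum_s f_is * env_sv / sum_s f_is, over the harmonized
    sample set.  Taxa with zero total abundance are excluded with a warning.
    """
    f = m.relative().data
    env = env.loc[f.index]
    totals = f.sum(axis=0)
    dead = totals[totals <= 0].index
    if len(dead):
        logger.warning("taxon_niche_values: excluding %d absent taxa", len(dead))
        f = f.drop(columns=dead)
        totals = totals.drop(dead)
    weights = f.div(totals, axis=1)  # samples × taxa, columns sum to 1
    return weights.T @ env  # taxa × variables


def niche_distance_matrix(
    niche: pd.DataFrame,
    variables: list[str] | None = None,
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean between-taxon distance over (optionally z-scored) optima.

    Zero-variance variables are dropped under standardization (with a
    warning) since they carry no niche information and cannot be scaled.
    """
    x = niche[list(variables)] if variables is not None else niche
    vals = x.to_numpy(dtype=float)
    if standardize:
        sd = vals.std(axis=0, ddof=1)
        flat = sd <= 0
        if flat.any():
            logger.warning(
                "niche_distance_matrix: dropping zero-variance variable(s) %s",
                list(x.columns[flat]),
            )
            vals = vals[:, ~flat]
            sd = sd[~flat]
        if vals.shape[1] == 0:
            raise ValidationError("no variables left after dropping constants")
        vals = (vals - vals.mean(axis=0)) / sd
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(vals)), ids=[str(i) for i in x.index])


@dataclass
class CorrelogramResult:
    """Mantel correlogram: per-class r, permutation p, corrected p."""

    classes: pd.DataFrame  # lower, upper, center, n_pairs, r, p, p_corrected
    n_perm: int

    def __repr__(self) -> str:  # compact table display
        return f"CorrelogramResult(n_perm={self.n_perm})\n{self.classes}"


def mantel_correlogram(
    phylo_d: DistanceMatrix,
    niche_d: DistanceMatrix,
    n_classes: int | str = "auto",
    n_perm: int = 999,
    seed: int | None = None,
) -> CorrelogramResult:
    """Mantel correlogram of niche distance against phylogenetic distance.

    Distance classes partition the observed phylogenetic-distance range into
    equal-width bins (Sturges' rule on the pair count when ``n_classes`` is
    ``"auto"``).  Per class, the Mantel statistic is the Pearson correlation
    between the niche distances and the class-membership indicator, negated
    so that positive r indicates within-class niche similarity.  p-values are
    two-sided permutation tests (taxon labels of the niche matrix permuted,
    the phylogenetic classes held fixed), corrected by progressive
    Bonferroni.  Classes with fewer than 3 pairs get NaN statistics.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    if list(phylo_d.ids) != list(niche_d.ids):
        niche_d = niche_d.filter(phylo_d.ids)  # raises if sets differ
    n = phylo_d.shape[0]
    iu = np.triu_indices(n, k=1)
    pv = phylo_d.data[iu]
    n_pairs_total = pv.size
    if n_classes == "auto":
        n_classes = int(np.ceil(1 + np.log2(n_pairs_total)))
    edges = np.linspace(pv.min(), pv.max(), int(n_classes) + 1)
    # right-inclusive bins; lowest edge inclusive
    which = np.clip(np.searchsorted(edges, pv, side="left") - 1, 0, int(n_classes) - 1)

    nich = niche_d.data
    nv = nich[iu]
    rng = np.random.default_rng(seed)

    # centered/normalized class indicators for fast correlation
    indicators = []
    counts = []
    for c in range(int(n_classes)):
        ind = (which == c).astype(float)
        counts.append(int(ind.sum()))
        ind_c = ind - ind.mean()
        norm = np.linalg.norm(ind_c)
        indicators.append(ind_c / norm if norm > 0 else np.full_like(ind_c, np.nan))
    ind_mat = np.vstack(indicators)  # n_classes × n_pairs

    def _r_all(vec: np.ndarray) -> np.ndarray:
        vc = vec - vec.mean()
        norm = np.linalg.norm(vc)
        if norm == 0:
            raise ValidationError("constant niche distance matrix")
        return -(ind_mat @ (vc / norm))

    r_obs = _r_all(nv)
    exceed = np.zeros(int(n_classes))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pv_perm = nich[perm[iu[0]], perm[iu[1]]]
        exceed += np.abs(_r_all(pv_perm)) >= np.abs(r_obs) - 1e-12
    p = (exceed + 1.0) / (n_perm + 1.0)

    valid = np.array(counts) >= 3
    r_obs = np.where(valid, r_obs, np.nan)
    p = np.where(valid, p, np.nan)
    # progressive Bonferroni: class k tested after classes 1..k-1
    p_corr = np.minimum(p * np.arange(1, int(n_classes) + 1), 1.0)
    classes = pd.DataFrame(
        {
            "lower": edges[:-1],
            "upper": edges[1:],
            "center": 0.5 * (edges[:-1] + edges[1:]),
            "n_pairs": counts,
            "r": r_obs,
            "p": p,
            "p_corrected": p_corr,
        }
    )
    assert classes["n_pairs"].sum() == n_pairs_total
    return CorrelogramResult(classes=classes, n_perm=n_perm)


def has_short_range_signal(result: CorrelogramResult, alpha: float = 0.05) -> bool:
    """True if the shortest valid distance class shows significant positive r."""
    ok = result.classes.dropna(subset=["r"])
    if ok.empty:
        return False
    first = ok.iloc[0]
    return bool(first["r"] > 0 and first["p_corrected"] <= alpha)
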
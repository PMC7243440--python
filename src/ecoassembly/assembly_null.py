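"""Phylogenetic and taxonomic null models for community assembly inference.

The core statistics:

* beta mean nearest taxon distance (βMNTD): abundance-weighted mean
  phylogenetic distance from each taxon in one community to its nearest
  relative in the other,
  βMNTD(j,k) = 0.5 [ Σ_i f_ij min_i' Δ_ii' + Σ_i f_ik min_i' Δ_ii' ].
* beta nearest taxon index (βNTI): standardized effect size of observed
  βMNTD against a "phylogeny pool" null in which each sample's observed
  abundance vector is reassigned to a uniformly random, equally rich subset
  of the regional pool's tips.  |βNTI| > 2 indicates deterministic selection
  (βNTI > +2 variable, βNTI < −2 homogeneous).
* Bray–Curtis-based Raup–Crick (RC_bray): observed Bray–Curtis compared with
  a taxonomic null that fixes each sample's richness and total abundance,
  draws taxa with probability proportional to regional occupancy and fills
  individuals proportionally to regional relative abundance; standardized to
  [−1, +1].  |RC| > 0.95 with |βNTI| < 2 separates dispersal limitation
  (RC > +0.95) from homogenizing dispersal (RC < −0.95); the remainder is
  undominated.

The regional species pool is always the union of taxa present in the
analyzed sample set, so per-timescale analyses recompute the nulls on their
own sub-dataset.  All null draws are seeded per sample pair via
counter-based substreams, making results independent of iteration order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from .containers import (
    ERA_ORDER,
    CommunityMatrix,
    PairwiseMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NullEnsembleConfig",
    "PROCESS_CLASSES",
    "beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "classify_pair",
    "classify_pairs",
    "ProcessFractions",
    "partition_processes",
    "subset_by_timescale",
    "TrendFit",
    "stochasticity_trend",
]

PROCESS_CLASSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


@dataclass
class NullEnsembleConfig:
    """Null-ensemble sizes and seeding for βNTI and RC_bray."""

    n_null_phylo: int = 1000
    n_null_rc: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null_phylo < 99 or self.n_null_rc < 99:
            raise ValidationError("null ensemble sizes must be >= 99")


def _pair_rng(seed: int, i: int, j: int, stream: int) -> np.random.Generator:
    """Independent substream for pair (i, j); order-independent."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, i, j]))


def _aligned_distances(m: CommunityMatrix, phylo_d) -> np.ndarray:
    """Distance matrix aligned to the matrix's taxon order."""
    if isinstance(phylo_d, TreeNode):
        phylo_d = phylo_d.tip_tip_distances()
    if isinstance(phylo_d, DistanceMatrix):
        ids = [str(t) for t in m.taxon_ids]
        missing = set(ids) - set(phylo_d.ids)
        if missing:
            raise ValidationError(
                f"{len(missing)} matrix taxa missing from the phylogeny "
                f"(e.g. {sorted(missing)[0]!r}); harmonize first"
            )
        return phylo_d.filter(ids).data
    d = np.asarray(phylo_d, dtype=float)
    if d.shape != (m.shape[1], m.shape[1]):
        raise ValidationError("distance matrix does not match taxon count")
    return d


# ---------------------------------------------------------------------------
# βMNTD
# ---------------------------------------------------------------------------

def _pair_beta_mntd(d: np.ndarray, tj, tk, fj, fk) -> float:
    dsub = d[np.ix_(tj, tk)]
    return 0.5 * (fj @ dsub.min(axis=1) + fk @ dsub.min(axis=0))


def beta_mntd(
    m: CommunityMatrix,
    phylo_d,
    abundance_weighted: bool = True,
) -> PairwiseMatrix:
    """Between-community mean nearest taxon distance for all sample pairs.

    Abundances are converted to per-sample relative abundances before
    weighting; taxa shared by both samples contribute a nearest distance of
    zero.  ``abundance_weighted=False`` is intentionally not implemented (the
    analysis is abundance-weighted throughout).
    """
    if not abundance_weighted:
        raise NotImplementedError("only abundance-weighted βMNTD is provided")
    d = _aligned_distances(m, phylo_d)
    f = m.relative().values()
    n = f.shape[0]
    present = [np.flatnonzero(f[i] > 0) for i in range(n)]
    for i, t in enumerate(present):
        if t.size == 0:
            raise ValidationError(f"sample {m.sample_ids[i]!r} has no taxa")
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            tj, tk = present[j], present[k]
            out[j, k] = out[k, j] = _pair_beta_mntd(d, tj, tk, f[j, tj], f[k, tk])
    return PairwiseMatrix(m.sample_ids, out, "beta_mntd")


# ---------------------------------------------------------------------------
# βNTI
# ---------------------------------------------------------------------------

def _null_subsets(rng, n_null: int, pool: int, richness: int) -> np.ndarray:
    """n_null uniformly random richness-subsets of range(pool), as an array."""
    keys = rng.random((n_null, pool))
    return np.argpartition(keys, richness - 1, axis=1)[:, :richness]


def beta_nti(
    m: CommunityMatrix,
    phylo_d,
    cfg: NullEnsembleConfig | None = None,
) -> PairwiseMatrix:
    """βNTI for all sample pairs against the phylogeny-pool null.

    Per pair, βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null over
    ``cfg.n_null_phylo`` draws; in each draw both samples independently keep
    their observed abundance vectors but are reassigned to uniformly random
    tip subsets of equal richness from the regional pool (all taxa present in
    the analyzed matrix).  Sample (n−1) standard deviation.  Pairs whose null
    has zero spread are reported NaN with a warning.
    """
    cfg = cfg or NullEnsembleConfig()
    d = _aligned_distances(m, phylo_d)
    f = m.relative().values()
    n, pool = f.shape
    present = [np.flatnonzero(f[i] > 0) for i in range(n)]
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, np.nan)
    degenerate = 0
    for j in range(n):
        for k in range(j + 1, n):
            tj, tk = present[j], present[k]
            fj, fk = f[j, tj], f[k, tk]
            obs = _pair_beta_mntd(d, tj, tk, fj, fk)
            rng = _pair_rng(cfg.seed, j, k, stream=1)
            sj = _null_subsets(rng, cfg.n_null_phylo, pool, tj.size)
            sk = _null_subsets(rng, cfg.n_null_phylo, pool, tk.size)
            nulls = np.empty(cfg.n_null_phylo)
            mask = np.zeros(pool, dtype=bool)
            for t in range(cfg.n_null_phylo):
                sjt, skt = sj[t], sk[t]
                # taxa shared by both null samples contribute distance 0
                mask[skt] = True
                need_j = ~mask[sjt]
                mask[skt] = False
                mask[sjt] = True
                need_k = ~mask[skt]
                mask[sjt] = False
                total = 0.0
                if need_j.any():
                    total += d[np.ix_(sjt[need_j], skt)].min(axis=1) @ fj[need_j]
                if need_k.any():
                    total += d[np.ix_(skt[need_k], sjt)].min(axis=1) @ fk[need_k]
                nulls[t] = 0.5 * total
            sd = nulls.std(ddof=1)
            if sd == 0:
                degenerate += 1
                continue
            out[j, k] = out[k, j] = (obs - nulls.mean()) / sd
    if degenerate:
        logger.warning("beta_nti: %d pair(s) with zero null spread -> NaN", degenerate)
    return PairwiseMatrix(m.sample_ids, out, "beta_nti")


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------

def _bray_curtis_counts(x: np.ndarray, y: np.ndarray) -> float:
    return np.abs(x - y).sum() / (x + y).sum()


def _null_sample(rng, occupancy_w, abundance_p, richness, total) -> np.ndarray:
    """One null community: occupancy-weighted taxa, abundance-filled reads."""
    # weighted sampling without replacement via exponential/Gumbel keys
    keys = rng.exponential(size=occupancy_w.size) / occupancy_w
    taxa = np.argpartition(keys, richness - 1)[:richness]
    counts = np.ones(richness, dtype=np.int64)
    if total > richness:
        p = abundance_p[taxa]
        counts += rng.multinomial(total - richness, p / p.sum())
    vec = np.zeros(occupancy_w.size, dtype=np.int64)
    vec[taxa] = counts
    return vec


def raup_crick_bray(
    m: CommunityMatrix,
    cfg: NullEnsembleConfig | None = None,
) -> PairwiseMatrix:
    """Raup–Crick deviation of Bray–Curtis from a taxonomic null, in [−1, 1].

    RC = 2·[ (#null BC < obs BC) + 0.5·(#null BC = obs BC) ] / n_null − 1.
    Null communities preserve each sample's richness and total read count;
    taxon identity is drawn ∝ regional occupancy (number of occupied
    samples), each drawn taxon receives one read, and the remaining reads are
    assigned ∝ regional relative abundance among the drawn taxa.
    """
    cfg = cfg or NullEnsembleConfig()
    if m.kind != "counts":
        raise ValidationError("raup_crick_bray requires a counts matrix")
    x = m.values().round().astype(np.int64)
    n, pool = x.shape
    occupancy = (x > 0).sum(axis=0).astype(float)
    abundance = x.sum(axis=0).astype(float)
    abundance_p = abundance / abundance.sum()
    richness = (x > 0).sum(axis=1)
    totals = x.sum(axis=1)
    if (richness > pool).any():
        raise ValidationError("sample richness exceeds pool size")
    out = np.full((n, n), np.nan)
    for j in range(n):
        for k in range(j + 1, n):
            obs = _bray_curtis_counts(x[j], x[k])
            rng = _pair_rng(cfg.seed, j, k, stream=2)
            below = 0.0
            for _ in range(cfg.n_null_rc):
                nj = _null_sample(rng, occupancy, abundance_p, richness[j], totals[j])
                nk = _null_sample(rng, occupancy, abundance_p, richness[k], totals[k])
                bc = _bray_curtis_counts(nj, nk)
                if bc < obs - 1e-12:
                    below += 1.0
                elif bc <= obs + 1e-12:
                    below += 0.5
            out[j, k] = out[k, j] = 2.0 * below / cfg.n_null_rc - 1.0
    return PairwiseMatrix(m.sample_ids, out, "rc_bray")


# ---------------------------------------------------------------------------
# classification and partitioning
# ---------------------------------------------------------------------------

def classify_pair(bnti: float, rc: float, inclusive: bool = False) -> str:
    """Map one (βNTI, RC_bray) pair to its assembly process class.

    Selection is judged on βNTI alone (> +2 variable, < −2 homogeneous);
    within |βNTI| < 2, RC > +0.95 is dispersal limitation, RC < −0.95 is
    homogenizing dispersal, and the remainder is undominated.  With the
    default strict boundaries, |βNTI| = 2 and |RC| = 0.95 exactly are
    non-significant; ``inclusive=True`` flips that convention.
    """
    if bnti is None or np.isnan(bnti):
        raise ValidationError("cannot classify a pair with undefined βNTI")
    if not (-1.0 - 1e-9 <= rc <= 1.0 + 1e-9):
        raise ValidationError(f"RC_bray {rc} outside [-1, 1]")
    sel = (abs(bnti) >= 2) if inclusive else (abs(bnti) > 2)
    if sel:
        return "variable_selection" if bnti > 0 else "homogeneous_selection"
    disp = (abs(rc) >= 0.95) if inclusive else (abs(rc) > 0.95)
    if disp:
        return "dispersal_limitation" if rc > 0 else "homogenizing_dispersal"
    return "undominated"


def classify_pairs(
    bnti: PairwiseMatrix,
    rc: PairwiseMatrix,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Long-format per-pair classification (NaN βNTI pairs excluded, logged)."""
    if bnti.sample_ids != rc.sample_ids:
        raise ValidationError("βNTI and RC matrices cover different samples")
    rows = []
    excluded = 0
    n = bnti.n
    for j in range(n):
        for k in range(j + 1, n):
            b, r = bnti.matrix[j, k], rc.matrix[j, k]
            if np.isnan(b):
                excluded += 1
                continue
            rows.append(
                (bnti.sample_ids[j], bnti.sample_ids[k], b, r,
                 classify_pair(b, r, inclusive=inclusive))
            )
    if excluded:
        logger.warning("classify_pairs: %d pair(s) excluded (βNTI undefined)", excluded)
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "beta_nti", "rc_bray", "process"]
    )


@dataclass
class ProcessFractions:
    """Relative contributions of the five assembly processes for a pair set."""

    fractions: dict[str, float]
    n_pairs: int
    n_excluded: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        total = sum(self.fractions.get(c, 0.0) for c in PROCESS_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"process fractions sum to {total}, not 1")

    @property
    def deterministic(self) -> float:
        return self.fractions["variable_selection"] + self.fractions["homogeneous_selection"]

    @property
    def stochastic(self) -> float:
        return self.fractions["dispersal_limitation"] + self.fractions["homogenizing_dispersal"]

    @property
    def undominated(self) -> float:
        return self.fractions["undominated"]

    @property
    def dominant(self) -> str:
        return max(PROCESS_CLASSES, key=lambda c: self.fractions[c])

    def to_series(self) -> pd.Series:
        s = pd.Series({c: self.fractions[c] for c in PROCESS_CLASSES})
        s["deterministic"] = self.deterministic
        s["stochastic"] = self.stochastic
        s["n_pairs"] = self.n_pairs
        return s


def partition_processes(
    bnti: PairwiseMatrix,
    rc: PairwiseMatrix,
    pair_mask: np.ndarray | None = None,
    inclusive: bool = False,
    label: str = "",
) -> ProcessFractions:
    """Fraction of sample pairs assigned to each assembly process.

    ``pair_mask`` is a boolean samples × samples matrix selecting which
    unordered pairs count (default: all).  Pairs with undefined βNTI are
    excluded from the denominator.
    """
    if bnti.sample_ids != rc.sample_ids:
        raise ValidationError("βNTI and RC matrices cover different samples")
    n = bnti.n
    if pair_mask is None:
        pair_mask = np.ones((n, n), dtype=bool)
    counts = dict.fromkeys(PROCESS_CLASSES, 0)
    excluded = 0
    for j in range(n):
        for k in range(j + 1, n):
            if not (pair_mask[j, k] or pair_mask[k, j]):
                continue
            b, r = bnti.matrix[j, k], rc.matrix[j, k]
            if np.isnan(b):
                excluded += 1
                continue
            counts[classify_pair(b, r, inclusive=inclusive)] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("no classifiable pairs selected")
    if excluded:
        logger.warning("partition_processes: %d pair(s) excluded", excluded)
    return ProcessFractions(
        fractions={c: counts[c] / total for c in PROCESS_CLASSES},
        n_pairs=total,
        n_excluded=excluded,
        label=label,
    )


# ---------------------------------------------------------------------------
# timescale subsetting
# ---------------------------------------------------------------------------

def subset_by_timescale(
    m: CommunityMatrix,
    samples: pd.DataFrame,
    mode: str,
    era: str | None = None,
    oldest_age: float | None = None,
    youngest_age: float | None = None,
    cross_pairs_only: bool = False,
):
    """Select the sub-dataset for a within-era or across-era analysis.

    Returns ``(community subset, sample subset, pair_mask)``.  Null models
    are then recomputed on the subset, whose taxon union is the regional
    pool.  ``within_era`` keeps one era's samples (all pairs);
    ``across_eras`` keeps samples with age in [youngest, oldest] and, with
    ``cross_pairs_only``, masks within-era pairs out.
    """
    samples = samples.loc[[str(s) for s in m.sample_ids]]
    if mode == "within_era":
        if era not in ERA_ORDER:
            raise ValidationError(f"unknown era {era!r}")
        keep = samples.index[samples["era"] == era]
        if len(keep) < 2:
            raise ValidationError(f"era {era!r} has fewer than 2 samples")
        sub = m.select_samples(keep)
        mask = np.ones((len(keep), len(keep)), dtype=bool)
        return sub, samples.loc[keep], mask
    if mode != "across_eras":
        raise ValidationError(f"unknown mode {mode!r}")
    if oldest_age is None or youngest_age is None:
        raise ValidationError("across_eras needs oldest_age and youngest_age")
    age = samples["age_years"].astype(float)
    keep = samples.index[(age >= youngest_age) & (age <= oldest_age)]
    eras = samples.loc[keep, "era"].unique()
    if len(eras) < 2:
        raise ValidationError("across-era span must contain at least 2 eras")
    sub = m.select_samples(keep)
    sf = samples.loc[keep]
    if cross_pairs_only:
        era_arr = sf["era"].to_numpy()
        mask = era_arr[:, None] != era_arr[None, :]
    else:
        mask = np.ones((len(keep), len(keep)), dtype=bool)
    return sub, sf, mask


# ---------------------------------------------------------------------------
# stochasticity trend
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    """OLS fit of stochastic fraction against successional timescale."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    points: pd.DataFrame = field(repr=False, default=None)


def stochasticity_trend(points) -> TrendFit:
    """Ordinary least squares of stochastic fraction on timescale span.

    ``points`` is an iterable of (span_years, stochastic_fraction); at least
    3 points with non-constant spans are required.
    """
    df = pd.DataFrame(list(points), columns=["span_years", "stochastic_fraction"])
    if len(df) < 3:
        raise ValidationError("trend fit needs at least 3 points")
    x = df["span_years"].to_numpy(float)
    y = df["stochastic_fraction"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValidationError("spans are constant; cannot fit a trend")
    fit = stats.linregress(x, y)
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(df),
        points=df,
    )
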
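"""Core in-memory containers shared by all analysis stages.

The universal currency of the package is a samples × taxa abundance matrix
(:class:`CommunityMatrix`), a rooted phylogeny over the taxa (a scikit-bio
``TreeNode``), and per-sample metadata / soil-chemistry tables (plain pandas
DataFrames indexed by sample id, validated by :mod:`ecoassembly.data_io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CommunityMatrix",
    "PairwiseMatrix",
    "ERA_ORDER",
    "ERA_AGE_BINS",
    "era_for_age",
]

#: Successional era labels, youngest first, with their calibrated age bounds
#: (years before sampling).  A layer of age ``a`` belongs to the first era
#: whose interval ``(lo, hi]`` contains it (modern is ``[0, 50]``).
ERA_ORDER: tuple[str, ...] = ("modern", "150-50", "300-150", "550-300", "630-550")
ERA_AGE_BINS: dict[str, tuple[float, float]] = {
    "modern": (0.0, 50.0),
    "150-50": (50.0, 150.0),
    "300-150": (150.0, 300.0),
    "550-300": (300.0, 550.0),
    "630-550": (550.0, 630.0),
}


class ValidationError(ValueError):
    """Raised when an input artifact violates a structural invariant."""


def era_for_age(age_years: float) -> str:
    """Map a calibrated age (years before sampling) to its successional era."""
    for era, (lo, hi) in ERA_AGE_BINS.items():
        if (lo <= age_years <= hi) if era == "modern" else (lo < age_years <= hi):
            return era
    raise ValidationError(f"age {age_years} outside the 0-630 year chronosequence")


@dataclass
class CommunityMatrix:
    """Samples × taxa abundance matrix.

    Parameters
    ----------
    data
        DataFrame with sample ids as index and taxon ids as columns.
    kind
        ``"counts"`` (non-negative integers) or ``"relative"`` (rows sum to 1).
    taxonomy
        Optional per-taxon ``;``-separated rank path
        (domain;phylum;class;order;family;genus), indexed by taxon id.
    """

    data: pd.DataFrame
    kind: str = "counts"
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> "CommunityMatrix":
        if self.kind not in ("counts", "relative"):
            raise ValidationError(f"kind must be counts|relative, got {self.kind!r}")
        vals = self.data.to_numpy(dtype=float)
        if vals.size == 0:
            raise ValidationError("empty community matrix")
        if not np.isfinite(vals).all():
            raise ValidationError("community matrix contains non-finite values")
        if (vals < 0).any():
            bad = self.data.columns[(vals < 0).any(axis=0)][0]
            raise ValidationError(f"negative abundance (e.g. taxon {bad!r})")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate taxon id {dup!r}")
        rowsum = vals.sum(axis=1)
        if (rowsum <= 0).any():
            bad = self.data.index[rowsum <= 0][0]
            raise ValidationError(f"sample {bad!r} has zero total abundance")
        if self.kind == "relative" and np.abs(rowsum - 1.0).max() > 1e-9:
            bad = self.data.index[np.argmax(np.abs(rowsum - 1.0))]
            raise ValidationError(f"relative rows must sum to 1 (sample {bad!r})")
        if self.taxonomy is not None:
            missing = self.data.columns.difference(self.taxonomy.index)
            if len(missing):
                raise ValidationError(f"taxonomy missing for taxon {missing[0]!r}")
        return self

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def relative(self) -> "CommunityMatrix":
        """Return a row-normalized (relative abundance) copy."""
        if self.kind == "relative":
            return self
        rel = self.data.div(self.data.sum(axis=1), axis=0)
        return CommunityMatrix(rel, kind="relative", taxonomy=self.taxonomy)

    def select_samples(self, sample_ids) -> "CommunityMatrix":
        sub = self.data.loc[list(sample_ids)]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        if self.kind == "relative":  # re-close after dropping absent taxa
            sub = sub.div(sub.sum(axis=1), axis=0)
        tax = self.taxonomy.loc[sub.columns] if self.taxonomy is not None else None
        return CommunityMatrix(sub, kind=self.kind, taxonomy=tax)

    def select_taxa(self, taxon_ids) -> "CommunityMatrix":
        sub = self.data.loc[:, list(taxon_ids)]
        tax = self.taxonomy.loc[sub.columns] if self.taxonomy is not None else None
        return CommunityMatrix(sub, kind=self.kind, taxonomy=tax)


@dataclass
class PairwiseMatrix:
    """Symmetric sample-pair matrix of a named statistic.

    ``beta_nti`` and ``rc_bray`` are signed deviations, not dissimilarities;
    their diagonal is NaN.  Dissimilarities (``bray_curtis``, ``beta_mntd``)
    have a zero diagonal.
    """

    sample_ids: list
    matrix: np.ndarray
    name: str

    _DISSIMILARITIES = ("bray_curtis", "beta_mntd")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if m.shape != (n, n):
            raise ValidationError(f"matrix shape {m.shape} != ({n},{n})")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(m[off], m.T[off], equal_nan=True):
            raise ValidationError(f"{self.name} matrix is not symmetric")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) values in row-major pair order."""
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)

    def pairs_frame(self) -> pd.DataFrame:
        """Long format: one row per unordered sample pair."""
        iu = np.triu_indices(self.n, k=1)
        ids = np.asarray(self.sample_ids, dtype=object)
        return pd.DataFrame(
            {
                "sample_a": ids[iu[0]],
                "sample_b": ids[iu[1]],
                self.name: self.matrix[iu],
            }
        )

    def select(self, sample_ids) -> "PairwiseMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return PairwiseMatrix(list(sample_ids), self.matrix[np.ix_(idx, idx)], self.name)
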
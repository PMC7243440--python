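"""Reading, validation and harmonization of the input artifacts.

Supported formats: OTU tables as TSV (taxa-as-rows by convention, ``#OTU ID``
header tolerated, optional ``taxonomy`` column) or BIOM 1.0 JSON; trees as
newick with branch lengths; sample metadata and soil chemistry as CSV with a
``sample_id`` column.  Rarefaction is a single seeded multivariate
hypergeometric draw (subsampling without replacement).
"""

from __future__ import annotations

import io
import json
import logging

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CommunityMatrix, ValidationError, era_for_age

logger = logging.getLogger(__name__)

__all__ = [
    "read_community_table",
    "write_community_table",
    "read_newick",
    "write_newick",
    "read_sample_frame",
    "read_env_table",
    "rarefy",
    "harmonize_bundle",
    "collapse_rank",
]

_RANK_INDEX = {
    "domain": 0,
    "phylum": 1,
    "class": 2,
    "order": 3,
    "family": 4,
    "genus": 5,
}


# ---------------------------------------------------------------------------
# community tables
# ---------------------------------------------------------------------------

def read_community_table(
    path,
    format: str = "tsv",
    orientation: str = "taxa_as_rows",
) -> CommunityMatrix:
    """Read an OTU/taxon abundance table into a counts CommunityMatrix.

    ``orientation`` applies to the TSV dialect only: ``taxa_as_rows`` (the
    common OTU-table convention, default) or ``samples_as_rows``.
    """
    if format == "biom":
        return _read_biom_json(path)
    if format != "tsv":
        raise ValidationError(f"unknown table format {format!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    df.index.name = None
    taxonomy = None
    tax_cols = [c for c in df.columns if str(c).strip().lower() == "taxonomy"]
    if tax_cols:
        taxonomy = df[tax_cols[0]].astype(str)
        df = df.drop(columns=tax_cols)
    df = df.apply(pd.to_numeric)
    if orientation == "taxa_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    elif taxonomy is not None:
        raise ValidationError("taxonomy column requires taxa_as_rows orientation")
    return CommunityMatrix(df, kind="counts", taxonomy=taxonomy)


def _read_biom_json(path) -> CommunityMatrix:
    """Minimal reader for the BIOM 1.0 JSON dialect (dense or sparse)."""
    with open(path) as fh:
        doc = json.load(fh)
    n_rows, n_cols = doc["shape"]
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    taxonomy = None
    if doc["rows"] and (doc["rows"][0].get("metadata") or {}).get("taxonomy"):
        taxonomy = pd.Series(
            {
                r["id"]: ";".join(r["metadata"]["taxonomy"])
                for r in doc["rows"]
                if r.get("metadata") and r["metadata"].get("taxonomy")
            }
        ).reindex(taxa)
    df = pd.DataFrame(mat.T, index=samples, columns=taxa)
    return CommunityMatrix(df, kind="counts", taxonomy=taxonomy)


def write_community_table(m: CommunityMatrix, path, format: str = "tsv") -> None:
    """Write a community matrix as taxa-as-rows TSV or BIOM 1.0 JSON."""
    if format == "tsv":
        out = m.data.T
        out.index.name = "#OTU ID"
        if m.taxonomy is not None:
            out = out.assign(taxonomy=m.taxonomy.reindex(out.index))
        out.to_csv(path, sep="\t")
    elif format == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "ecoassembly",
            "matrix_type": "dense",
            "matrix_element_type": "float",
            "shape": [m.shape[1], m.shape[0]],
            "rows": [
                {
                    "id": str(t),
                    "metadata": (
                        {"taxonomy": str(m.taxonomy[t]).split(";")}
                        if m.taxonomy is not None
                        else None
                    ),
                }
                for t in m.taxon_ids
            ],
            "columns": [{"id": str(s), "metadata": None} for s in m.sample_ids],
            "data": m.values().T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValidationError(f"unknown table format {format!r}")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path_or_str) -> TreeNode:
    """Read a rooted newick tree, requiring branch lengths on every edge."""
    if isinstance(path_or_str, str) and path_or_str.rstrip().endswith(";"):
        tree = TreeNode.read(io.StringIO(path_or_str), format="newick")
    else:
        tree = TreeNode.read(str(path_or_str), format="newick")
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValidationError("tree must have at least 2 tips")
    names = [t.name for t in tips]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                f"missing branch length above {node.name or 'internal node'!r}"
            )
        if not np.isfinite(node.length) or node.length < 0:
            raise ValidationError(f"invalid branch length {node.length!r}")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# sample metadata and environment
# ---------------------------------------------------------------------------

def read_sample_frame(path) -> pd.DataFrame:
    """Read per-sample metadata CSV (depth_cm, age_years, era, replicate).

    If ``era`` is absent it is derived from ``age_years`` via the five
    chronosequence age bins.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValidationError("sample table needs a 'sample_id' column")
    df = df.set_index(df["sample_id"].astype(str)).drop(columns="sample_id")
    if df.index.has_duplicates:
        raise ValidationError("duplicate sample ids in sample table")
    if "age_years" not in df.columns:
        raise ValidationError("sample table needs an 'age_years' column")
    if "era" not in df.columns:
        df["era"] = [era_for_age(a) for a in df["age_years"]]
    return df


def read_env_table(path) -> pd.DataFrame:
    """Read the soil-chemistry CSV; all values must be numeric and finite."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValidationError("env table needs a 'sample_id' column")
    df = df.set_index(df["sample_id"].astype(str)).drop(columns="sample_id")
    df = df.apply(pd.to_numeric)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValidationError("env table contains missing/non-finite values")
    return df


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(m: CommunityMatrix, depth: int, seed: int | None = None) -> CommunityMatrix:
    """Subsample every sample without replacement to a common read depth.

    Samples with fewer than ``depth`` reads are dropped with a warning; an
    error is raised if that would drop everything.  A single multivariate
    hypergeometric draw per sample, deterministic given ``seed``.
    """
    if m.kind != "counts":
        raise ValidationError("rarefy requires a counts matrix")
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    counts = m.values().round().astype(np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    dropped = [s for s, k in zip(m.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    rows = []
    for i in np.flatnonzero(keep):
        if totals[i] == depth:
            rows.append(counts[i])
        else:
            rows.append(rng.multivariate_hypergeometric(counts[i], depth))
    sub = pd.DataFrame(
        np.asarray(rows),
        index=[s for s, k in zip(m.sample_ids, keep) if k],
        columns=m.taxon_ids,
    )
    sub = sub.loc[:, sub.sum(axis=0) > 0]
    tax = m.taxonomy.loc[sub.columns] if m.taxonomy is not None else None
    return CommunityMatrix(sub, kind="counts", taxonomy=tax)


# ---------------------------------------------------------------------------
# harmonization and taxonomy collapsing
# ---------------------------------------------------------------------------

def harmonize_bundle(
    m: CommunityMatrix,
    tree: TreeNode | None = None,
    samples: pd.DataFrame | None = None,
    env: pd.DataFrame | None = None,
):
    """Restrict all artifacts to their common taxa and samples.

    Taxa are intersected between the matrix columns and the tree tips (tree
    sheared, matrix filtered); samples are intersected across all provided
    tables.  Idempotent.  Returns ``(matrix, tree, samples, env)`` with
    ``None`` passed through for absent artifacts.
    """
    taxa = list(m.taxon_ids)
    if tree is not None:
        tip_names = {t.name for t in tree.tips()}
        shared = [t for t in taxa if str(t) in tip_names]
        if not shared:
            raise ValidationError("no taxa shared between matrix and tree")
        if len(shared) < len(taxa) or len(tip_names) > len(shared):
            logger.info(
                "harmonize: %d matrix taxa and %d tree tips dropped",
                len(taxa) - len(shared), len(tip_names) - len(shared),
            )
        tree = tree.shear([str(t) for t in shared])
        tree.prune()
        m = m.select_taxa(shared)

    sample_sets = [list(m.sample_ids)]
    for tbl in (samples, env):
        if tbl is not None:
            sample_sets.append(list(tbl.index.astype(str)))
    common = [s for s in sample_sets[0] if all(str(s) in set(ss) for ss in sample_sets[1:])]
    if not common:
        raise ValidationError("no samples shared across input tables")
    n_drop = sum(len(ss) - len(common) for ss in sample_sets)
    if n_drop:
        logger.info("harmonize: %d sample entries dropped across tables", n_drop)
    if common != list(m.sample_ids):
        m = m.select_samples(common)
        if tree is not None:  # some taxa may have vanished with the samples
            return harmonize_bundle(m, tree, samples, env)
    if samples is not None:
        samples = samples.loc[[str(s) for s in common]]
    if env is not None:
        env = env.loc[[str(s) for s in common]]
    return m, tree, samples, env


def collapse_rank(m: CommunityMatrix, rank: str = "family") -> CommunityMatrix:
    """Sum taxa into higher-rank groups using the ``;``-separated taxonomy.

    Taxa without an assignment at ``rank`` are pooled into
    ``unclassified_<rank>``.  Per-sample totals are conserved.
    """
    if m.taxonomy is None:
        raise ValidationError("collapse_rank requires taxonomy paths")
    if rank not in _RANK_INDEX:
        raise ValidationError(f"unknown rank {rank!r}")
    idx = _RANK_INDEX[rank]
    labels = {}
    for taxon in m.taxon_ids:
        parts = [p.strip() for p in str(m.taxonomy[taxon]).split(";")]
        name = parts[idx] if idx < len(parts) else ""
        if len(name) > 3 and name[1:3] == "__":  # greengenes-style prefix
            name = name[3:]
        labels[taxon] = name if name else f"unclassified_{rank}"
    grouped = m.data.T.groupby(pd.Series(labels)).sum().T
    return CommunityMatrix(grouped, kind=m.kind)
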
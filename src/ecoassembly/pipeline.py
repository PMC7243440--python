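"""End-to-end orchestration: validate → rarefy → signal gate → null models
→ process partitioning → trend → supporting stats → biomarkers.

Driven by a single YAML/dict config; every stage writes TSV outputs under a
versioned output directory together with a reproducibility manifest
(package version, config hash, seeds, pair accounting).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import ERA_ORDER, ValidationError
from . import assembly_null, biomarker_rf, community_stats, data_io, phylo_signal

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

#: Across-era timescale spans (span_years, oldest_age, youngest_age).
DEFAULT_SPANS = (
    (300, 630.0, 300.0),
    (480, 630.0, 150.0),
    (580, 630.0, 50.0),
    (630, 630.0, 0.0),
)


@dataclass
class RunConfig:
    """Input paths and analysis parameters for one pipeline run."""

    table: str
    tree: str
    samples: str
    env: str
    out: str = "ecoassembly_out"
    table_format: str = "tsv"
    rarefaction_depth: int | None = 65000
    n_null_phylo: int = 1000
    n_null_rc: int = 999
    n_perm: int = 999
    seed: int = 0
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    spans: tuple = DEFAULT_SPANS
    cross_pairs_only: bool = False
    run_biomarkers: bool = True
    biomarker_top_k: int = 13
    env_groups: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        spans = raw.pop("spans", None)
        cfg = cls(**raw)
        if spans is not None:
            cfg.spans = tuple(tuple(s) for s in spans)
        return cfg

    def validate_paths(self) -> None:
        for name in ("table", "tree", "samples", "env"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"config path {name}={p} does not exist")

    def config_hash(self) -> str:
        doc = {k: (list(map(list, v)) if k == "spans" else v)
               for k, v in self.__dict__.items()}
        return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()


def _versioned_dir(base: Path) -> Path:
    """Never overwrite a previous run: suffix .1, .2, ... if needed."""
    if not base.exists():
        base.mkdir(parents=True)
        return base
    i = 1
    while (cand := base.with_name(f"{base.name}.{i}")).exists():
        i += 1
    cand.mkdir(parents=True)
    return cand


def run_pipeline(cfg: RunConfig):
    """Run the full analysis; returns the output directory path."""
    cfg.validate_paths()
    out = _versioned_dir(Path(cfg.out))
    logging.basicConfig(level=logging.INFO)
    logger.info("pipeline: writing to %s", out)

    # ---- load & harmonize ------------------------------------------------
    m = data_io.read_community_table(cfg.table, format=cfg.table_format)
    tree = data_io.read_newick(cfg.tree)
    samples = data_io.read_sample_frame(cfg.samples)
    env = data_io.read_env_table(cfg.env)
    if cfg.rarefaction_depth:
        m = data_io.rarefy(m, cfg.rarefaction_depth, seed=cfg.seed)
    m, tree, samples, env = data_io.harmonize_bundle(m, tree, samples, env)
    logger.info("pipeline: %d samples × %d taxa after harmonization", *m.shape)

    # ---- phylogenetic signal gate ---------------------------------------
    phylo_d = phylo_signal.cophenetic_matrix(tree)
    niche = phylo_signal.taxon_niche_values(m, env)
    niche_d = phylo_signal.niche_distance_matrix(niche)
    correlogram = phylo_signal.mantel_correlogram(
        phylo_d, niche_d, n_perm=cfg.n_perm, seed=cfg.seed
    )
    correlogram.classes.to_csv(out / "correlogram.tsv", sep="\t", index=False)
    gate_ok = phylo_signal.has_short_range_signal(correlogram)
    if not gate_ok:
        logger.warning(
            "pipeline: no significant short-distance phylogenetic signal; "
            "βNTI-based inferences assume niche conservatism — interpret with care"
        )

    # ---- null models per scope ------------------------------------------
    null_cfg = assembly_null.NullEnsembleConfig(
        n_null_phylo=cfg.n_null_phylo, n_null_rc=cfg.n_null_rc, seed=cfg.seed
    )
    qpe_dir = out / "qpe"
    qpe_dir.mkdir()
    scope_rows = []
    pair_accounting = {}
    trend_points = []

    scopes = [("within", era, None) for era in ERA_ORDER
              if (samples["era"] == era).sum() >= 2]
    scopes += [("across", f"{int(span)}_years", (span, oldest, youngest))
               for span, oldest, youngest in cfg.spans]
    for kind, label, span in scopes:
        if kind == "within":
            sub, sf, mask = assembly_null.subset_by_timescale(
                m, samples, "within_era", era=label
            )
        else:
            _, oldest, youngest = span
            sub, sf, mask = assembly_null.subset_by_timescale(
                m, samples, "across_eras", oldest_age=oldest,
                youngest_age=youngest, cross_pairs_only=cfg.cross_pairs_only,
            )
        sub_d = phylo_d.filter([str(t) for t in sub.taxon_ids])
        bnti = assembly_null.beta_nti(sub, sub_d, null_cfg)
        rc = assembly_null.raup_crick_bray(sub, null_cfg)
        pairs = assembly_null.classify_pairs(bnti, rc)
        pairs.to_csv(qpe_dir / f"pairs_{kind}_{label}.tsv", sep="\t", index=False)
        frac = assembly_null.partition_processes(bnti, rc, pair_mask=mask,
                                                 label=f"{kind}:{label}")
        row = frac.to_series()
        row["scope"] = f"{kind}:{label}"
        scope_rows.append(row)
        pair_accounting[f"{kind}:{label}"] = {
            "classified": int(frac.n_pairs), "excluded": int(frac.n_excluded)
        }
        if kind == "across":
            trend_points.append((span[0], frac.stochastic))
    fractions = pd.DataFrame(scope_rows).set_index("scope")
    fractions.to_csv(qpe_dir / "process_fractions.tsv", sep="\t")

    trend = assembly_null.stochasticity_trend(trend_points)
    trend.points.assign(slope=trend.slope, intercept=trend.intercept,
                        r_squared=trend.r_squared, p_value=trend.p_value
                        ).to_csv(qpe_dir / "stochasticity_trend.tsv", sep="\t",
                                 index=False)

    # ---- supporting statistics ------------------------------------------
    stats_dir = out / "stats"
    stats_dir.mkdir()
    bc = community_stats.bray_curtis(m)
    bmntd = assembly_null.beta_mntd(m, phylo_d)
    alpha = community_stats.alpha_diversity(m, tree)
    alpha.to_csv(stats_dir / "alpha_diversity.tsv", sep="\t")
    community_stats.correlate_alpha_env(alpha, env).to_csv(
        stats_dir / "alpha_env_correlations.tsv", sep="\t", index=False
    )
    groups = cfg.env_groups or community_stats.DEFAULT_ENV_GROUPS
    for name, pm in (("bray_curtis", bc), ("beta_mntd", bmntd)):
        ord_res = community_stats.nmds(pm, seed=cfg.seed)
        ord_res.coordinates.assign(stress=ord_res.stress).to_csv(
            stats_dir / f"nmds_{name}.tsv", sep="\t"
        )
        community_stats.env_group_mantel(pm, env, groups, n_perm=cfg.n_perm,
                                         seed=cfg.seed).to_csv(
            stats_dir / f"mantel_{name}.tsv", sep="\t", index=False
        )
    perm = community_stats.permanova(bc, samples["era"], n_perm=cfg.n_perm,
                                     seed=cfg.seed)
    pd.DataFrame([{"statistic": perm.statistic, "p_value": perm.p_value,
                   "permutations": perm.permutations}]).to_csv(
        stats_dir / "permanova_era.tsv", sep="\t", index=False
    )
    if m.taxonomy is not None:
        genus = data_io.collapse_rank(m, "genus")
        community_stats.era_genus_sharing(genus, samples).to_csv(
            stats_dir / "era_genus_sharing.tsv", sep="\t", index=False
        )

    # ---- biomarkers ------------------------------------------------------
    if cfg.run_biomarkers and m.taxonomy is not None:
        fam = data_io.collapse_rank(m, "family").relative()
        response = biomarker_rf.era_midpoint_response(samples)
        ranking = biomarker_rf.fit_importance(fam, response, seed=cfg.seed)
        k = min(cfg.biomarker_top_k, fam.shape[1])
        chosen = biomarker_rf.select_biomarkers(ranking, k=k)
        long = (
            fam.data[chosen]
            .assign(era=samples["era"])
            .groupby("era", sort=False).mean()
            .reset_index()
            .melt(id_vars="era", var_name="family", value_name="mean_rel_abundance")
        )
        ranking.ranking.head(k).merge(
            long, on="family"
        ).to_csv(out / "biomarkers.tsv", sep="\t", index=False)

    # ---- manifest --------------------------------------------------------
    manifest = {
        "package": "ecoassembly",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_samples": m.shape[0],
        "n_taxa": m.shape[1],
        "phylo_signal_gate": bool(gate_ok),
        "pair_accounting": pair_accounting,
        "trend": {"slope": trend.slope, "r_squared": trend.r_squared,
                  "p_value": trend.p_value},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
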
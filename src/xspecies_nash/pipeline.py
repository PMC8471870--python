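"""Config-driven orchestration of the full analysis.

A run config (YAML) names the cohorts (expression TSV, sample TSV, platform,
role, optional orthologue TSV and group-label mapping), the gene-set GMT,
the thresholds, and a single seed. ``run_all`` executes
preprocess -> differential expression -> preranked GSEA -> concordance ->
biomarker screen, writes every intermediate table under the output
directory, and returns a machine-readable report with the headline numbers.

The run seed fans out to per-stage seeds by stable hashing of the stage
name, so any stage is reproducible independently of execution order.
Cohort roles: ``gp`` (the model cohort; exactly one required for the
biomarker stage), ``hnash1`` (DEG-overlap and cross-projection reference),
``hnash2`` (advanced-disease human cohort; direction reference of the
biomarker cascade), ``mouse`` (benchmark models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from xspecies_nash import __version__
from xspecies_nash.biomarker import candidate_genes, fibrosis_screen
from xspecies_nash.concordance import (
    cross_projection,
    deg_overlap,
    nes_concordance_matrix,
    pathway_share,
    pca,
)
from xspecies_nash.diffexp import (
    moderated_t_test,
    nb_wald_test,
    select_degs,
    top_n_by_abs_lfc,
)
from xspecies_nash.enrichment import gsea_permutation, rank_by_lfc, top50_pathways
from xspecies_nash.io_formats import (
    ExpressionMatrix,
    FormatError,
    check_samples_covered,
    read_expression,
    read_gmt,
    read_orthologue_map,
    read_sample_table,
)
from xspecies_nash.preprocess import (
    filter_low_counts,
    map_to_orthologues,
    size_factors_median_of_ratios,
    vst_log,
)
from xspecies_nash.study import derive_seed


class ConfigError(ValueError):
    """Invalid run configuration."""


DEFAULT_THRESHOLDS = {
    "min_identity": 50.0,
    "min_total": 200,
    "q_deg": 0.05,
    "q_pathway": 0.1,
    "top_n": 200,
    "rho_min": 0.8,
    "lfc_min": 1.0,
    "n_perm": 1000,
}

ROLES = {"gp", "hnash1", "hnash2", "mouse"}


@dataclass
class CohortConfig:
    cohort_id: str
    role: str
    platform: str
    expression: str
    samples: str
    orthologues: str | None = None
    group_map: dict[str, str] = field(default_factory=dict)


@dataclass
class RunConfig:
    cohorts: list[CohortConfig]
    gene_sets: str
    seed: int
    out_dir: str
    thresholds: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        ids = [c.cohort_id for c in self.cohorts]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate cohort ids")
        for c in self.cohorts:
            if c.role not in ROLES:
                raise ConfigError(f"cohort {c.cohort_id!r}: unknown role {c.role!r}")
            if c.platform not in ("count", "intensity"):
                raise ConfigError(f"cohort {c.cohort_id!r}: unknown platform {c.platform!r}")
        if sum(c.role == "gp" for c in self.cohorts) != 1:
            raise ConfigError("exactly one cohort with role 'gp' is required")
        if sum(c.role == "hnash2" for c in self.cohorts) > 1:
            raise ConfigError("at most one cohort with role 'hnash2'")
        if sum(c.role == "hnash1" for c in self.cohorts) > 1:
            raise ConfigError("at most one cohort with role 'hnash1'")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        cohorts = [
            CohortConfig(
                cohort_id=c["id"],
                role=c["role"],
                platform=c["platform"],
                expression=c["expression"],
                samples=c["samples"],
                orthologues=c.get("orthologues"),
                group_map=c.get("group_map", {}),
            )
            for c in raw["cohorts"]
        ]
        return RunConfig(
            cohorts=cohorts,
            gene_sets=raw["gene_sets"],
            seed=int(raw["seed"]),
            out_dir=raw.get("out_dir", "results"),
            thresholds=raw.get("thresholds", {}),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing config key {exc}") from exc


@dataclass
class ProcessedCohort:
    config: CohortConfig
    matrix: ExpressionMatrix  # harmonized (counts filtered / human symbols)
    transformed: ExpressionMatrix  # log-scale matrix for PCA/correlation
    groups: pd.Series
    samples: pd.DataFrame
    size_factors: pd.Series | None = None


def _stage(msg: str, log: list[str]) -> None:
    log.append(msg)


def preprocess_cohort(cfg: CohortConfig, thresholds: dict[str, Any]) -> ProcessedCohort:
    matrix = read_expression(cfg.expression, cfg.platform)
    table = read_sample_table(cfg.samples) if not cfg.group_map else _mapped_samples(cfg)
    check_samples_covered(matrix, table)
    groups = table.set_index("sample")["group"].reindex(matrix.samples)
    if cfg.orthologues:
        orth = read_orthologue_map(cfg.orthologues)
        matrix, _report = map_to_orthologues(matrix, orth, thresholds["min_identity"])
    if cfg.platform == "count":
        matrix = filter_low_counts(matrix, thresholds["min_total"])
        s = size_factors_median_of_ratios(matrix)
        transformed = vst_log(matrix, s)
    else:
        s = None
        transformed = matrix
    return ProcessedCohort(cfg, matrix, transformed, groups, table, s)


def _mapped_samples(cfg: CohortConfig) -> pd.DataFrame:
    """Apply a cohort-specific group-label mapping before validation."""
    raw = pd.read_csv(cfg.samples, sep="\t", dtype={"sample": str, "group": str})
    raw["group"] = raw["group"].map(lambda g: cfg.group_map.get(g, g))
    tmp = raw
    for col in ("sample", "group", "cohort"):
        if col not in tmp.columns:
            raise FormatError(f"{cfg.samples}: missing required column {col!r}")
    unknown = set(tmp["group"]) - {"control", "case"}
    if unknown:
        raise FormatError(f"{cfg.samples}: unmapped group label(s) {sorted(unknown)}")
    return tmp


def run_de(cohort: ProcessedCohort) -> pd.DataFrame:
    if cohort.matrix.platform == "count":
        return nb_wald_test(cohort.matrix, cohort.groups, cohort.size_factors)
    return moderated_t_test(cohort.matrix, cohort.groups)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    thresholds = config.thresholds
    collection = read_gmt(config.gene_sets)

    processed: dict[str, ProcessedCohort] = {}
    de_tables: dict[str, pd.DataFrame] = {}
    gsea_tables: dict[str, pd.DataFrame] = {}
    top50: dict[str, Any] = {}
    degs: dict[str, set[str]] = {}

    for cfg in config.cohorts:
        cid = cfg.cohort_id
        try:
            cohort = preprocess_cohort(cfg, thresholds)
        except Exception as exc:
            raise RuntimeError(f"stage preprocess failed for cohort {cid}: {exc}") from exc
        processed[cid] = cohort
        _stage(f"preprocess:{cid}: {cohort.matrix.values.shape[0]} genes kept", log)

        try:
            de = run_de(cohort)
        except Exception as exc:
            raise RuntimeError(f"stage de failed for cohort {cid}: {exc}") from exc
        de_tables[cid] = de
        degs[cid] = select_degs(de, thresholds["q_deg"])
        de.to_csv(out / f"de_{cid}.tsv", sep="\t", index=False)
        _stage(f"de:{cid}: {len(degs[cid])} DEGs at q<{thresholds['q_deg']}", log)

        try:
            ranked = rank_by_lfc(de)
            enr = gsea_permutation(
                ranked,
                collection,
                n_perm=int(thresholds["n_perm"]),
                seed=derive_seed(config.seed, f"gsea:{cid}"),
            )
        except Exception as exc:
            raise RuntimeError(f"stage gsea failed for cohort {cid}: {exc}") from exc
        gsea_tables[cid] = enr
        top50[cid] = top50_pathways(enr, thresholds["q_pathway"])
        enr.to_csv(out / f"gsea_{cid}.tsv", sep="\t", index=False)
        _stage(f"gsea:{cid}: {int(enr['q'].lt(0.1).sum())} pathways at q<0.1", log)

    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {k: v for k, v in thresholds.items()},
        "cohorts": {cid: {"n_degs": len(degs[cid])} for cid in processed},
    }

    role_of = {c.cohort_id: c.role for c in config.cohorts}
    gp_id = next(cid for cid, r in role_of.items() if r == "gp")
    h1_id = next((cid for cid, r in role_of.items() if r == "hnash1"), None)
    h2_id = next((cid for cid, r in role_of.items() if r == "hnash2"), None)

    # --- concordance ------------------------------------------------------
    try:
        conc: dict[str, Any] = {}
        if h1_id and degs[h1_id]:
            ov = deg_overlap(degs[h1_id], degs[gp_id])
            conc["deg_overlap"] = {
                "reference": h1_id,
                "query": gp_id,
                "n": ov.n,
                "pct_vs_reference": ov.pct_vs_reference,
                "pct_vs_query": ov.pct_vs_query,
            }
            signature = top_n_by_abs_lfc(de_tables[gp_id], thresholds["top_n"], thresholds["q_deg"])
            proj = cross_projection(
                signature, processed[h1_id].transformed, processed[h1_id].groups
            )
            conc["cross_projection"] = {
                "signature_from": gp_id,
                "onto": h1_id,
                "separation_auc": proj.separation_auc,
                "pc1_variance_fraction": float(proj.pca.variance_fraction[0]),
                "n_genes_used": proj.n_genes_used,
            }
        if h2_id:
            shares = {}
            for cid in processed:
                if cid == h2_id:
                    continue
                sh = pathway_share(top50[h2_id], top50[cid])
                shares[cid] = {
                    "n_shared": len(sh.shared),
                    "share_pct": sh.share_pct,
                    "n_same_direction": sh.n_same_direction,
                    "n_opposite": sh.n_opposite,
                }
            conc["pathway_share_vs_" + h2_id] = shares
        evaluated = {cid: t for cid, t in gsea_tables.items()}
        nes, link, order = nes_concordance_matrix(evaluated)
        nes.to_csv(out / "nes_matrix.tsv", sep="\t")
        conc["nes_clustering"] = {
            "cohort_order": order,
            "linkage": [[float(v) for v in row] for row in link],
        }
        pca_gp = pca(processed[gp_id].transformed)
        conc["gp_pca_pc1_variance_pct"] = float(100.0 * pca_gp.variance_fraction[0])
        report["concordance"] = conc
        _stage("concordance: done", log)
    except Exception as exc:
        raise RuntimeError(f"stage concordance failed: {exc}") from exc

    # --- biomarker cascade ------------------------------------------------
    gp_samples = processed[gp_id].samples
    if "fibrosis_area" in gp_samples.columns and h2_id is not None:
        try:
            fib = gp_samples.set_index("sample")["fibrosis_area"]
            screen = fibrosis_screen(
                processed[gp_id].transformed,
                fib,
                processed[gp_id].groups,
                de_tables[gp_id],
                de_tables[h2_id],
                rho_min=thresholds["rho_min"],
                lfc_min=thresholds["lfc_min"],
            )
            screen.to_csv(out / "biomarker_screen.tsv", sep="\t", index=False)
            report["biomarkers"] = {
                "candidates": candidate_genes(screen),
                "n_screened": len(screen),
            }
            _stage(f"biomarkers: {len(report['biomarkers']['candidates'])} candidates", log)
        except Exception as exc:
            raise RuntimeError(f"stage biomarkers failed: {exc}") from exc
    report["log"] = log
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def simulate_to_dir(seed: int, out_dir: str | Path, n_genes: int | None = None) -> RunConfig:
    """Generate the default synthetic study on disk and return its RunConfig."""
    from xspecies_nash.study import build_study, write_study

    kwargs = {} if n_genes is None else {"n_genes": n_genes}
    study = build_study(seed, **kwargs)
    manifest = write_study(study, Path(out_dir) / "data")
    cohorts = [
        CohortConfig(
            cohort_id=c["id"],
            role=c["role"],
            platform=c["platform"],
            expression=c["expression"],
            samples=c["samples"],
            orthologues=c.get("orthologues"),
        )
        for c in manifest["cohorts"]
    ]
    config = RunConfig(
        cohorts=cohorts,
        gene_sets=manifest["gene_sets"],
        seed=seed,
        out_dir=str(out_dir),
    )
    with open(Path(out_dir) / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "seed": seed,
                "out_dir": str(out_dir),
                "gene_sets": manifest["gene_sets"],
                "cohorts": manifest["cohorts"],
            },
            fh,
        )
    return config
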
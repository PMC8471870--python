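"""Default synthetic study design: six cohorts with coordinated planted truth.

This module wires the low-level generators of :mod:`xspecies_nash.syndata`
into a study emulating the structure of a cross-species NASH comparison:

* ``gp`` — the model-organism cohort: RNA-seq counts, 6 control vs 6 case
  animals, per-animal relative fibrosis areas (control 1.39 +/- 0.24 %,
  case 7.48 +/- 1.81 %), source gene ids harmonized to human symbols via a
  synthetic orthologue map, planted DE genes, and nine planted
  fibrosis-correlated candidate genes.
* ``hnash1`` — a larger human-like RNA-seq cohort (14 vs 16) sharing part
  of the model cohort's DE programme, used for DEG overlap and
  cross-projection.
* ``hnash2`` — a human-like array cohort (40 vs 32, log-intensities)
  sharing coordinated pathway shifts with ``gp`` and carrying
  direction-concordant effects for the nine candidate genes.
* ``wd1``/``wd2``/``diamond`` — small array cohorts (5 vs 5) sharing fewer
  pathway shifts with ``hnash2``, mimicking preclinical models of varying
  translational fidelity.

Effect sizes are fixed here once and treated as the study conditions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from xspecies_nash.io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    write_expression,
    write_gmt,
    write_orthologue_map,
    write_sample_table,
)
from xspecies_nash.syndata import (
    CohortSpec,
    cohort_sample_table,
    generate_array_cohort,
    generate_count_cohort,
    generate_fibrosis,
    generate_gene_sets,
    generate_orthologue_map,
    pathway_lfc_by_cohort,
    plant_correlated_genes,
)

N_GENES = 2000
N_GENE_SETS = 60
SET_SIZE_RANGE = (15, 60)
PATHWAY_SHIFT = 0.8
CANDIDATE_RHO = 0.95
CANDIDATE_LFC = 1.5
N_CANDIDATES = 9
N_CANDIDATES_DOWN = 2  # of the nine, two are down/negatively correlated
HUMAN_CONCORDANT_LFC = 0.5
N_SHARED_DE = 120
N_PRIVATE_DE = 80
DE_LFC_SCALE = 2.0


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage seed below 2**31 derived from the run seed."""
    return zlib.crc32(f"{seed}:{label}".encode()) & 0x7FFFFFFF


def gene_universe(n_genes: int = N_GENES) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n_genes)]


def source_id(symbol: str) -> str:
    return f"CP_{symbol}"


@dataclass
class Cohort:
    spec: CohortSpec
    matrix: ExpressionMatrix
    truth: pd.DataFrame
    samples: pd.DataFrame
    role: str
    orthologues: pd.DataFrame | None = None


@dataclass
class Study:
    cohorts: dict[str, Cohort]
    gene_sets: GeneSetCollection
    pathway_truth: pd.DataFrame
    candidate_genes: list[str]
    candidate_lfc: dict[str, float]
    fibrosis: pd.Series
    seed: int


def _pathway_design(seed: int, genes: list[str]) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Gene sets with coordinated shifts of varying cross-cohort sharing.

    17 sets are shifted identically in gp and hnash2 (5 up, 12 down); wd2
    shares 12 of those, wd1 5 and diamond 6; each cohort additionally gets
    private shifted sets so its enrichment landscape is non-trivial, and
    the remaining sets are null.
    """
    shared = [f"SHARED_{i + 1:02d}" for i in range(17)]
    gp_only = [f"GPONLY_{i + 1:02d}" for i in range(8)]
    h2_only = [f"H2ONLY_{i + 1:02d}" for i in range(8)]
    shifts: dict[str, dict[str, float]] = {}
    for i, name in enumerate(shared):
        direction = 1.0 if i < 5 else -1.0
        eff = direction * PATHWAY_SHIFT
        shifts[name] = {"gp": eff, "hnash2": eff}
        if i < 12:
            shifts[name]["wd2"] = eff
        if i < 5:
            shifts[name]["wd1"] = eff
        if i < 6:
            shifts[name]["diamond"] = eff
    for i, name in enumerate(gp_only):
        shifts[name] = {"gp": PATHWAY_SHIFT if i % 2 == 0 else -PATHWAY_SHIFT}
    for i, name in enumerate(h2_only):
        shifts[name] = {"hnash2": PATHWAY_SHIFT if i % 2 == 0 else -PATHWAY_SHIFT}
    # set sizes scale with the universe so small test universes keep enough
    # genes untouched by pathway planting
    hi = max(SET_SIZE_RANGE[0] + 1, min(SET_SIZE_RANGE[1], 3 * len(genes) // 100))
    return generate_gene_sets(
        genes, N_GENE_SETS, (SET_SIZE_RANGE[0], hi), planted_shifts=shifts, seed=seed
    )


def _de_pools(genes: list[str], seed: int) -> dict[str, dict[str, float]]:
    """Shared and private DE gene pools for the two sequencing cohorts."""
    rng = np.random.default_rng(seed)
    # pool sizes scale with the universe (120 shared / 80 private at 2000 genes)
    n_shared = max(10, int(round(len(genes) * N_SHARED_DE / N_GENES)))
    n_private = max(5, int(round(len(genes) * N_PRIVATE_DE / N_GENES)))
    chosen = rng.choice(len(genes), size=n_shared + 2 * n_private, replace=False)
    shared = chosen[:n_shared]
    gp_private = chosen[n_shared : n_shared + n_private]
    h1_private = chosen[n_shared + n_private :]
    shared_lfc = rng.normal(0.0, DE_LFC_SCALE, n_shared)
    gp_lfc = rng.normal(0.0, DE_LFC_SCALE, n_private)
    h1_lfc = rng.normal(0.0, DE_LFC_SCALE, n_private)
    gp_map = {genes[i]: float(v) for i, v in zip(shared, shared_lfc)}
    gp_map.update({genes[i]: float(v) for i, v in zip(gp_private, gp_lfc)})
    h1_map = {genes[i]: float(v) for i, v in zip(shared, shared_lfc)}
    h1_map.update({genes[i]: float(v) for i, v in zip(h1_private, h1_lfc)})
    return {"gp": gp_map, "hnash1": h1_map}


def _merge_lfc(*maps: dict[str, float]) -> dict[str, float]:
    """Merge effect maps; later maps win only with a larger magnitude."""
    out: dict[str, float] = {}
    for m in maps:
        for gene, value in m.items():
            if abs(value) > abs(out.get(gene, 0.0)):
                out[gene] = value
    return out


def build_study(seed: int, n_genes: int = N_GENES) -> Study:
    """Assemble the full six-cohort synthetic study for one run seed."""
    genes = gene_universe(n_genes)
    gene_sets, pathway_truth = _pathway_design(derive_seed(seed, "gene_sets"), genes)
    pathway_lfc = pathway_lfc_by_cohort(gene_sets, pathway_truth)
    de_pools = _de_pools(genes, derive_seed(seed, "de_pools"))

    # --- model-organism count cohort (source-id keyed) -------------------
    gp_effects_sym = _merge_lfc(pathway_lfc.get("gp", {}), de_pools["gp"])
    source_genes = [source_id(g) for g in genes]
    gp_effects_src = {source_id(g): v for g, v in gp_effects_sym.items()}
    gp_spec = CohortSpec(
        cohort_id="gp",
        platform="count",
        n_genes=n_genes,
        n_control=6,
        n_case=6,
        de_fraction=0.0,
        lfc_scale=DE_LFC_SCALE,
        nb_dispersion=0.05,
        seed=derive_seed(seed, "gp"),
    )
    gp_matrix, gp_truth = generate_count_cohort(gp_spec, genes=source_genes, extra_lfc=gp_effects_src)

    fibrosis = generate_fibrosis(
        6, 6, seed=derive_seed(seed, "fibrosis"), sample_ids=gp_spec.sample_ids()
    )

    # nine candidate genes: well-expressed, untouched by DE or pathway planting
    touched = set(gp_effects_sym)
    totals = gp_matrix.values.sum(axis=1)
    eligible = [
        g
        for g in genes
        if g not in touched and totals[source_id(g)] >= 2000
    ]
    candidates = eligible[:N_CANDIDATES]
    if len(candidates) < N_CANDIDATES:
        raise RuntimeError("not enough eligible genes for candidate planting")
    candidate_lfc = {
        g: (-CANDIDATE_LFC if i < N_CANDIDATES_DOWN else CANDIDATE_LFC)
        for i, g in enumerate(candidates)
    }
    gp_groups = gp_spec.groups()
    for gene, g_lfc in candidate_lfc.items():
        rho = CANDIDATE_RHO if g_lfc > 0 else -CANDIDATE_RHO
        gp_matrix, _ = plant_correlated_genes(
            gp_matrix,
            fibrosis,
            [source_id(gene)],
            target_rho=rho,
            groups=gp_groups,
            exact=True,
            lfc=g_lfc,
            seed=derive_seed(seed, f"plant:{gene}"),
        )
        gp_truth.loc[gp_truth["gene"] == source_id(gene), "planted_rho"] = rho
        gp_truth.loc[gp_truth["gene"] == source_id(gene), "planted_lfc"] = g_lfc

    orthologues = generate_orthologue_map(
        source_genes,
        mapped_fraction=0.85,
        identity_range=(30.0, 100.0),
        seed=derive_seed(seed, "orthologues"),
        target_symbols=genes,
        collision_fraction=0.02,
        pinned_identity={source_id(g): 100.0 for g in candidates},
    )
    gp = Cohort(
        spec=gp_spec,
        matrix=gp_matrix,
        truth=gp_truth,
        samples=cohort_sample_table(gp_spec, fibrosis),
        role="gp",
        orthologues=orthologues,
    )

    # --- human-like sequencing cohort ------------------------------------
    h1_spec = CohortSpec(
        cohort_id="hnash1",
        platform="count",
        n_genes=n_genes,
        n_control=14,
        n_case=16,
        lfc_scale=DE_LFC_SCALE,
        nb_dispersion=0.05,
        seed=derive_seed(seed, "hnash1"),
    )
    h1_matrix, h1_truth = generate_count_cohort(h1_spec, genes=genes, extra_lfc=de_pools["hnash1"])
    hnash1 = Cohort(h1_spec, h1_matrix, h1_truth, cohort_sample_table(h1_spec), role="hnash1")

    # --- human-like array cohort (advanced disease) ----------------------
    h2_effects = _merge_lfc(
        pathway_lfc.get("hnash2", {}),
        {g: (HUMAN_CONCORDANT_LFC if v > 0 else -HUMAN_CONCORDANT_LFC) for g, v in candidate_lfc.items()},
    )
    h2_spec = CohortSpec(
        cohort_id="hnash2",
        platform="intensity",
        n_genes=n_genes,
        n_control=40,
        n_case=32,
        de_fraction=0.02,
        lfc_scale=1.0,
        noise_sd=0.5,
        seed=derive_seed(seed, "hnash2"),
    )
    h2_matrix, h2_truth = generate_array_cohort(h2_spec, genes=genes, extra_lfc=h2_effects)
    hnash2 = Cohort(h2_spec, h2_matrix, h2_truth, cohort_sample_table(h2_spec), role="hnash2")

    # --- murine-like array cohorts ---------------------------------------
    cohorts = {"gp": gp, "hnash1": hnash1, "hnash2": hnash2}
    for cid in ("wd1", "wd2", "diamond"):
        spec = CohortSpec(
            cohort_id=cid,
            platform="intensity",
            n_genes=n_genes,
            n_control=5,
            n_case=5,
            de_fraction=0.02,
            lfc_scale=1.0,
            noise_sd=0.5,
            seed=derive_seed(seed, cid),
        )
        matrix, truth = generate_array_cohort(spec, genes=genes, extra_lfc=pathway_lfc.get(cid, {}))
        cohorts[cid] = Cohort(spec, matrix, truth, cohort_sample_table(spec), role="mouse")

    return Study(
        cohorts=cohorts,
        gene_sets=gene_sets,
        pathway_truth=pathway_truth,
        candidate_genes=candidates,
        candidate_lfc=candidate_lfc,
        fibrosis=fibrosis,
        seed=seed,
    )


def write_study(study: Study, out_dir: str | Path) -> dict:
    """Write every cohort and shared resource as plain TSV/GMT files.

    Returns a manifest dict (also usable as the pipeline config skeleton).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gmt(study.gene_sets, out / "gene_sets.gmt")
    study.pathway_truth.to_csv(out / "pathway_truth.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": study.candidate_genes}).to_csv(
        out / "candidate_truth.tsv", sep="\t", index=False
    )
    cohorts = []
    for cid, cohort in study.cohorts.items():
        expr = out / f"{cid}_expression.tsv"
        samp = out / f"{cid}_samples.tsv"
        write_expression(cohort.matrix, expr)
        write_sample_table(cohort.samples, samp)
        cohort.truth.to_csv(out / f"{cid}_truth.tsv", sep="\t", index=False)
        entry = {
            "id": cid,
            "role": cohort.role,
            "platform": cohort.matrix.platform,
            "expression": str(expr),
            "samples": str(samp),
        }
        if cohort.orthologues is not None:
            orth = out / f"{cid}_orthologues.tsv"
            write_orthologue_map(cohort.orthologues, orth)
            entry["orthologues"] = str(orth)
        cohorts.append(entry)
    return {"gene_sets": str(out / "gene_sets.gmt"), "cohorts": cohorts}


@dataclass
class BiomarkerFixture:
    """Self-contained planted-truth fixture for the candidate-gene cascade."""

    expr: ExpressionMatrix  # transformed model-cohort matrix
    fibrosis: pd.Series
    groups: pd.Series
    gp_de: pd.DataFrame
    human_de: pd.DataFrame
    planted: list[str] = field(default_factory=list)


def biomarker_fixture(seed: int, n_genes: int = N_GENES) -> BiomarkerFixture:
    """A 2000-gene, 6 vs 6 cohort with nine fibrosis-correlated genes.

    The background carries no differential expression; the nine planted
    genes get exact within-group correlation 0.95 (two of them negative)
    and |log2fc| = 1.5, with direction-concordant effects in a human-like
    array cohort. The cascade at default thresholds should recover exactly
    these nine.
    """
    from xspecies_nash.diffexp import moderated_t_test, nb_wald_test
    from xspecies_nash.preprocess import size_factors_median_of_ratios, vst_log

    genes = gene_universe(n_genes)
    spec = CohortSpec(
        cohort_id="bm",
        platform="count",
        n_genes=n_genes,
        n_control=6,
        n_case=6,
        de_fraction=0.0,
        nb_dispersion=0.05,
        seed=derive_seed(seed, "bm_cohort"),
    )
    matrix, _ = generate_count_cohort(spec, genes=genes)
    fibrosis = generate_fibrosis(
        6, 6, seed=derive_seed(seed, "bm_fibrosis"), sample_ids=spec.sample_ids()
    )
    totals = matrix.values.sum(axis=1)
    eligible = [g for g in genes if totals[g] >= 2000]
    planted = eligible[:N_CANDIDATES]
    lfc_map = {
        g: (-CANDIDATE_LFC if i < N_CANDIDATES_DOWN else CANDIDATE_LFC)
        for i, g in enumerate(planted)
    }
    groups = spec.groups()
    for gene, g_lfc in lfc_map.items():
        rho = CANDIDATE_RHO if g_lfc > 0 else -CANDIDATE_RHO
        matrix, _ = plant_correlated_genes(
            matrix,
            fibrosis,
            [gene],
            target_rho=rho,
            groups=groups,
            exact=True,
            lfc=g_lfc,
            seed=derive_seed(seed, f"bm_plant:{gene}"),
        )

    s = size_factors_median_of_ratios(matrix)
    transformed = vst_log(matrix, s)
    gp_de = nb_wald_test(matrix, groups, s)

    h_spec = CohortSpec(
        cohort_id="bm_h",
        platform="intensity",
        n_genes=n_genes,
        n_control=40,
        n_case=32,
        noise_sd=0.5,
        seed=derive_seed(seed, "bm_human"),
    )
    h_matrix, _ = generate_array_cohort(
        h_spec,
        genes=genes,
        extra_lfc={
            g: (HUMAN_CONCORDANT_LFC if v > 0 else -HUMAN_CONCORDANT_LFC)
            for g, v in lfc_map.items()
        },
    )
    human_de = moderated_t_test(h_matrix, h_spec.groups())
    return BiomarkerFixture(
        expr=transformed,
        fibrosis=fibrosis,
        groups=groups,
        gp_de=gp_de,
        human_de=human_de,
        planted=planted,
    )
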
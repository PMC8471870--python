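"""Synthetic multi-cohort transcriptome generator with known planted truth.

Emulates the structure of a cross-species NASH study: a small guinea-pig-like
RNA-seq cohort (6 vs 6 with per-animal relative fibrosis areas), a larger
human-like count cohort, and array-like intensity cohorts; with planted
differentially expressed genes, planted coordinated pathway shifts, planted
fibrosis-correlated genes, and a synthetic orthologue map. Every generator is
a pure function of its spec (including the seed), so downstream stages can be
tested against the returned truth tables without any external download.

Counts are drawn per gene i, sample j as negative binomial with mean
``s_j * q_i * 2**(lfc_i * x_j)`` (x_j = 1 for case samples) and a common
dispersion; size factors s_j are drawn log-uniform in [0.5, 2] so that
normalization is non-trivially exercised. Array intensities are Gaussian
around a per-gene baseline shifted by the planted log2 fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from xspecies_nash.io_formats import ExpressionMatrix, GeneSetCollection

SIZE_FACTOR_RANGE = (0.5, 2.0)

# Relative fibrosis area (% of section staining collagen-positive),
# group mean +/- sd for control and NASH animals.
FIBROSIS_CONTROL_MEAN = 1.39
FIBROSIS_CONTROL_SD = 0.24
FIBROSIS_CASE_MEAN = 7.48
FIBROSIS_CASE_SD = 1.81


class ParameterError(ValueError):
    """Invalid generator parameterization."""


@dataclass(frozen=True)
class CohortSpec:
    """Shape and effect-size parameters of one synthetic cohort."""

    cohort_id: str
    platform: str  # "count" | "intensity"
    n_genes: int
    n_control: int
    n_case: int
    de_fraction: float = 0.0
    lfc_scale: float = 1.0
    nb_dispersion: float = 0.05
    noise_sd: float = 0.5
    baseline_log2_mean_range: tuple[float, float] = (3.0, 10.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.platform not in ("count", "intensity"):
            raise ParameterError(f"unknown platform {self.platform!r}")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be positive")
        if self.n_control < 2 or self.n_case < 2:
            raise ParameterError("need at least 2 samples per group")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ParameterError("de_fraction must lie in [0, 1]")
        if self.lfc_scale <= 0:
            raise ParameterError("lfc_scale must be positive")
        if self.platform == "count" and self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be positive")
        if self.platform == "intensity" and self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if self.seed is None:
            raise ParameterError("seed is required (no implicit global randomness)")
        if self.seed < 0:
            raise ParameterError("seed must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_case

    def sample_ids(self) -> list[str]:
        return [f"{self.cohort_id}_ctrl{i + 1}" for i in range(self.n_control)] + [
            f"{self.cohort_id}_case{i + 1}" for i in range(self.n_case)
        ]

    def groups(self) -> pd.Series:
        """Group label per sample, aligned with :meth:`sample_ids`."""
        labels = ["control"] * self.n_control + ["case"] * self.n_case
        return pd.Series(labels, index=self.sample_ids(), name="group")


def cohort_sample_table(spec: CohortSpec, fibrosis: pd.Series | None = None) -> pd.DataFrame:
    """Sample metadata table for a cohort; optionally joins fibrosis areas."""
    table = pd.DataFrame(
        {
            "sample": spec.sample_ids(),
            "group": ["control"] * spec.n_control + ["case"] * spec.n_case,
            "cohort": spec.cohort_id,
        }
    )
    if fibrosis is not None:
        table["fibrosis_area"] = table["sample"].map(fibrosis).to_numpy()
    return table


def _default_genes(spec: CohortSpec) -> list[str]:
    width = max(5, len(str(spec.n_genes)))
    return [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]


def _plant_lfc(
    spec: CohortSpec, genes: Sequence[str], rng: np.random.Generator,
    extra_lfc: Mapping[str, float] | None,
) -> pd.Series:
    lfc = pd.Series(0.0, index=pd.Index(genes))
    n_de = int(round(spec.de_fraction * spec.n_genes))
    if n_de:
        chosen = rng.choice(len(genes), size=n_de, replace=False)
        lfc.iloc[chosen] = rng.normal(0.0, spec.lfc_scale, size=n_de)
    if extra_lfc:
        for gene, value in extra_lfc.items():
            if gene in lfc.index:
                lfc.loc[gene] = value
    return lfc


def _truth(lfc: pd.Series) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": lfc.index,
            "planted_lfc": lfc.to_numpy(),
            "planted_rho": np.nan,
            "pathway_memberships": "",
        }
    ).reset_index(drop=True)


def generate_count_cohort(
    spec: CohortSpec,
    genes: Sequence[str] | None = None,
    extra_lfc: Mapping[str, float] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial count cohort with planted fold changes.

    Returns the count matrix and a truth table with one row per gene
    (``planted_lfc`` is exactly 0 for non-DE genes). ``extra_lfc`` overrides
    or adds planted effects for named genes (used to coordinate pathway
    shifts and shared signatures across cohorts).
    """
    if spec.platform != "count":
        raise ParameterError("generate_count_cohort requires a count-platform spec")
    rng = np.random.default_rng(spec.seed)
    gene_ids = list(genes) if genes is not None else _default_genes(spec)
    if len(gene_ids) != spec.n_genes:
        raise ParameterError("gene list length must equal n_genes")
    lo, hi = spec.baseline_log2_mean_range
    baseline = 2.0 ** rng.uniform(lo, hi, spec.n_genes)
    size_factors = np.exp(
        rng.uniform(np.log(SIZE_FACTOR_RANGE[0]), np.log(SIZE_FACTOR_RANGE[1]), spec.n_samples)
    )
    lfc = _plant_lfc(spec, gene_ids, rng, extra_lfc)
    x = np.array([0.0] * spec.n_control + [1.0] * spec.n_case)
    mu = size_factors[None, :] * baseline[:, None] * 2.0 ** (lfc.to_numpy()[:, None] * x[None, :])
    r = 1.0 / spec.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    values = pd.DataFrame(counts, index=gene_ids, columns=spec.sample_ids())
    return ExpressionMatrix(values, "count"), _truth(lfc)


def generate_array_cohort(
    spec: CohortSpec,
    genes: Sequence[str] | None = None,
    extra_lfc: Mapping[str, float] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Gaussian log-intensity cohort with planted fold changes."""
    if spec.platform != "intensity":
        raise ParameterError("generate_array_cohort requires an intensity-platform spec")
    rng = np.random.default_rng(spec.seed)
    gene_ids = list(genes) if genes is not None else _default_genes(spec)
    if len(gene_ids) != spec.n_genes:
        raise ParameterError("gene list length must equal n_genes")
    lo, hi = spec.baseline_log2_mean_range
    baseline = rng.uniform(lo, hi, spec.n_genes)
    lfc = _plant_lfc(spec, gene_ids, rng, extra_lfc)
    x = np.array([0.0] * spec.n_control + [1.0] * spec.n_case)
    mean = baseline[:, None] + lfc.to_numpy()[:, None] * x[None, :]
    intensities = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    values = pd.DataFrame(intensities, index=gene_ids, columns=spec.sample_ids())
    return ExpressionMatrix(values, "intensity"), _truth(lfc)


def generate_fibrosis(
    n_control: int,
    n_case: int,
    control_mean: float = FIBROSIS_CONTROL_MEAN,
    control_sd: float = FIBROSIS_CONTROL_SD,
    case_mean: float = FIBROSIS_CASE_MEAN,
    case_sd: float = FIBROSIS_CASE_SD,
    seed: int | None = None,
    sample_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Per-sample relative fibrosis areas (percent, strictly positive).

    Normal draws per group; non-positive draws are redrawn (up to 100
    attempts, then clamped to 0.01) because areas are percentages > 0.
    Defaults are the histology means/sds of the emulated study groups.
    """
    if control_mean <= 0 or case_mean <= 0 or control_sd < 0 or case_sd < 0:
        raise ParameterError("fibrosis means must be > 0 and sds >= 0")
    if seed is None:
        raise ParameterError("seed is required")
    rng = np.random.default_rng(seed)

    def draw(n: int, mean: float, sd: float) -> np.ndarray:
        values = rng.normal(mean, sd, n)
        for _ in range(100):
            bad = values <= 0
            if not bad.any():
                break
            values[bad] = rng.normal(mean, sd, bad.sum())
        return np.maximum(values, 0.01)

    values = np.concatenate(
        [draw(n_control, control_mean, control_sd), draw(n_case, case_mean, case_sd)]
    )
    if sample_ids is None:
        sample_ids = [f"ctrl{i + 1}" for i in range(n_control)] + [
            f"case{i + 1}" for i in range(n_case)
        ]
    if len(sample_ids) != n_control + n_case:
        raise ParameterError("sample_ids length mismatch")
    return pd.Series(values, index=list(sample_ids), name="fibrosis_area")


def _standardize(v: np.ndarray) -> np.ndarray:
    c = v - v.mean()
    norm = np.linalg.norm(c)
    if norm == 0:
        raise ParameterError("constant vector cannot be standardized")
    return c / norm


def _residual_unit(noise: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Residualize noise against [1, basis] and return at unit norm."""
    e = noise - noise.mean()
    e = e - (e @ basis) * basis
    norm = np.linalg.norm(e)
    if norm == 0:
        raise ParameterError("degenerate noise draw")
    return e / norm


def plant_correlated_genes(
    matrix: ExpressionMatrix,
    fibrosis: pd.Series,
    genes: Sequence[str],
    target_rho: float,
    groups: pd.Series | None = None,
    exact: bool = False,
    lfc: float | Mapping[str, float] | None = None,
    amplitude: float = 1.0,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Overwrite selected genes so they correlate with fibrosis area.

    On the log scale each planted gene becomes ``rho * z(fibrosis) +
    sqrt(1 - rho^2) * eps``, rescaled to the gene's expression level. In
    exact mode eps is residualized against z(fibrosis) and rescaled so the
    sample correlation over all samples equals ``target_rho`` to within 1e-9
    (rounding back to counts perturbs this slightly; tests assert exactness
    on the transformed matrix).

    When both ``groups`` and ``lfc`` are given, the construction is
    group-aware: the correlation is planted exactly (in exact mode) *within
    each group*, and the group intercepts are set so the case-vs-control
    difference of the planted log2 values equals ``lfc``. This is the mode
    used for biomarker-screen fixtures, whose thresholds apply to the
    all-samples and case-only correlations simultaneously; an all-samples-
    exact planting cannot pin the within-case correlation (and for strongly
    group-separated fibrosis the two targets can be jointly infeasible).

    Counts are back-transformed as ``round(s_j * (2**y - 1))``; intensity
    matrices receive the log-scale values directly.
    """
    if not abs(target_rho) <= 1:
        raise ParameterError("|target_rho| must be <= 1")
    if seed is None:
        raise ParameterError("seed is required")
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ParameterError(f"genes not in matrix: {missing[:10]}")
    samples = list(matrix.samples)
    if len(samples) < 3:
        raise ParameterError("need at least 3 samples to define a correlation")
    f = fibrosis.reindex(samples)
    if f.isna().any():
        raise ParameterError("fibrosis value missing for some samples")
    rng = np.random.default_rng(seed)

    if matrix.platform == "count":
        from xspecies_nash.preprocess import size_factors_median_of_ratios

        s = size_factors_median_of_ratios(matrix).reindex(samples).to_numpy()
        log_values = np.log2(matrix.values.to_numpy() / s[None, :] + 1.0)
    else:
        s = np.ones(len(samples))
        log_values = matrix.values.to_numpy().copy()
    log_df = pd.DataFrame(log_values, index=matrix.values.index, columns=samples)

    fv = f.to_numpy(dtype=float)
    rho = float(target_rho)
    tail = np.sqrt(max(0.0, 1.0 - rho**2))

    lfc_map: dict[str, float] = {}
    if lfc is not None:
        if isinstance(lfc, Mapping):
            lfc_map = {g: float(lfc[g]) for g in genes}
        else:
            lfc_map = {g: float(lfc) for g in genes}

    group_aware = groups is not None and lfc_map
    if group_aware:
        grp = groups.reindex(samples)
        if grp.isna().any():
            raise ParameterError("group label missing for some samples")
        masks = {
            "control": (grp == "control").to_numpy(),
            "case": (grp == "case").to_numpy(),
        }
        for name, mask in masks.items():
            if mask.sum() < 3:
                raise ParameterError(f"{name} group needs >= 3 samples for planting")
        delta_f = fv[masks["case"]].mean() - fv[masks["control"]].mean()
        if delta_f == 0:
            raise ParameterError("groups do not differ in fibrosis; lfc scale undefined")

    z_all = _standardize(fv)
    planted_rows = []
    for gene in genes:
        center = float(log_df.loc[gene].mean())
        if group_aware:
            g_lfc = lfc_map[gene]
            y = np.empty(len(samples))
            means = {"control": center - g_lfc / 2.0, "case": center + g_lfc / 2.0}
            b = abs(g_lfc) / abs(delta_f)
            for name, mask in masks.items():
                fg = fv[mask]
                zg = _standardize(fg)
                noise = rng.normal(size=mask.sum())
                eg = _residual_unit(noise, zg) if exact else _standardize(noise)
                ug = rho * zg + tail * eg
                y[mask] = means[name] + b * np.linalg.norm(fg - fg.mean()) * ug
        else:
            noise = rng.normal(size=len(samples))
            e = _residual_unit(noise, z_all) if exact else _standardize(noise)
            u = rho * z_all + tail * e
            g_lfc = lfc_map.get(gene, np.nan)
            y = center + amplitude * u * np.sqrt(len(samples) - 1)
        log_df.loc[gene] = y
        planted_rows.append({"gene": gene, "planted_rho": rho, "planted_lfc": g_lfc})

    if matrix.platform == "count":
        counts = np.round(np.maximum(2.0 ** log_df.to_numpy() - 1.0, 0.0) * s[None, :])
        out = ExpressionMatrix(
            pd.DataFrame(counts.astype(np.int64), index=log_df.index, columns=samples),
            "count",
        )
    else:
        out = ExpressionMatrix(log_df, "intensity")
    return out, pd.DataFrame(planted_rows)


def generate_gene_sets(
    genes: Sequence[str],
    n_sets: int,
    size_range: tuple[int, int] = (10, 60),
    planted_shifts: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | None = None,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Random gene sets, some carrying coordinated expression shifts.

    ``planted_shifts`` maps set name -> {cohort_id: lfc}; member genes of a
    planted set receive that coordinated log2 fold change in the stated
    cohort (retrieve per-cohort gene effects with
    :func:`pathway_lfc_by_cohort`), enabling concordant and discordant
    cross-cohort designs. The remaining sets are unplanted (null) draws.
    """
    if seed is None:
        raise ParameterError("seed is required")
    lo, hi = size_range
    if lo < 5 or hi > len(genes):
        raise ParameterError("size_range must lie within [5, len(genes)]")
    if lo > hi:
        raise ParameterError("invalid size_range")
    planted_shifts = dict(planted_shifts or {})
    if len(planted_shifts) > n_sets:
        raise ParameterError("more planted sets than n_sets")
    rng = np.random.default_rng(seed)
    genes = list(genes)

    sets: dict[str, frozenset[str]] = {}
    truth_rows = []
    names = list(planted_shifts) + [
        f"SET_{i + 1:04d}" for i in range(n_sets - len(planted_shifts))
    ]
    for name in names:
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        sets[name] = members
        for cohort, shift in planted_shifts.get(name, {}).items():
            truth_rows.append({"set": name, "cohort": cohort, "planted_lfc": float(shift)})
    truth = pd.DataFrame(truth_rows, columns=["set", "cohort", "planted_lfc"])
    return GeneSetCollection(sets), truth


def pathway_lfc_by_cohort(
    collection: GeneSetCollection, truth: pd.DataFrame
) -> dict[str, dict[str, float]]:
    """Per-cohort gene -> lfc dictionaries implied by planted pathway shifts.

    If a gene belongs to several planted sets in the same cohort, the shift
    with the largest magnitude wins (coordinated shifts should not cancel by
    bookkeeping accident).
    """
    out: dict[str, dict[str, float]] = {}
    for row in truth.itertuples(index=False):
        cohort_map = out.setdefault(row.cohort, {})
        for gene in collection[row.set]:
            prev = cohort_map.get(gene, 0.0)
            if abs(row.planted_lfc) > abs(prev):
                cohort_map[gene] = float(row.planted_lfc)
    return out


def generate_orthologue_map(
    source_genes: Sequence[str],
    mapped_fraction: float = 0.85,
    identity_range: tuple[float, float] = (30.0, 100.0),
    seed: int | None = None,
    target_symbols: Sequence[str] | None = None,
    collision_fraction: float = 0.02,
    pinned_identity: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Synthetic source-gene -> human-symbol map with percent identities.

    ``mapped_fraction`` of the source genes receive a human symbol
    (``target_symbols[i]`` when provided, otherwise a synthesized symbol)
    with identity drawn uniformly in ``identity_range``; the remainder stay
    unmapped (absent rows). ``collision_fraction`` of mapped genes emit an
    extra row pointing a second source gene at the same symbol, exercising
    the many-to-one collapse rule downstream. ``pinned_identity`` fixes the
    identity of named source genes (e.g. to keep planted genes above the
    filter cutoff).
    """
    if not 0.0 <= mapped_fraction <= 1.0:
        raise ParameterError("mapped_fraction must lie in [0, 1]")
    lo, hi = identity_range
    if not (0.0 < lo <= hi <= 100.0):
        raise ParameterError("identity_range must lie within (0, 100]")
    if seed is None:
        raise ParameterError("seed is required")
    rng = np.random.default_rng(seed)
    source_genes = list(source_genes)
    n = len(source_genes)
    if target_symbols is not None and len(target_symbols) != n:
        raise ParameterError("target_symbols must align with source_genes")

    n_mapped = int(round(mapped_fraction * n))
    mapped_idx = np.sort(rng.choice(n, size=n_mapped, replace=False))
    if pinned_identity:
        # pinned sources are guaranteed a mapping row
        pinned_idx = [i for i, g in enumerate(source_genes) if g in pinned_identity]
        mapped_idx = np.union1d(mapped_idx, np.array(pinned_idx, dtype=int))
    rows = []
    for i in mapped_idx:
        src = source_genes[i]
        symbol = target_symbols[i] if target_symbols is not None else f"HS_{src}"
        identity = float(rng.uniform(lo, hi))
        if pinned_identity and src in pinned_identity:
            identity = float(pinned_identity[src])
        rows.append({"source_gene": src, "human_symbol": symbol, "pct_identity": round(identity, 2)})

    n_coll = int(round(collision_fraction * n_mapped))
    if n_coll and n_mapped >= 2:
        for _ in range(n_coll):
            a, b = rng.choice(len(rows), size=2, replace=False)
            rows.append(
                {
                    "source_gene": rows[a]["source_gene"],
                    "human_symbol": rows[b]["human_symbol"],
                    "pct_identity": round(float(rng.uniform(lo, hi)), 2),
                }
            )
    return pd.DataFrame(rows, columns=["source_gene", "human_symbol", "pct_identity"])
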
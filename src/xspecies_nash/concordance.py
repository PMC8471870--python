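"""Cross-cohort concordance: DEG overlap, pathway sharing, NES clustering,
and cross-projection PCA separation.

These metrics quantify how similar two disease signatures are: the raw
overlap of DEG sets (with both denominator conventions reported), the share
of top-50 enriched pathways in common and their direction agreement, a
pathways x cohorts NES matrix with hierarchical clustering of cohorts, and
the ability of one cohort's top-DEG signature to separate case from control
samples of another cohort in PCA (summarized as a rank AUC on PC1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import rankdata

from xspecies_nash.enrichment import PathwaySelection
from xspecies_nash.io_formats import ExpressionMatrix, FormatError


@dataclass(frozen=True)
class DegOverlap:
    n: int
    pct_vs_reference: float
    pct_vs_query: float


def deg_overlap(reference_degs: set[str], query_degs: set[str]) -> DegOverlap:
    """Intersection size and percentage against each DEG-set size.

    The headline number convention in cross-species comparisons divides by
    the reference (human) set size; both percentages are reported so the
    denominator is auditable.
    """
    if not reference_degs:
        raise FormatError("empty reference DEG set; percentage undefined")
    n = len(reference_degs & query_degs)
    pct_ref = 100.0 * n / len(reference_degs)
    pct_query = 100.0 * n / len(query_degs) if query_degs else 0.0
    return DegOverlap(n, pct_ref, pct_query)


@dataclass(frozen=True)
class PathwayShare:
    shared: list[str]
    share_pct: float
    n_same_direction: int
    n_opposite: int


def pathway_share(
    top50_a: PathwaySelection, top50_b: PathwaySelection, denominator: int = 50
) -> PathwayShare:
    """Shared top-pathway names and NES direction agreement.

    ``share_pct`` uses a fixed denominator of 50 (the nominal top-50 size)
    even when fewer pathways qualify, matching the x/50 reporting
    convention.
    """
    a = top50_a.table.set_index("pathway")["nes"]
    b = top50_b.table.set_index("pathway")["nes"]
    shared = sorted(set(a.index) & set(b.index))
    same = sum(1 for p in shared if np.sign(a[p]) == np.sign(b[p]))
    return PathwayShare(
        shared=shared,
        share_pct=100.0 * len(shared) / denominator,
        n_same_direction=same,
        n_opposite=len(shared) - same,
    )


def nes_concordance_matrix(
    results: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Pathways x cohorts NES matrix plus cohort clustering.

    Pathways are restricted to those evaluated (non-NaN NES) in every
    cohort. Cohorts are clustered on their NES columns with Euclidean
    distance and average linkage; the SciPy linkage matrix and the cohort
    order are returned alongside the matrix.
    """
    if len(results) < 2:
        raise FormatError("need at least two cohorts")
    cohorts = sorted(results)
    columns = {}
    for cohort in cohorts:
        t = results[cohort]
        columns[cohort] = t[t["nes"].notna()].set_index("pathway")["nes"]
    common = set.intersection(*(set(c.index) for c in columns.values()))
    if not common:
        raise FormatError("no pathway evaluated in every cohort")
    index = sorted(common)
    matrix = pd.DataFrame({c: columns[c].reindex(index) for c in cohorts}, index=index)
    z = linkage(matrix.to_numpy().T, method="average", metric="euclidean")
    return matrix, z, cohorts


@dataclass(frozen=True)
class PCAResult:
    """Sample coordinates on principal components and variance fractions."""

    coordinates: pd.DataFrame  # samples x PCs
    variance_fraction: np.ndarray

    @property
    def pc1(self) -> pd.Series:
        return self.coordinates.iloc[:, 0]


def pca(matrix: ExpressionMatrix) -> PCAResult:
    """Gene-centered (unscaled) PCA of samples via SVD.

    Sign convention: on each component the gene loading with the largest
    absolute value is made positive, so results are deterministic across
    SVD implementations.
    """
    x = matrix.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise FormatError("PCA needs at least 2 samples")
    xc = x - x.mean(axis=1, keepdims=True)
    if not np.any(xc):
        raise FormatError("constant matrix has no principal components")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign per component
    for c in range(u.shape[1]):
        pivot = np.argmax(np.abs(u[:, c]))
        if u[pivot, c] < 0:
            u[:, c] = -u[:, c]
            vt[c, :] = -vt[c, :]
    coords = (s[:, None] * vt).T
    var = s**2
    frac = var / var.sum()
    n_pc = coords.shape[1]
    coordinates = pd.DataFrame(
        coords,
        index=matrix.samples,
        columns=[f"PC{i + 1}" for i in range(n_pc)],
    )
    return PCAResult(coordinates, frac)


def _rank_auc(scores: np.ndarray, is_case: np.ndarray) -> float:
    """Rank-based AUC of scores against binary labels, folded to [0.5, 1]."""
    n1 = int(is_case.sum())
    n0 = int((~is_case).sum())
    if n0 == 0 or n1 == 0:
        raise FormatError("both groups must be non-empty for separation AUC")
    ranks = rankdata(scores)
    auc = (ranks[is_case].sum() - n1 * (n1 + 1) / 2) / (n0 * n1)
    return float(max(auc, 1.0 - auc))


@dataclass(frozen=True)
class CrossProjection:
    pca: PCAResult
    separation_auc: float
    n_genes_used: int


def cross_projection(
    signature: list[str],
    matrix_b: ExpressionMatrix,
    groups_b: pd.Series,
) -> CrossProjection:
    """Project cohort B onto another cohort's top-DEG signature.

    Subsets B (already normalized/transformed) to the signature genes
    present — at least half of the signature must be present — runs PCA,
    and summarizes case/control separation as the rank AUC of PC1 scores
    (folded, so 0.5 is chance and 1.0 is perfect separation; invariant to
    the sign of PC1).
    """
    if not signature:
        raise FormatError("empty signature")
    present = [g for g in signature if g in matrix_b.values.index]
    if len(present) < 0.5 * len(signature):
        raise FormatError(
            f"only {len(present)}/{len(signature)} signature genes present in target matrix"
        )
    sub = matrix_b.subset_genes(present)
    result = pca(sub)
    g = groups_b.reindex(sub.samples)
    if g.isna().any():
        raise FormatError("group label missing for some samples")
    is_case = (g == "case").to_numpy()
    auc = _rank_auc(result.pc1.to_numpy(), is_case)
    return CrossProjection(result, auc, len(present))
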
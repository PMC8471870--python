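"""Gene-space harmonization, count filtering, normalization, log transform.

The harmonization step maps model-organism gene ids to human symbols through
an orthologue table with a strict >50% sequence-identity cutoff (rows at or
below the cutoff, and unmapped rows, are dropped); many-to-one collisions on
a human symbol are resolved deterministically. Counts are normalized with
median-of-ratios size factors and variance-stabilized as
``log2(count / s_j + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from xspecies_nash.io_formats import ExpressionMatrix, FormatError


@dataclass(frozen=True)
class MappingReport:
    """Row-drop accounting for the orthologue harmonization step."""

    n_input: int
    n_unmapped: int
    n_low_identity: int
    n_collision_dropped: int
    n_output: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reason": ["input", "unmapped", "low_identity", "collision_dropped", "output"],
                "n_genes": [
                    self.n_input,
                    self.n_unmapped,
                    self.n_low_identity,
                    self.n_collision_dropped,
                    self.n_output,
                ],
            }
        )


def map_to_orthologues(
    matrix: ExpressionMatrix,
    orthologue_map: pd.DataFrame,
    min_identity: float = 50.0,
) -> tuple[ExpressionMatrix, MappingReport]:
    """Re-key a source-species matrix to human symbols.

    Rows without a mapping, or whose best identity is <= ``min_identity``
    (strict cutoff), are dropped. When several source genes map to the same
    human symbol, the source row with the highest identity is kept; ties are
    broken by higher mean expression, then lexicographically smaller source
    id — a deterministic rule stable under permutation of the map.
    """
    genes = matrix.values.index
    m = orthologue_map[orthologue_map["source_gene"].isin(genes)].copy()
    mapped_sources = set(m["source_gene"])
    n_unmapped = int(sum(g not in mapped_sources for g in genes))

    m = m[m["pct_identity"] > min_identity]
    kept_sources = set(m["source_gene"])
    n_low_identity = int(sum(g in mapped_sources and g not in kept_sources for g in genes))

    # A source gene with several surviving rows contributes its best row only.
    m = m.sort_values(
        ["source_gene", "pct_identity", "human_symbol"], ascending=[True, False, True]
    ).drop_duplicates("source_gene", keep="first")

    mean_expr = matrix.values.mean(axis=1)
    m = m.assign(_mean=m["source_gene"].map(mean_expr))
    m = m.sort_values(
        ["human_symbol", "pct_identity", "_mean", "source_gene"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    winners = m.drop_duplicates("human_symbol", keep="first")
    n_collision_dropped = len(m) - len(winners)

    if winners.empty:
        raise FormatError(
            "orthologue mapping produced an empty matrix; review min_identity "
            f"(={min_identity}) and the orthologue table"
        )
    out = matrix.values.loc[winners["source_gene"]].copy()
    out.index = winners["human_symbol"].to_numpy()
    out = out.sort_index()
    report = MappingReport(
        n_input=len(genes),
        n_unmapped=n_unmapped,
        n_low_identity=n_low_identity,
        n_collision_dropped=int(n_collision_dropped),
        n_output=len(out),
    )
    return ExpressionMatrix(out, matrix.platform), report


def filter_low_counts(matrix: ExpressionMatrix, min_total: int = 200) -> ExpressionMatrix:
    """Drop genes whose total count across all samples is below ``min_total``.

    The comparison is strict (< min_total removed), so a gene totalling
    exactly ``min_total`` is kept.
    """
    if matrix.platform != "count":
        raise FormatError("filter_low_counts applies to count matrices only")
    totals = matrix.values.sum(axis=1)
    kept = matrix.values[totals >= min_total]
    if kept.empty:
        raise FormatError(f"all genes fall below min_total={min_total}")
    return ExpressionMatrix(kept, "count")


def size_factors_median_of_ratios(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference convention).

    s_j = median over genes (with positive geometric mean) of
    k_ij / geomean_i(k_i.). Requires at least one gene with nonzero counts
    in every sample.
    """
    if matrix.platform != "count":
        raise FormatError("size factors are defined for count matrices")
    counts = matrix.values.to_numpy(dtype=float)
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=matrix.samples, name="size_factor")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise FormatError("no gene has positive counts in every sample")
    ref = counts[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return pd.Series(s, index=matrix.samples, name="size_factor")


def vst_log(matrix: ExpressionMatrix, size_factors: pd.Series) -> ExpressionMatrix:
    """Log variance-stabilizing transform: ``log2(count / s_j + 1)``.

    A pragmatic stand-in for regularized-log transforms: monotone per
    sample, exact at powers of two, and returning an intensity-platform
    matrix so downstream stages treat it as transformed data.
    """
    if matrix.platform != "count":
        raise FormatError("vst_log applies to count matrices")
    s = size_factors.reindex(matrix.samples)
    if s.isna().any() or (s <= 0).any():
        raise FormatError("size factors must be positive and cover every sample")
    values = np.log2(matrix.values.to_numpy(dtype=float) / s.to_numpy()[None, :] + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(values, index=matrix.values.index, columns=matrix.samples),
        "intensity",
    )
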
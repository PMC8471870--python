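"""Preranked gene-set enrichment: running-sum ES, permutation NES/p, top-50 rule.

The enrichment score of a set S against a list of N genes ranked by a
statistic r is the signed maximal deviation from zero of a running sum that
adds ``|r_i|**w / sum_hits |r|**w`` at member positions and subtracts
``1 / (N - |S|)`` elsewhere (weight exponent w = 1 by default, the classic
preranked convention; w = 0 gives the unweighted Kolmogorov-Smirnov-like
statistic with closed-form small cases). Significance comes from a
gene-label permutation null: random same-size subsets of the ranked
universe. NES divides the observed ES by the mean |null ES| of the same
sign, and the permutation p-value counts same-sign null scores at least as
extreme, with the +1 guard in numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from xspecies_nash.diffexp import bh_adjust
from xspecies_nash.io_formats import FormatError, GeneSetCollection

MIN_SET_SIZE = 5
MAX_SET_SIZE = 500


def rank_by_lfc(table: pd.DataFrame) -> pd.Series:
    """Ranked list: log2 fold change descending, ties by gene id ascending."""
    if table.empty:
        raise FormatError("cannot rank an empty DE table")
    if table["gene"].duplicated().any():
        dups = sorted(table.loc[table["gene"].duplicated(), "gene"].unique())
        raise FormatError(f"duplicate genes in DE table: {dups[:10]}")
    ordered = table.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    )
    return pd.Series(
        ordered["log2fc"].to_numpy(), index=ordered["gene"].to_numpy(), name="log2fc"
    )


def gsea_es(
    ranked: pd.Series,
    members: frozenset[str] | set[str],
    weight_exponent: float = 1.0,
) -> tuple[float, list[str]]:
    """Enrichment score and leading edge of one gene set.

    The leading edge contains the member genes at or before the running-sum
    extremum for a positive score, and at or after it for a negative score.
    """
    genes = ranked.index.to_numpy()
    hit = np.isin(genes, list(members))
    n = len(genes)
    k = int(hit.sum())
    if k == 0:
        raise FormatError("no gene-set member present in the ranked list")
    if k == n:
        raise FormatError("gene set covers the whole ranked list")
    weights = np.abs(ranked.to_numpy()) ** weight_exponent
    hit_w = np.where(hit, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member statistics are exactly zero
        hit_w = hit.astype(float)
        total = float(k)
    steps = hit_w / total - (~hit) / (n - k)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    es = float(running[idx])
    if es > 0:
        leading = genes[: idx + 1][hit[: idx + 1]]
    elif es < 0:
        leading = genes[idx:][hit[idx:]]
    else:
        leading = np.array([], dtype=genes.dtype)
    return es, [str(g) for g in leading]


def _null_es(
    rng: np.random.Generator,
    stat_weights: np.ndarray,
    k: int,
    n_perm: int,
) -> np.ndarray:
    """Vectorized null ES for random k-subsets of the ranked universe.

    Uses the position-based form of the running sum: extrema can only occur
    immediately after a hit (positive side) or immediately before one
    (negative side), so each permutation costs O(k) after the subset draw.
    """
    n = stat_weights.size
    d = 1.0 / (n - k)
    keys = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(keys, k - 1, axis=1)[:, :k], axis=1)
    w = stat_weights[pos]
    cum = np.cumsum(w, axis=1)
    total = cum[:, -1].copy()
    flat = total == 0
    if flat.any():  # all-zero weights: fall back to unweighted steps
        cum[flat] = np.arange(1, k + 1)[None, :]
        total[flat] = k
    i = np.arange(1, k + 1)[None, :]
    after = cum / total[:, None] - (pos + 1 - i) * d
    before = (cum - w) / total[:, None] - (pos - (i - 1)) * d
    if flat.any():
        before[flat] = (np.arange(k)[None, :] / k) - (pos[flat] - (i - 1)) * d
    pos_dev = np.maximum(after.max(axis=1), 0.0)
    neg_dev = np.minimum(before.min(axis=1), 0.0)
    return np.where(pos_dev >= -neg_dev, pos_dev, neg_dev)


def gsea_permutation(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int | None = None,
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
) -> pd.DataFrame:
    """Permutation GSEA over a gene-set collection.

    Sets are evaluated against their intersection with the ranked universe;
    sets outside [min_size, max_size] after intersection (or with no member
    present) are reported with NaN scores and excluded from the BH
    correction, which is applied jointly across all evaluated pathways.
    """
    if n_perm < 100:
        raise FormatError("n_perm must be >= 100")
    if seed is None:
        raise FormatError("seed is required")
    universe = set(ranked.index)
    n = len(universe)
    weights = np.abs(ranked.to_numpy()) ** weight_exponent
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in collection.items():
        present = members & universe
        k = len(present)
        if k == 0 or k < min_size or k > max_size:
            if k >= n:
                raise FormatError(f"set {name!r} is not smaller than the universe")
            rows.append(
                {
                    "pathway": name,
                    "size": k,
                    "es": np.nan,
                    "nes": np.nan,
                    "p": np.nan,
                    "q": np.nan,
                    "leading_edge": "",
                }
            )
            continue
        if k >= n:
            raise FormatError(f"set {name!r} is not smaller than the universe")
        es, leading = gsea_es(ranked, present, weight_exponent)
        null = _null_es(rng, weights, k, n_perm)
        if es >= 0:
            same = null[null > 0]
            extreme = int((same >= es).sum())
        else:
            same = -null[null < 0]
            extreme = int((same >= -es).sum())
        p = (1.0 + extreme) / (1.0 + same.size)
        denom = same.mean() if same.size else np.nan
        nes = 0.0 if es == 0 else (es / denom if denom and not np.isnan(denom) else np.nan)
        rows.append(
            {
                "pathway": name,
                "size": k,
                "es": es,
                "nes": nes,
                "p": p,
                "q": np.nan,
                "leading_edge": ",".join(leading),
            }
        )
    table = pd.DataFrame(rows)
    evaluated = table["p"].notna()
    if evaluated.any():
        table.loc[evaluated, "q"] = bh_adjust(table.loc[evaluated, "p"].to_numpy())
    return table


@dataclass(frozen=True)
class PathwaySelection:
    """Top-50 pathway list: up to 25 most up- and 25 most downregulated."""

    table: pd.DataFrame  # columns: pathway, nes, direction

    @property
    def names(self) -> list[str]:
        return list(self.table["pathway"])


def top50_pathways(
    table: pd.DataFrame, q_max: float = 0.1, n_each: int = 25
) -> PathwaySelection:
    """Select the most enriched pathways in each direction at q < q_max.

    Among pathways with q strictly below the cutoff: the ``n_each`` largest
    positive NES plus the ``n_each`` most negative NES (fewer if fewer
    qualify). The result keeps NES and a direction label.
    """
    ok = table[(table["q"].notna()) & (table["q"] < q_max)].copy()
    up = ok[ok["nes"] > 0].sort_values(
        ["nes", "pathway"], ascending=[False, True], kind="mergesort"
    ).head(n_each)
    down = ok[ok["nes"] < 0].sort_values(
        ["nes", "pathway"], ascending=[True, True], kind="mergesort"
    ).head(n_each)
    sel = pd.concat([up, down])[["pathway", "nes"]].reset_index(drop=True)
    sel["direction"] = np.where(sel["nes"] > 0, "up", "down")
    return PathwaySelection(sel)
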
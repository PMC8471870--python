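"""Fibrosis-correlation candidate-gene cascade.

Screens every gene of a transformed expression matrix for correlation with
the continuous fibrosis phenotype (relative fibrosis area, percent), in two
scopes: all samples, and NASH (case) samples alone. A candidate must

1. correlate strongly in both scopes (|rho| >= rho_min in each),
2. with the same correlation sign in both,
3. be strongly regulated in the model cohort (|log2fc| > lfc_min), and
4. change in the same direction in the advanced-disease human cohort.

Thresholds are read on absolute values: a strongly *negatively* correlated,
downregulated gene is as much a fibrosis marker as a positively correlated
upregulated one. No p- or q-value filter is applied in the cascade itself
(an optional DEG-membership filter is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from xspecies_nash.io_formats import ExpressionMatrix, FormatError


@dataclass(frozen=True)
class PearsonResult:
    rho: float
    n: int
    p: float


def pearson(x: np.ndarray, y: np.ndarray) -> PearsonResult:
    """Pearson correlation with the two-sided t-test p-value.

    t = rho * sqrt(n - 2) / sqrt(1 - rho^2) with n - 2 degrees of freedom;
    |rho| = 1 gives p = 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FormatError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise FormatError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise FormatError("correlation undefined for constant input")
    rho = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if abs(rho) == 1.0:
        return PearsonResult(rho, n, 0.0)
    t = rho * np.sqrt(n - 2) / np.sqrt(1.0 - rho**2)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return PearsonResult(rho, n, p)


def fibrosis_screen(
    expr: ExpressionMatrix,
    fibrosis: pd.Series,
    groups: pd.Series,
    gp_de: pd.DataFrame,
    human_de: pd.DataFrame,
    rho_min: float = 0.8,
    lfc_min: float = 1.0,
    require_deg_q: float | None = None,
) -> pd.DataFrame:
    """Candidate-gene table with per-criterion pass flags.

    ``expr`` must be the transformed (log-scale) model-cohort matrix;
    ``gp_de`` its DE table, and ``human_de`` the DE table of the
    advanced-disease human cohort against which direction concordance is
    checked (a gene absent there fails criterion 4).
    ``require_deg_q`` optionally adds a DEG-membership filter
    (q < threshold in ``gp_de``); it is off by default.
    Rows are sorted by gene symbol; ``passed`` is the conjunction of all
    criterion flags.
    """
    samples = list(expr.samples)
    f = fibrosis.reindex(samples)
    if f.isna().any():
        missing = [s for s, bad in zip(samples, f.isna()) if bad]
        raise FormatError(f"fibrosis area missing for samples {missing[:10]}")
    g = groups.reindex(samples)
    if g.isna().any():
        raise FormatError("group label missing for some samples")
    case_mask = (g == "case").to_numpy()
    if case_mask.sum() < 3:
        raise FormatError("need at least 3 case samples for the case-only correlation")

    gp_lfc = gp_de.set_index("gene")["log2fc"]
    gp_q = gp_de.set_index("gene")["q"]
    human_lfc = human_de.set_index("gene")["log2fc"]

    fv = f.to_numpy(dtype=float)
    fv_case = fv[case_mask]
    x = expr.values.to_numpy(dtype=float)

    rows = []
    for i, gene in enumerate(expr.values.index):
        v = x[i]
        try:
            all_res = pearson(v, fv)
        except FormatError:
            all_res = PearsonResult(np.nan, len(fv), np.nan)
        try:
            nash_res = pearson(v[case_mask], fv_case)
        except FormatError:
            nash_res = PearsonResult(np.nan, int(case_mask.sum()), np.nan)
        lfc = float(gp_lfc.get(gene, np.nan))
        h_lfc = float(human_lfc.get(gene, np.nan))

        c1 = (
            not np.isnan(all_res.rho)
            and not np.isnan(nash_res.rho)
            and abs(all_res.rho) >= rho_min
            and abs(nash_res.rho) >= rho_min
        )
        c2 = (
            not np.isnan(all_res.rho)
            and not np.isnan(nash_res.rho)
            and np.sign(all_res.rho) == np.sign(nash_res.rho)
            and np.sign(all_res.rho) != 0
        )
        c3 = not np.isnan(lfc) and abs(lfc) > lfc_min
        c4 = (
            not np.isnan(lfc)
            and not np.isnan(h_lfc)
            and np.sign(lfc) == np.sign(h_lfc)
            and np.sign(lfc) != 0
        )
        passed = bool(c1 and c2 and c3 and c4)
        if require_deg_q is not None:
            passed = passed and bool(gp_q.get(gene, np.nan) < require_deg_q)
        rows.append(
            {
                "gene": gene,
                "rho_all": all_res.rho,
                "p_all": all_res.p,
                "rho_nash": nash_res.rho,
                "p_nash": nash_res.p,
                "gp_log2fc": lfc,
                "human_log2fc": h_lfc,
                "pass_correlation": bool(c1),
                "pass_sign_consistency": bool(c2),
                "pass_lfc": bool(c3),
                "pass_human_direction": bool(c4),
                "passed": passed,
            }
        )
    table = pd.DataFrame(rows).sort_values("gene", kind="mergesort").reset_index(drop=True)
    return table


def candidate_genes(screen_table: pd.DataFrame) -> list[str]:
    """Genes passing every criterion of the cascade, alphabetically."""
    return list(screen_table.loc[screen_table["passed"], "gene"])
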
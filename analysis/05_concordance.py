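"""Cross-cohort concordance: DEG overlap, pathway sharing, NES clustering,
cross-projection PCA.

Quantifies how well the model cohort's disease signature transfers to the
human-like cohorts: percentage DEG overlap (reference denominator), the
share of top-50 pathways in common with the advanced-disease cohort and
their direction agreement, hierarchical clustering of cohorts on NES
profiles, and the separation AUC when the human cohort is projected onto
the model cohort's top-200 signature.
"""

import json

from _common import ensure_study, load_processed, out_path, parse_seed

from xspecies_nash.concordance import (
    cross_projection,
    deg_overlap,
    nes_concordance_matrix,
    pathway_share,
    pca,
)
from xspecies_nash.diffexp import select_degs, top_n_by_abs_lfc
from xspecies_nash.enrichment import gsea_permutation, rank_by_lfc, top50_pathways
from xspecies_nash.io_formats import read_gmt
from xspecies_nash.pipeline import run_de
from xspecies_nash.study import derive_seed


def main() -> None:
    seed = parse_seed(__doc__)
    config = ensure_study(seed)
    collection = read_gmt(config.gene_sets)

    cohorts, de_tables, enr_tables, top50 = {}, {}, {}, {}
    for cfg in config.cohorts:
        cohorts[cfg.cohort_id] = load_processed(config, cfg.cohort_id)
        de_tables[cfg.cohort_id] = run_de(cohorts[cfg.cohort_id])
        enr_tables[cfg.cohort_id] = gsea_permutation(
            rank_by_lfc(de_tables[cfg.cohort_id]), collection,
            n_perm=int(config.thresholds["n_perm"]),
            seed=derive_seed(config.seed, f"gsea:{cfg.cohort_id}"),
        )
        top50[cfg.cohort_id] = top50_pathways(enr_tables[cfg.cohort_id])

    role = {c.cohort_id: c.role for c in config.cohorts}
    gp = next(c for c, r in role.items() if r == "gp")
    h1 = next(c for c, r in role.items() if r == "hnash1")
    h2 = next(c for c, r in role.items() if r == "hnash2")

    ov = deg_overlap(select_degs(de_tables[h1]), select_degs(de_tables[gp]))
    print(
        f"DEG overlap {gp} vs {h1}: {ov.n} genes = {ov.pct_vs_reference:.1f}% of the "
        f"human reference set ({ov.pct_vs_query:.1f}% of the model set)"
    )

    signature = top_n_by_abs_lfc(de_tables[gp], int(config.thresholds["top_n"]))
    proj = cross_projection(signature, cohorts[h1].transformed, cohorts[h1].groups)
    print(
        f"cross-projection of the {gp} top-200 signature onto {h1}: "
        f"separation AUC {proj.separation_auc:.2f} "
        f"(PC1 {100 * proj.pca.variance_fraction[0]:.1f}% of variance)"
    )

    print(f"\ntop-50 pathway share vs {h2} (share of 50, direction agreement):")
    shares = {}
    for cid in cohorts:
        if cid == h2:
            continue
        sh = pathway_share(top50[h2], top50[cid])
        shares[cid] = sh
        print(
            f"  {cid:8s}: {len(sh.shared):2d}/50 = {sh.share_pct:4.1f}% "
            f"({sh.n_same_direction} same direction, {sh.n_opposite} opposite)"
        )

    nes, link, order = nes_concordance_matrix(enr_tables)
    nes.to_csv(out_path("nes_matrix.tsv"), sep="\t")
    print(f"\nNES clustering over {nes.shape[0]} shared pathways, cohorts: {order}")
    print("merge heights:", [round(float(h), 2) for h in link[:, 2]])

    res = pca(cohorts[gp].transformed)
    print(f"{gp} PCA: PC1 explains {100 * res.variance_fraction[0]:.2f}% of variance")

    summary = {
        "deg_overlap_pct": ov.pct_vs_reference,
        "cross_projection_auc": proj.separation_auc,
        "share_pct": {c: s.share_pct for c, s in shares.items()},
        "pc1_pct": 100 * res.variance_fraction[0],
    }
    with open(out_path("concordance_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
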
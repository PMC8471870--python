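"""Preranked GSEA per cohort and the top-50 pathway selections.

Ranks each cohort's genes by log2 fold change, runs permutation GSEA
against the study gene sets, and reports the 25 most up- and downregulated
pathways at q < 0.1 per cohort.
"""

import pandas as pd
from _common import ensure_study, load_processed, out_path, parse_seed

from xspecies_nash.enrichment import gsea_permutation, rank_by_lfc, top50_pathways
from xspecies_nash.io_formats import read_gmt
from xspecies_nash.pipeline import run_de
from xspecies_nash.study import derive_seed


def main() -> None:
    seed = parse_seed(__doc__)
    config = ensure_study(seed)
    collection = read_gmt(config.gene_sets)
    for cfg in config.cohorts:
        cohort = load_processed(config, cfg.cohort_id)
        de = run_de(cohort)
        enr = gsea_permutation(
            rank_by_lfc(de),
            collection,
            n_perm=int(config.thresholds["n_perm"]),
            seed=derive_seed(config.seed, f"gsea:{cfg.cohort_id}"),
        )
        enr.to_csv(out_path(f"gsea_{cfg.cohort_id}.tsv"), sep="\t", index=False)
        sel = top50_pathways(enr, config.thresholds["q_pathway"])
        sel.table.to_csv(out_path(f"top50_{cfg.cohort_id}.tsv"), sep="\t", index=False)
        n_up = int((sel.table["direction"] == "up").sum())
        n_down = len(sel.table) - n_up
        sig = enr["q"].lt(0.1).sum()
        print(
            f"{cfg.cohort_id:8s}: {sig:3d} pathways at q < 0.1; "
            f"top-50 selection keeps {n_up} up + {n_down} down"
        )
        top3 = sel.table.head(3)
        if not top3.empty:
            txt = ", ".join(f"{r.pathway} (NES {r.nes:+.2f})" for r in top3.itertuples())
            print(f"          strongest: {txt}")


if __name__ == "__main__":
    main()
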
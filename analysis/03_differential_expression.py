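"""Differential expression in every cohort and the top-20 signature.

Counts DEGs (BH q < 0.05) per cohort — NB Wald for the sequencing cohorts,
moderated t for the array cohorts — and prints the model cohort's top-20
genes by absolute log2 fold change.
"""

from _common import ensure_study, load_processed, out_path, parse_seed

from xspecies_nash.diffexp import select_degs, top_n_by_abs_lfc
from xspecies_nash.pipeline import run_de


def main() -> None:
    seed = parse_seed(__doc__)
    config = ensure_study(seed)
    gp_table = None
    for cfg in config.cohorts:
        cohort = load_processed(config, cfg.cohort_id)
        de = run_de(cohort)
        de.to_csv(out_path(f"de_{cfg.cohort_id}.tsv"), sep="\t", index=False)
        degs = select_degs(de, config.thresholds["q_deg"])
        engine = "NB Wald" if cfg.platform == "count" else "moderated t"
        print(f"{cfg.cohort_id:8s} ({engine:11s}): {len(degs):4d} DEGs at q < 0.05")
        if cfg.role == "gp":
            gp_table = de

    top20 = top_n_by_abs_lfc(gp_table, 20)
    show = gp_table.set_index("gene").loc[top20, ["log2fc", "q"]]
    print("\nmodel-cohort top 20 DEGs by |log2FC|:")
    print(show.round(3).to_string())


if __name__ == "__main__":
    main()
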
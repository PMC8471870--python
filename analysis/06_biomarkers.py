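"""Fibrosis-correlation candidate-gene cascade on the model cohort.

Correlates every harmonized gene with the per-animal relative fibrosis
area (all animals, and NASH animals alone), applies the four-criterion
cascade (|rho| >= 0.8 in both scopes, consistent sign, |log2FC| > 1,
direction-concordant in the advanced-disease human cohort), and compares
the candidate list against the planted truth.
"""

import pandas as pd
from _common import DATA_DIR, ensure_study, load_processed, out_path, parse_seed

from xspecies_nash.biomarker import candidate_genes, fibrosis_screen
from xspecies_nash.pipeline import run_de


def main() -> None:
    seed = parse_seed(__doc__)
    config = ensure_study(seed)
    role = {c.cohort_id: c.role for c in config.cohorts}
    gp = next(c for c, r in role.items() if r == "gp")
    h2 = next(c for c, r in role.items() if r == "hnash2")

    gp_cohort = load_processed(config, gp)
    h2_cohort = load_processed(config, h2)
    fibrosis = gp_cohort.samples.set_index("sample")["fibrosis_area"]

    screen = fibrosis_screen(
        gp_cohort.transformed,
        fibrosis,
        gp_cohort.groups,
        run_de(gp_cohort),
        run_de(h2_cohort),
        rho_min=config.thresholds["rho_min"],
        lfc_min=config.thresholds["lfc_min"],
    )
    screen.to_csv(out_path("biomarker_screen.tsv"), sep="\t", index=False)

    candidates = candidate_genes(screen)
    print(f"{len(screen)} genes screened; {len(candidates)} candidates pass the cascade:")
    cols = ["gene", "rho_all", "p_all", "rho_nash", "p_nash", "gp_log2fc", "human_log2fc"]
    table = screen[screen["passed"]][cols].round(3)
    print(table.to_string(index=False))

    truth = pd.read_csv(DATA_DIR / "data" / "candidate_truth.tsv", sep="\t")["gene"].tolist()
    recovered = sorted(set(candidates) & set(truth))
    extra = sorted(set(candidates) - set(truth))
    print(f"\nplanted truth: {len(truth)} genes; recovered {len(recovered)}/{len(truth)}")
    if extra:
        print(f"additional screen hits not planted: {extra}")


if __name__ == "__main__":
    main()
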
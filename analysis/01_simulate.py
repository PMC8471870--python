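"""Generate the synthetic multi-cohort study with known planted truth.

Writes six cohorts (a 6 vs 6 model-organism count cohort with per-animal
fibrosis areas, two human-like cohorts, three small array cohorts), the
gene-set GMT, the orthologue map, and the truth tables under results/study.
"""

from _common import DATA_DIR, ensure_study, parse_seed

from xspecies_nash.io_formats import read_expression


def main() -> None:
    seed = parse_seed(__doc__)
    config = ensure_study(seed)
    print(f"synthetic study (seed {seed}) written under {DATA_DIR}")
    for cohort in config.cohorts:
        matrix = read_expression(cohort.expression, cohort.platform)
        n_genes, n_samples = matrix.values.shape
        print(
            f"  {cohort.cohort_id:8s} role={cohort.role:7s} platform={cohort.platform:9s} "
            f"{n_genes} genes x {n_samples} samples"
        )
    print("planted truth: per-cohort *_truth.tsv, pathway_truth.tsv, candidate_truth.tsv")


if __name__ == "__main__":
    main()
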
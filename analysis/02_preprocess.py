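"""Harmonize the model cohort to human symbols and filter low counts.

Reports how many genes survive the >50% identity orthologue cutoff and the
total-count >= 200 filter, mirroring the annotation funnel of a
cross-species RNA-seq study.
"""

from _common import ensure_study, out_path, parse_seed

from xspecies_nash.io_formats import read_expression, read_orthologue_map, write_expression
from xspecies_nash.preprocess import (
    filter_low_counts,
    map_to_orthologues,
    size_factors_median_of_ratios,
    vst_log,
)


def main() -> None:
    seed = parse_seed(__doc__)
    config = ensure_study(seed)
    gp = next(c for c in config.cohorts if c.role == "gp")
    matrix = read_expression(gp.expression, "count")
    orth = read_orthologue_map(gp.orthologues)

    mapped, report = map_to_orthologues(matrix, orth, config.thresholds["min_identity"])
    print(f"orthologue harmonization of {gp.cohort_id}:")
    print(report.as_frame().to_string(index=False))

    filtered = filter_low_counts(mapped, config.thresholds["min_total"])
    print(
        f"low-count filter (total < {config.thresholds['min_total']}): "
        f"{mapped.values.shape[0]} -> {filtered.values.shape[0]} genes"
    )
    s = size_factors_median_of_ratios(filtered)
    print(f"size factors: min {s.min():.3f}, max {s.max():.3f} (median-of-ratios)")

    write_expression(filtered, out_path("gp_harmonized_counts.tsv"))
    write_expression(vst_log(filtered, s), out_path("gp_vst.tsv"))
    report.as_frame().to_csv(out_path("gp_mapping_report.tsv"), sep="\t", index=False)
    print(f"tables written under {out_path('').parent}")


if __name__ == "__main__":
    main()
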
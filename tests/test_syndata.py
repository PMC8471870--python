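import numpy as np
import pandas as pd
import pytest

from xspecies_nash.biomarker import pearson
from xspecies_nash.diffexp import moderated_t_test, nb_wald_test
from xspecies_nash.preprocess import size_factors_median_of_ratios
from xspecies_nash.syndata import (
    CohortSpec,
    ParameterError,
    generate_array_cohort,
    generate_count_cohort,
    generate_fibrosis,
    generate_gene_sets,
    generate_orthologue_map,
    pathway_lfc_by_cohort,
    plant_correlated_genes,
)


def count_spec(**kw):
    base = dict(
        cohort_id="c", platform="count", n_genes=200, n_control=4, n_case=4, seed=1
    )
    base.update(kw)
    return CohortSpec(**base)


def array_spec(**kw):
    base = dict(
        cohort_id="a", platform="intensity", n_genes=200, n_control=4, n_case=4, seed=1
    )
    base.update(kw)
    return CohortSpec(**base)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_control=1),
            dict(de_fraction=1.5),
            dict(nb_dispersion=-0.1),
            dict(lfc_scale=0.0),
            dict(seed=None),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ParameterError):
            count_spec(**kw)

    def test_noise_sd_must_be_positive_for_arrays(self):
        with pytest.raises(ParameterError):
            array_spec(noise_sd=0.0)


class TestCountCohort:
    def test_no_effects_requested_gives_all_zero_truth(self):
        _, truth = generate_count_cohort(count_spec(de_fraction=0.0))
        assert (truth["planted_lfc"] == 0).all()

    def test_deterministic_for_fixed_seed(self):
        m1, t1 = generate_count_cohort(count_spec(de_fraction=0.2))
        m2, t2 = generate_count_cohort(count_spec(de_fraction=0.2))
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_counts_are_nonnegative_integers(self):
        m, _ = generate_count_cohort(count_spec(de_fraction=0.3))
        arr = m.values.to_numpy()
        assert np.issubdtype(arr.dtype, np.integer)
        assert (arr >= 0).all()

    def test_truth_covers_matrix_genes_exactly(self):
        m, truth = generate_count_cohort(count_spec(de_fraction=0.1))
        assert list(truth["gene"]) == list(m.values.index)

    def test_extra_lfc_overrides_planting(self):
        m, truth = generate_count_cohort(
            count_spec(de_fraction=0.0, n_genes=50), extra_lfc={"G00007": 2.5}
        )
        assert truth.set_index("gene").loc["G00007", "planted_lfc"] == 2.5

    def test_downstream_sign_recovery_for_strong_planted_genes(self):
        # parameter-recovery simulation: DE calls vs the returned truth table
        spec = count_spec(
            n_genes=2000, n_control=6, n_case=6, de_fraction=0.1, lfc_scale=2.0,
            nb_dispersion=0.05, seed=7,
        )
        matrix, truth = generate_count_cohort(spec)
        s = size_factors_median_of_ratios(matrix)
        de = nb_wald_test(matrix, spec.groups(), s).set_index("gene")
        strong = truth[truth["planted_lfc"].abs() >= 1].set_index("gene")
        est = de.loc[strong.index, "log2fc"]
        sign_ok = (np.sign(est) == np.sign(strong["planted_lfc"])).mean()
        assert sign_ok >= 0.90
        close = (est - strong["planted_lfc"]).abs() <= 0.5
        assert close.mean() >= 0.90


class TestArrayCohort:
    def test_noise_free_limit_recovers_planted_difference(self):
        spec = array_spec(noise_sd=1e-9, n_genes=20)
        m, _ = generate_array_cohort(spec, extra_lfc={"G00003": 3.0})
        row = m.values.loc["G00003"]
        diff = row[4:].mean() - row[:4].mean()
        assert diff == pytest.approx(3.0, abs=1e-6)

    def test_deterministic_for_fixed_seed(self):
        m1, _ = generate_array_cohort(array_spec(de_fraction=0.2))
        m2, _ = generate_array_cohort(array_spec(de_fraction=0.2))
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_null_cohort_moderated_t_is_calibrated(self):
        # type-I simulation at the spec's stated size; binomial tolerance
        spec = array_spec(n_genes=5000, n_control=5, n_case=5, de_fraction=0.0, seed=11)
        m, _ = generate_array_cohort(spec)
        de = moderated_t_test(m, spec.groups())
        assert (de["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.01)


class TestFibrosis:
    def test_defaults_give_positive_values_near_group_targets(self):
        f = generate_fibrosis(6, 6, seed=3)
        assert (f > 0).all()
        ctrl, case = f[:6], f[6:]
        assert abs(ctrl.mean() - 1.39) <= 3 * 0.24 / np.sqrt(6)
        assert abs(case.mean() - 7.48) <= 3 * 1.81 / np.sqrt(6)

    def test_zero_sd_is_degenerate_at_the_mean(self):
        f = generate_fibrosis(4, 4, control_sd=0.0, seed=1)
        assert (f[:4] == 1.39).all()

    def test_deterministic_for_fixed_seed(self):
        a = generate_fibrosis(6, 6, seed=5)
        b = generate_fibrosis(6, 6, seed=5)
        pd.testing.assert_series_equal(a, b)


class TestPlantCorrelatedGenes:
    def _setup(self, seed=2):
        spec = count_spec(n_genes=100, n_control=6, n_case=6, seed=seed,
                          baseline_log2_mean_range=(6.0, 10.0))
        matrix, _ = generate_count_cohort(spec)
        fib = generate_fibrosis(6, 6, seed=seed + 1, sample_ids=spec.sample_ids())
        return spec, matrix, fib

    def test_exact_mode_pins_all_samples_correlation(self):
        _, matrix, fib = self._setup()
        planted, _ = plant_correlated_genes(
            matrix, fib, ["G00010"], target_rho=0.8, exact=True, seed=9
        )
        s = size_factors_median_of_ratios(matrix)
        y = np.log2(planted.values.loc["G00010"].to_numpy() / s.to_numpy() + 1.0)
        rho = pearson(y, fib.to_numpy()).rho
        # rounding back to counts perturbs the planted values slightly
        assert rho == pytest.approx(0.8, abs=0.02)

    def test_exact_mode_on_intensity_matrix_is_machine_exact(self):
        spec = array_spec(n_genes=50, n_control=6, n_case=6, seed=4)
        matrix, _ = generate_array_cohort(spec)
        fib = generate_fibrosis(6, 6, seed=5, sample_ids=spec.sample_ids())
        planted, _ = plant_correlated_genes(
            matrix, fib, ["G00001"], target_rho=0.8, exact=True, seed=9
        )
        rho = pearson(planted.values.loc["G00001"].to_numpy(), fib.to_numpy()).rho
        assert rho == pytest.approx(0.8, abs=1e-9)

    def test_rho_one_gives_affine_function_of_fibrosis(self):
        spec = array_spec(n_genes=50, n_control=6, n_case=6, seed=4)
        matrix, _ = generate_array_cohort(spec)
        fib = generate_fibrosis(6, 6, seed=5, sample_ids=spec.sample_ids())
        planted, _ = plant_correlated_genes(
            matrix, fib, ["G00002"], target_rho=1.0, exact=True, seed=9
        )
        y = planted.values.loc["G00002"].to_numpy()
        resid = np.polyfit(fib.to_numpy(), y, 1, full=True)[1]
        assert float(resid[0]) == pytest.approx(0.0, abs=1e-18)

    def test_group_aware_mode_pins_within_group_correlations(self):
        spec = array_spec(n_genes=50, n_control=6, n_case=6, seed=4)
        matrix, _ = generate_array_cohort(spec)
        fib = generate_fibrosis(6, 6, seed=5, sample_ids=spec.sample_ids())
        planted, _ = plant_correlated_genes(
            matrix, fib, ["G00003"], target_rho=0.95,
            groups=spec.groups(), exact=True, lfc=1.5, seed=9,
        )
        y = planted.values.loc["G00003"]
        case = [s for s in y.index if "case" in s]
        ctrl = [s for s in y.index if "ctrl" in s]
        rho_case = pearson(y[case].to_numpy(), fib[case].to_numpy()).rho
        rho_ctrl = pearson(y[ctrl].to_numpy(), fib[ctrl].to_numpy()).rho
        assert rho_case == pytest.approx(0.95, abs=1e-9)
        assert rho_ctrl == pytest.approx(0.95, abs=1e-9)
        assert y[case].mean() - y[ctrl].mean() == pytest.approx(1.5, abs=1e-9)

    def test_target_rho_out_of_range_rejected(self):
        _, matrix, fib = self._setup()
        with pytest.raises(ParameterError):
            plant_correlated_genes(matrix, fib, ["G00001"], target_rho=1.2, seed=1)

    def test_unknown_gene_rejected(self):
        _, matrix, fib = self._setup()
        with pytest.raises(ParameterError, match="NOPE"):
            plant_correlated_genes(matrix, fib, ["NOPE"], target_rho=0.5, seed=1)


class TestGeneSets:
    def test_zero_sets_gives_empty_collection(self):
        coll, truth = generate_gene_sets([f"g{i}" for i in range(50)], 0, (5, 10), seed=1)
        assert len(coll) == 0
        assert truth.empty

    def test_size_range_exceeding_universe_rejected(self):
        with pytest.raises(ParameterError):
            generate_gene_sets(["a", "b", "c"], 1, (5, 10), seed=1)

    def test_planted_shifts_propagate_to_cohort_lfc_maps(self):
        genes = [f"g{i}" for i in range(100)]
        coll, truth = generate_gene_sets(
            genes, 5, (5, 10),
            planted_shifts={"UP_A": {"x": 1.0, "y": 1.0}, "DN_B": {"x": -1.0}},
            seed=2,
        )
        by_cohort = pathway_lfc_by_cohort(coll, truth)
        assert set(by_cohort) == {"x", "y"}
        for g in coll["UP_A"]:
            assert by_cohort["x"][g] == 1.0
        for g in coll["DN_B"]:
            assert by_cohort["x"][g] == -1.0

    def test_deterministic_for_fixed_seed(self):
        genes = [f"g{i}" for i in range(100)]
        a, _ = generate_gene_sets(genes, 5, (5, 10), seed=7)
        b, _ = generate_gene_sets(genes, 5, (5, 10), seed=7)
        assert dict(a.items()) == dict(b.items())


class TestOrthologueMap:
    def test_full_mapping_high_identity_passes_any_filter(self):
        m = generate_orthologue_map(
            ["s1", "s2", "s3"], mapped_fraction=1.0, identity_range=(90.0, 100.0), seed=1
        )
        assert set(m["source_gene"]) == {"s1", "s2", "s3"}
        assert (m["pct_identity"] > 50).all()

    def test_zero_mapping_gives_empty_map(self):
        m = generate_orthologue_map(["s1", "s2"], mapped_fraction=0.0, seed=1)
        assert m.empty

    def test_deterministic_for_fixed_seed(self):
        a = generate_orthologue_map([f"s{i}" for i in range(50)], seed=3)
        b = generate_orthologue_map([f"s{i}" for i in range(50)], seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_pinned_identity_respected(self):
        m = generate_orthologue_map(
            ["s1", "s2"], mapped_fraction=1.0, seed=1, pinned_identity={"s1": 100.0}
        )
        assert m.set_index("source_gene").loc["s1", "pct_identity"] == 100.0
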
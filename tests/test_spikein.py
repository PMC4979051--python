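import numpy as np
import pytest

from probetest import (
    ConfigurationError,
    DomainError,
    SpikeInDesign,
    SpikeInModel,
    ValidationError,
    default_concentrations,
    rearrange_latin_square,
    run_probe_level_test,
    simulate_latin_square,
    simulate_two_condition,
    summarize_with_background_error,
)


def constant_model(background=0.0, affinity=1.0, noise_cv=0.0, **kwargs):
    return SpikeInModel(
        noise_cv=noise_cv,
        background_median=background,
        background_sdlog=0.0,
        affinity_median=affinity,
        affinity_sdlog=0.0,
        **kwargs,
    )


def toy_design(**kwargs):
    defaults = dict(
        n_groups=4,
        genes_per_group=2,
        replicates=2,
        concentrations=default_concentrations(4),
        n_null_genes=0,
        probes_per_gene=3,
    )
    defaults.update(kwargs)
    return SpikeInDesign(**defaults)


class TestDesign:
    def test_paper_defaults(self):
        design = SpikeInDesign()
        assert design.n_groups == 14
        assert design.n_spiked_genes == 42
        assert design.n_samples == 42
        assert design.probes_per_gene == 11
        assert design.concentrations[0] == 0.0
        assert design.concentrations[-1] == 512.0
        # doubling series after the 0
        ratios = np.diff(np.log2(design.concentrations[1:]))
        np.testing.assert_allclose(ratios, 1.0)

    def test_latin_square_property_exhaustive(self):
        design = SpikeInDesign()
        for m in range(design.n_groups):
            visited = sorted(
                design.concentration_index(m, k) for k in range(design.n_groups)
            )
            assert visited == list(range(design.n_groups))

    def test_concentration_count_must_match_groups(self):
        with pytest.raises(ConfigurationError):
            SpikeInDesign(n_groups=5, concentrations=(0.0, 1.0, 2.0))

    def test_schedule_shape(self):
        design = toy_design()
        sched = design.schedule()
        assert sched.shape == (design.n_spiked_genes, design.n_samples)


class TestRearrange:
    def test_paper_design_counts(self):
        experiments = rearrange_latin_square(SpikeInDesign())
        assert len(experiments) == 14
        for exp in experiments:
            assert len(exp.truth) == 39
            assert len(exp.excluded) == 3
            assert not (exp.truth & exp.excluded)

    def test_every_spiked_gene_in_exactly_one_bucket(self):
        design = SpikeInDesign()
        all_spiked = {
            g for m in range(design.n_groups) for g in design.spiked_gene_ids(m)
        }
        for exp in rearrange_latin_square(design):
            assert exp.truth | exp.excluded == all_spiked

    def test_toy_design_counts(self):
        experiments = rearrange_latin_square(toy_design())
        assert len(experiments) == 4
        for exp in experiments:
            assert len(exp.truth) == 6
            assert len(exp.excluded) == 2

    def test_closed_form_truth_size(self):
        for n_groups, gpg in [(3, 1), (5, 4), (14, 3)]:
            design = toy_design(
                n_groups=n_groups,
                genes_per_group=gpg,
                concentrations=default_concentrations(n_groups),
            )
            experiments = rearrange_latin_square(design)
            assert len(experiments) == n_groups
            assert all(len(e.truth) == gpg * (n_groups - 1) for e in experiments)

    def test_excluded_group_spans_the_wrap(self):
        design = toy_design()
        for k, exp in enumerate(rearrange_latin_square(design)):
            (m,) = {
                m
                for m in range(design.n_groups)
                if set(design.spiked_gene_ids(m)) == set(exp.excluded)
            }
            # transition of the excluded group runs from the last schedule
            # index (maximum concentration) back to index 0 (0 pM)
            assert design.concentration_index(m, k) == design.n_groups - 1
            assert design.concentration_index(m, k + 1) == 0

    def test_truth_fold_change_is_two_off_the_zero_transition(self):
        design = SpikeInDesign()
        for k, exp in enumerate(rearrange_latin_square(design)):
            for m in range(design.n_groups):
                genes = set(design.spiked_gene_ids(m))
                if not (genes <= exp.truth):
                    continue
                c_a = design.concentration(m, k)
                c_b = design.concentration(m, (k + 1) % design.n_groups)
                if c_a > 0:
                    assert c_b == pytest.approx(2 * c_a)

    def test_requires_zero_concentration(self):
        design = toy_design(concentrations=(1.0, 2.0, 4.0, 8.0))
        with pytest.raises(ConfigurationError):
            rearrange_latin_square(design)

    def test_experiment_design_conversion(self):
        exp = rearrange_latin_square(toy_design())[0]
        design = exp.to_design()
        assert design.n_a == 2 and design.n_b == 2


class TestSimulateLatinSquare:
    def test_noiseless_identity(self):
        design = toy_design(genes_per_group=1, replicates=1, probes_per_gene=1)
        sim = simulate_latin_square(design, constant_model(), seed=0)
        np.testing.assert_array_equal(
            sim.matrix.values, design.schedule().to_numpy()
        )

    def test_deterministic_per_seed(self):
        design = toy_design(n_null_genes=5)
        a = simulate_latin_square(design, seed=11)
        b = simulate_latin_square(design, seed=11)
        np.testing.assert_array_equal(a.matrix.values, b.matrix.values)
        assert a.model.background == b.model.background

    def test_different_seeds_differ(self):
        design = toy_design(n_null_genes=5)
        a = simulate_latin_square(design, seed=1)
        b = simulate_latin_square(design, seed=2)
        assert not np.array_equal(a.matrix.values, b.matrix.values)

    def test_background_recovered_at_zero_concentration(self):
        # theta = 0 everywhere: intensities are B * eps with E[eps] = 1
        design = SpikeInDesign(
            n_groups=2,
            genes_per_group=1,
            replicates=300,
            concentrations=(0.0, 0.0),
            probes_per_gene=1,
        )
        model = SpikeInModel(
            noise_cv=0.3,
            background={"spike_01_1:01": 80.0, "spike_02_1:01": 80.0},
            affinity={"spike_01_1:01": 1.0, "spike_02_1:01": 1.0},
        )
        sim = simulate_latin_square(design, model, seed=4)
        sample_mean = sim.matrix.values[0].mean()
        se = 80.0 * 0.3 / np.sqrt(sim.matrix.n_samples)
        assert abs(sample_mean - 80.0) < 3 * se

    def test_null_theta_constant_across_samples(self):
        design = toy_design(n_null_genes=4)
        sim = simulate_latin_square(design, seed=2)
        null_rows = sim.theta.loc[[g for g in sim.theta.index if g.startswith("null")]]
        assert (null_rows.nunique(axis=1) == 1).all()

    def test_negative_noise_cv_rejected(self):
        with pytest.raises(DomainError):
            SpikeInModel(noise_cv=-0.1)


class TestSimulateTwoCondition:
    def test_no_deg_empty_truth(self):
        _, _, truth = simulate_two_condition(10, 0, 2.0, 3, 3, seed=0)
        assert truth == frozenset()

    def test_deterministic_per_seed(self):
        a = simulate_two_condition(12, 3, 2.0, 4, 4, seed=5)
        b = simulate_two_condition(12, 3, 2.0, 4, 4, seed=5)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        assert a[2] == b[2]

    def test_fold_change_applied_to_truth_genes(self):
        model = constant_model(background=0.0, affinity=1.0, noise_cv=0.0)
        matrix, design, truth = simulate_two_condition(
            6, 2, 2.0, 3, 3, model=model, probes_per_gene=1, seed=8
        )
        idx_a = [matrix.sample_index(s) for s in design.samples_a]
        idx_b = [matrix.sample_index(s) for s in design.samples_b]
        for i, probe in enumerate(matrix.probe_ids):
            gene = matrix.probe_to_gene[probe]
            ratio = matrix.values[i, idx_b].mean() / matrix.values[i, idx_a].mean()
            assert ratio == pytest.approx(2.0 if gene in truth else 1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(DomainError):
            simulate_two_condition(5, 6, 2.0, 3, 3)
        with pytest.raises(DomainError):
            simulate_two_condition(5, 1, 0.0, 3, 3)
        with pytest.raises(ConfigurationError):
            simulate_two_condition(5, 1, 2.0, 1, 3)

    def test_noiseless_truth_ranks_above_nulls(self):
        model = constant_model(background=0.0, affinity=1.0, noise_cv=0.0)
        matrix, design, truth = simulate_two_condition(
            20, 5, 2.0, 3, 3, model=model, probes_per_gene=3, seed=3
        )
        results = run_probe_level_test(matrix, design, normalize=False)
        ranked = [r.gene_id for r in sorted(results, key=lambda r: r.rank)]
        assert set(ranked[: len(truth)]) == set(truth)


class TestSummarize:
    def test_perfect_recovery_without_errors(self):
        model = constant_model(background=10.0, affinity=1.0, noise_cv=0.0)
        matrix, design, _, realized = simulate_two_condition(
            5, 0, 2.0, 3, 3, model=model, probes_per_gene=4, seed=0, return_model=True
        )
        expr = summarize_with_background_error(matrix, realized, 0.0, seed=1)
        # theta is constant per gene across samples; recovered exactly
        assert (expr.nunique(axis=1) == 1).all()
        np.testing.assert_allclose(
            expr.to_numpy(), matrix.values[::4, :] - 10.0, rtol=1e-12
        )

    def test_floor_respected(self):
        model = constant_model(background=100.0, affinity=1.0, noise_cv=0.0)
        matrix, _, _, realized = simulate_two_condition(
            5, 0, 2.0, 3, 3, model=model, probes_per_gene=3, seed=0, return_model=True
        )
        expr = summarize_with_background_error(
            matrix, realized, 500.0, seed=2, floor=0.5
        )
        assert (expr.to_numpy() >= 0.5).all()

    def test_low_expression_suffers_larger_relative_error(self):
        # same misestimation noise, theta 5 vs 500: relative error shrinks
        model_lo = constant_model(background=100.0, affinity=1.0, noise_cv=0.0,
                                  theta_median=5.0, theta_sdlog=0.0)
        model_hi = constant_model(background=100.0, affinity=1.0, noise_cv=0.0,
                                  theta_median=500.0, theta_sdlog=0.0)
        rel_errors = {}
        for name, model, theta in [("lo", model_lo, 5.0), ("hi", model_hi, 500.0)]:
            errs = []
            for seed in range(10):
                matrix, _, _, realized = simulate_two_condition(
                    30, 0, 2.0, 3, 3, model=model, probes_per_gene=3,
                    seed=seed, return_model=True,
                )
                expr = summarize_with_background_error(
                    matrix, realized, 20.0, seed=seed + 100
                )
                errs.append(np.abs(expr.to_numpy() - theta).mean() / theta)
            rel_errors[name] = np.mean(errs)
        assert rel_errors["lo"] > 5 * rel_errors["hi"]

    def test_requires_realized_model(self):
        matrix, _, _ = simulate_two_condition(3, 0, 2.0, 3, 3, seed=0)
        with pytest.raises(ValidationError):
            summarize_with_background_error(matrix, SpikeInModel(), 1.0, seed=0)

    def test_negative_sd_rejected(self):
        matrix, _, _, realized = simulate_two_condition(
            3, 0, 2.0, 3, 3, seed=0, return_model=True
        )
        with pytest.raises(DomainError):
            summarize_with_background_error(matrix, realized, -1.0, seed=0)
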
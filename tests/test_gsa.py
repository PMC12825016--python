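"""Global sensitivity analysis: LHS stratification, MLRA, ranking tests."""

import numpy as np
import pytest

from nanopbpk import GsaConfig, SensitivityResult, load_kinetics, rank_parameters, run_gsa
from nanopbpk.gsa import OUTPUT_NAMES, evaluate_outputs, lhs_sample, mlra_indices
from nanopbpk.params import KINETIC_PARAM_NAMES


@pytest.fixture(scope="module")
def meso_config(meso_kin):
    return GsaConfig(baseline=meso_kin, n_samples=80, n_replicates=2, seed=42)


class TestLHS:
    def test_stratification_one_sample_per_bin(self, meso_config, meso_kin):
        """Each unclipped column places exactly one sample per equal stratum."""
        samples = lhs_sample(meso_config, replicate=0)
        n = meso_config.n_samples
        base = meso_kin.to_array()
        for j, b in enumerate(base):
            if KINETIC_PARAM_NAMES[j].startswith("f_") and b * 1.5 > 1.0:
                continue  # clipped column, strata collapse at the bound
            edges = np.linspace(b * 0.5, b * 1.5, n + 1)
            counts, _ = np.histogram(samples[:, j], bins=edges)
            assert np.all(counts == 1)

    def test_zero_perturbation_returns_baseline_rows(self, meso_kin):
        config = GsaConfig(baseline=meso_kin, n_samples=80, perturbation=0.0, seed=0)
        samples = lhs_sample(config, 0)
        np.testing.assert_allclose(samples, np.tile(meso_kin.to_array(), (80, 1)))

    def test_fraction_clipping(self):
        """MA's f_k = 0.926: the +50% range is clipped at the physical bound 1."""
        config = GsaConfig(baseline=load_kinetics("MA"), n_samples=100, seed=3)
        samples = lhs_sample(config, 0)
        col = samples[:, KINETIC_PARAM_NAMES.index("f_k")]
        assert col.min() >= 0.926 * 0.5 - 1e-12
        assert col.max() <= 1.0
        assert np.any(col == 1.0)  # upper strata collapse onto the bound

    def test_zero_baseline_degenerate_range(self, meso_kin):
        config = GsaConfig(baseline=meso_kin.replace(k_e_mps=0.0), n_samples=80, seed=0)
        with pytest.raises(ValueError, match="collapses"):
            lhs_sample(config, 0)

    def test_reproducible_per_seed_and_replicate(self, meso_config):
        a = lhs_sample(meso_config, 1)
        b = lhs_sample(meso_config, 1)
        c = lhs_sample(meso_config, 2)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_too_few_samples_rejected(self, meso_kin):
        with pytest.raises(ValueError, match="at least 10 per parameter"):
            GsaConfig(baseline=meso_kin, n_samples=20)


class TestMLRA:
    def _unit_lhs(self, n, d, seed=0):
        from scipy.stats import qmc

        return qmc.LatinHypercube(d=d, seed=seed).random(n)

    def test_exact_single_regressor(self):
        x = self._unit_lhs(100, 8)
        y = 3.0 * x[:, [0]]
        si = mlra_indices(x, y)
        assert si[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert np.max(np.abs(si[1:, 0])) < 1e-10

    def test_symmetric_equal_variance_contributions(self):
        x = self._unit_lhs(100, 8)
        x[:, 1] = np.random.default_rng(0).permutation(x[:, 0])  # identical marginals
        y = (x[:, 0] + x[:, 1])[:, None]
        si = mlra_indices(x, y)
        assert si[0, 0] == pytest.approx(si[1, 0], abs=1e-10)

    def test_dominant_regressor_wins_in_every_replicate(self):
        rng = np.random.default_rng(2024)
        for rep in range(10):
            x = self._unit_lhs(100, 8, seed=rep)
            y = (2.0 * x[:, 0] - x[:, 1] + rng.normal(0, 0.01, 100))[:, None]
            si = mlra_indices(x, y)
            assert abs(si[0, 0]) > abs(si[1, 0])

    def test_affine_rescaling_invariance(self):
        """SIs do not change when a parameter's units are rescaled."""
        x = self._unit_lhs(100, 8)
        y = (x @ np.arange(1.0, 9.0))[:, None]
        x2 = x.copy()
        x2[:, 3] = 1000.0 * x2[:, 3] + 5.0
        np.testing.assert_allclose(mlra_indices(x, y), mlra_indices(x2, y), atol=1e-10)

    def test_collinear_matrix_signalled(self):
        x = self._unit_lhs(100, 8)
        x[:, 1] = 2.0 * x[:, 0]
        with pytest.raises(ValueError, match="collinear"):
            mlra_indices(x, np.ones((100, 1)))


class TestEvaluateOutputs:
    def test_zero_dose_gives_zero_outputs(self, meso_kin, mouse_phys):
        out = evaluate_outputs(meso_kin.to_array()[None, :], mouse_phys, dose_amount=0.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_linear_in_dose(self, meso_kin, mouse_phys):
        row = meso_kin.to_array()[None, :]
        one = evaluate_outputs(row, mouse_phys, dose_amount=100.0)
        two = evaluate_outputs(row, mouse_phys, dose_amount=200.0)
        np.testing.assert_allclose(two, 2.0 * one, rtol=1e-9)

    def test_kidney_auc_converged_under_grid_refinement(self, meso_kin, mouse_phys):
        row = meso_kin.to_array()[None, :]
        coarse = evaluate_outputs(row, mouse_phys, grid_points=400)
        fine = evaluate_outputs(row, mouse_phys, grid_points=4000)
        k = OUTPUT_NAMES.index("kidneys_auc")
        assert abs(coarse[0, k] - fine[0, k]) / fine[0, k] < 1e-3

    def test_invalid_row_flagged_not_fatal(self, meso_kin, mouse_phys):
        rows = np.vstack([meso_kin.to_array(), meso_kin.to_array()])
        rows[1, 0] = 2.0  # f_lu > 1 violates the parameter domain
        out = evaluate_outputs(rows, mouse_phys)
        assert np.all(np.isfinite(out[0]))
        assert np.all(np.isnan(out[1]))


class TestRanking:
    def _result(self, si, meso_kin):
        return SensitivityResult(si=si, config=GsaConfig(baseline=meso_kin, n_samples=80))

    def test_identical_sis_tie_to_mean_rank(self, meso_kin):
        si = np.full((3, 8, 7), 0.5)
        mean_rank, tests, _ = rank_parameters(self._result(si, meso_kin))
        np.testing.assert_allclose(mean_rank.to_numpy(), 4.5)  # mean of ranks 1..8
        assert (tests["anova_p"] >= 0.99).all()

    def test_single_dominant_parameter_separated(self, meso_kin):
        si = np.zeros((5, 8, 7))
        si[:, 2, :] = 1.0  # one parameter carries all the sensitivity
        si += np.random.default_rng(0).normal(0, 1e-3, si.shape)
        result = self._result(si, meso_kin)
        mean_rank, tests, tukey = rank_parameters(result)
        assert (mean_rank.iloc[2] == 1.0).all()
        assert (tests["anova_p"] < 1e-6).all()
        frame = tukey[OUTPUT_NAMES[0]].summary()
        # Tukey rejects equality for every pair involving the dominant parameter
        dominant = KINETIC_PARAM_NAMES[2]
        rows = [r for r in frame.data[1:] if dominant in (str(r[0]), str(r[1]))]
        assert rows and all(bool(r[-1]) for r in rows)

    def test_single_replicate_rejected(self, meso_kin):
        with pytest.raises(ValueError, match="2 replicates"):
            rank_parameters(self._result(np.ones((1, 8, 7)), meso_kin))


class TestEndToEnd:
    def test_run_gsa_shapes_and_reproducibility(self, mouse_phys, meso_config):
        res = run_gsa(mouse_phys, meso_config)
        assert res.si.shape == (2, 8, 7)
        assert res.n_excluded == 0
        res2 = run_gsa(mouse_phys, meso_config)
        np.testing.assert_array_equal(res.si, res2.si)
        long = res.si_frame()
        assert len(long) == 2 * 8 * 7

    def test_renal_parameters_dominate_urine_output(self, mouse_phys, meso_kin):
        """f_k and k_e_k control the urine pathway in every replicate."""
        config = GsaConfig(baseline=meso_kin, n_samples=80, n_replicates=4, seed=7)
        res = run_gsa(mouse_phys, config)
        ranks = res.ranks()
        u = OUTPUT_NAMES.index("urine_final")
        f_k = KINETIC_PARAM_NAMES.index("f_k")
        k_e_k = KINETIC_PARAM_NAMES.index("k_e_k")
        f_lu = KINETIC_PARAM_NAMES.index("f_lu")
        assert np.all(ranks[:, f_k, u] <= 2)
        assert np.all(ranks[:, k_e_k, u] <= 2)
        # f_k outranks the lung unbound fraction for the kidney AUC on average
        kid = OUTPUT_NAMES.index("kidneys_auc")
        assert ranks[:, f_k, kid].mean() < ranks[:, f_lu, kid].mean()
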
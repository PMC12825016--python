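"""Model core: right-hand side arithmetic, simulation, mass balance, units."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from nanopbpk import DoseSpec, convert_units, rhs, simulate
from nanopbpk.model import MICROGRAM, PERCENT_ID

from _helpers import random_kinetics


def reference_amount_matrix(phys, kin):
    """The 7x7 rate matrix written out term by term from the balance equations.

    Independent of the package's own matrix assembly: each entry is typed
    directly from the transport/excretion fluxes in amount coordinates.
    """
    a = np.zeros((7, 7))
    organs = [
        ("lungs", phys.q_lu, kin.f_lu, phys.v_lu, 1),
        ("mps", kin.q_mps, kin.f_mps, phys.v_mps, 2),
        ("kidneys", phys.q_k, kin.f_k, phys.v_k, 3),
        ("others", kin.q_o, kin.f_o, phys.v_o, 4),
    ]
    for _, q, f, v, i in organs:
        a[0, 0] -= q / phys.v_p          # plasma outflow to organ i
        a[i, 0] += q / phys.v_p
        a[0, i] += q * f / v             # unbound return flux
        a[i, i] -= q * f / v
    a[2, 2] -= (1 - kin.f_mps) * kin.k_e_mps
    a[6, 2] += (1 - kin.f_mps) * kin.k_e_mps   # MPS -> feces
    a[3, 3] -= (1 - kin.f_k) * kin.k_e_k
    a[5, 3] += (1 - kin.f_k) * kin.k_e_k       # kidneys -> urine
    return a


class TestRHS:
    def test_zero_state_gives_zero_derivative(self, mouse_phys, meso_kin):
        assert np.all(rhs(np.zeros(7), mouse_phys, meso_kin) == 0.0)

    def test_lung_influx_from_plasma_only(self, mouse_phys, meso_kin):
        """Only plasma loaded: dC_lu/dt = Q_lu * C_p / V_lu."""
        state = np.zeros(7)
        state[0] = 58.8
        deriv = rhs(state, mouse_phys, meso_kin)
        assert deriv[1] == pytest.approx(667 * 58.8 / 0.514, rel=1e-12)

    def test_mass_balance_closes_for_random_states(self, mouse_phys, rng):
        volumes = np.array([1.7, 0.514, 1.56, 0.496, 13.2, 1.0, 1.0])
        for kin in random_kinetics(rng, 25):
            state = rng.uniform(0, 50, size=7)
            deriv = rhs(state, mouse_phys, kin)
            assert abs(np.dot(volumes, deriv)) < 1e-8 * np.abs(deriv).max()

    def test_non_finite_state_rejected(self, mouse_phys, meso_kin):
        bad = np.zeros(7)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            rhs(bad, mouse_phys, meso_kin)


class TestSimulate:
    def test_initial_condition_is_dose_over_plasma_volume(self, mouse_phys, meso_kin, mouse_dose):
        res = simulate(mouse_phys, meso_kin, mouse_dose, [0.0, 1.0])
        assert res.concentrations["plasma"].iloc[0] == pytest.approx(100 / 1.7, rel=1e-12)
        assert (res.concentrations.iloc[0, 1:] == 0).all()
        assert (res.excreta.iloc[0] == 0).all()

    def test_negligible_flows_freeze_plasma(self, mouse_phys, meso_kin, mouse_dose):
        """With vanishing organ flows and no excretion the dose stays in plasma."""
        phys = mouse_phys.__class__(
            species="mouse", v_p=1.7, v_lu=0.514, v_mps=1.56, v_k=0.496, v_o=13.2,
            q_lu=1e-12, q_k=1e-12, q_mps=1e-12, q_o=1e-12, bw=0.02,
        )
        kin = meso_kin.replace(q_mps=0.0, q_o=0.0, k_e_mps=0.0, k_e_k=0.0)
        res = simulate(phys, kin, mouse_dose, [0.0, 10.0, 100.0], method="expm")
        assert res.concentrations["plasma"].to_numpy() == pytest.approx(
            np.full(3, 100 / 1.7), rel=1e-9
        )

    def test_matches_matrix_exponential_oracle(self, mouse_phys, mouse_dose, rng):
        """Stiff solver output equals the closed-form solution of the linear system."""
        grid = np.concatenate(([0.0], np.geomspace(1e-3, 72.0, 19)))
        for kin in random_kinetics(rng, 5):
            res = simulate(mouse_phys, kin, mouse_dose, grid)
            a = reference_amount_matrix(mouse_phys, kin)
            x = np.zeros(7)
            x[0] = 100.0
            volumes = np.array([1.7, 0.514, 1.56, 0.496, 13.2, 1.0, 1.0])
            got = np.c_[res.concentrations.to_numpy(), res.excreta.to_numpy()]
            for i, t in enumerate(grid):
                ref = expm(a * t) @ x / volumes
                assert np.all(np.abs(got[i] - ref) <= 1e-6 * np.abs(ref) + 1e-9 * 100)

    def test_mass_conservation_and_nonnegativity(self, mouse_phys, mouse_dose, rng):
        grid = np.concatenate(([0.0], np.geomspace(1e-3, 200.0, 25)))
        for kin in random_kinetics(rng, 20):
            res = simulate(mouse_phys, kin, mouse_dose, grid)
            assert np.max(np.abs(res.total_mass() - 100.0)) / 100.0 < 1e-6
            floor = -1e-9 * 100.0 / min(mouse_phys.volumes.values())
            assert res.concentrations.to_numpy().min() >= floor
            assert res.excreta.to_numpy().min() >= floor

    def test_linearity_in_dose(self, mouse_phys, meso_kin):
        grid = [0.0, 1.0, 24.0, 72.0]
        low = simulate(mouse_phys, meso_kin, DoseSpec(200.0), grid, units=MICROGRAM)
        high = simulate(mouse_phys, meso_kin, DoseSpec(400.0), grid, units=MICROGRAM)
        np.testing.assert_allclose(
            high.concentrations.to_numpy(), 2 * low.concentrations.to_numpy(), rtol=1e-7
        )
        np.testing.assert_allclose(
            high.excreta.to_numpy(), 2 * low.excreta.to_numpy(), rtol=1e-7, atol=1e-12
        )

    @pytest.mark.parametrize("label", ["8A", "AR8", "MA", "Meso", "SA", "Stober"])
    def test_everything_is_eventually_excreted(self, mouse_phys, mouse_dose, label):
        """Packaged sets (positive excretion rates, all f > 0) clear > 99% by 5000 h."""
        from nanopbpk import load_kinetics

        kin = load_kinetics(label)
        res = simulate(mouse_phys, kin, mouse_dose, [0.0, 5000.0], method="expm")
        assert res.excreta.iloc[-1].sum() > 99.0

    def test_invalid_grid_rejected(self, mouse_phys, meso_kin, mouse_dose):
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate(mouse_phys, meso_kin, mouse_dose, [0.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="start at 0"):
            simulate(mouse_phys, meso_kin, mouse_dose, [1.0, 2.0])

    def test_tidy_frame_schema(self, mouse_phys, meso_kin, mouse_dose):
        frame = simulate(mouse_phys, meso_kin, mouse_dose, [0.0, 1.0]).to_frame()
        assert set(frame.columns) == {"compartment", "time_h", "value", "unit"}
        assert frame["compartment"].nunique() == 7


class TestConvertUnits:
    def test_concentration_conversion(self, mouse_phys, meso_kin):
        res = simulate(mouse_phys, meso_kin, DoseSpec(400.0), [0.0, 24.0], units=MICROGRAM)
        rel = convert_units(res, "to_percent_id")
        # 2 µg/mL at 400 µg dose is 0.5 %ID/g
        np.testing.assert_allclose(
            rel.concentrations.to_numpy(),
            100.0 * res.concentrations.to_numpy() / 400.0,
        )
        assert rel.units == PERCENT_ID

    def test_round_trip_identity(self, mouse_phys, meso_kin):
        res = simulate(mouse_phys, meso_kin, DoseSpec(123.0), [0.0, 24.0], units=MICROGRAM)
        back = convert_units(convert_units(res, "to_percent_id"), "to_microgram")
        np.testing.assert_allclose(back.concentrations.to_numpy(), res.concentrations.to_numpy())

    def test_full_excretion_reads_100_percent(self, mouse_phys, meso_kin, mouse_dose):
        res = simulate(mouse_phys, meso_kin, mouse_dose, [0.0, 5000.0], method="expm")
        assert res.excreta.iloc[-1].sum() == pytest.approx(100.0, rel=1e-4)

    def test_unknown_direction(self, mouse_phys, meso_kin, mouse_dose):
        res = simulate(mouse_phys, meso_kin, mouse_dose, [0.0, 1.0])
        with pytest.raises(ValueError, match="direction"):
            convert_units(res, "sideways")


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    f=st.floats(0.0, 1.0),
    k=st.floats(0.0, 50.0),
    scale=st.floats(0.1, 10.0),
)
def test_rhs_scales_linearly_with_state(f, k, scale):
    """Superposition: the derivative is homogeneous of degree 1 in the state."""
    from nanopbpk import load_kinetics, load_physiology

    phys = load_physiology("mouse")
    kin = load_kinetics("Meso").replace(f_k=f, k_e_k=k)
    state = np.array([10.0, 1.0, 2.0, 3.0, 0.5, 0.1, 0.2])
    np.testing.assert_allclose(
        rhs(state * scale, phys, kin), np.asarray(rhs(state, phys, kin)) * scale,
        rtol=1e-9, atol=1e-12,
    )
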
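"""Sequential binding model: frozen examples, invariants, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msbind import (
    BindingModel,
    free_ligand_concentration,
    joint_mole_fractions_independent,
    mean_occupancy,
    mole_fractions,
    mole_fractions_grid,
)
from msbind.exceptions import InvalidInputError

from conftest import oracle_equilibrium, quadratic_single_site

kd_strategy = st.floats(min_value=1e-2, max_value=1e4)
conc_strategy = st.floats(min_value=0.0, max_value=1e4)


class TestBindingModel:
    def test_kd_ka_round_trip_exact(self):
        kd = np.array([47.8, 124.4])
        model = BindingModel.from_kd(kd)
        assert np.array_equal(1.0 / model.k_a, kd)
        assert np.array_equal(model.k_d, kd)

    def test_zero_step_constant_allowed_with_infinite_kd(self):
        model = BindingModel(k_a=[0.0, 0.0])
        assert np.all(np.isinf(model.k_d))

    @pytest.mark.parametrize("bad", [[], [-1.0], [np.nan], [np.inf]])
    def test_invalid_constants_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            BindingModel(k_a=bad)

    def test_config_round_trip(self, tmp_path, atp_model):
        path = tmp_path / "model.json"
        atp_model.to_json(path)
        back = BindingModel.from_json(path)
        assert np.allclose(back.k_d, atp_model.k_d, rtol=0, atol=0)


class TestFreeLigand:
    def test_no_binding_leaves_ligand_free(self):
        model = BindingModel(k_a=[0.0, 0.0])
        assert free_ligand_concentration(model, 0.5, 37.0) == pytest.approx(37.0)

    def test_zero_total_ligand(self, atp_model):
        assert free_ligand_concentration(atp_model, 0.5, 0.0) == 0.0

    def test_single_site_matches_quadratic(self):
        # K_D=50, P=0.5, L=20: root of x^2 + (K_D+P-L)x - K_D*L
        model = BindingModel.from_kd([50.0])
        x = free_ligand_concentration(model, 0.5, 20.0)
        assert x == pytest.approx(19.857869488193096, abs=1e-10)
        assert x == pytest.approx(quadratic_single_site(50.0, 0.5, 20.0), abs=1e-10)

    def test_nonfinite_inputs_rejected(self, atp_model):
        with pytest.raises(InvalidInputError):
            free_ligand_concentration(atp_model, np.nan, 10.0)
        with pytest.raises(InvalidInputError):
            free_ligand_concentration(atp_model, 0.5, -1.0)


class TestMoleFractions:
    def test_no_binding_is_all_apo(self):
        state = mole_fractions(BindingModel(k_a=[0.0, 0.0]), 0.5, 100.0)
        assert np.allclose(state.fractions, [1.0, 0.0, 0.0], atol=1e-15)

    def test_single_site_frozen_example(self):
        state = mole_fractions(BindingModel.from_kd([50.0]), 0.5, 20.0)
        assert state.fractions == pytest.approx([0.7157389763861989,
                                                 0.2842610236138011], abs=1e-10)

    def test_two_site_frozen_example(self, atp_model):
        # fixed point of the depletion-corrected model, verified to 1e-12
        state = mole_fractions(atp_model, 0.5, 20.0)
        assert state.fractions == pytest.approx(
            [0.67541066, 0.27999030, 0.04459905], abs=1e-7)
        assert state.l_free == pytest.approx(19.815405804748, abs=1e-9)

    def test_mean_occupancy_examples(self, atp_model):
        state = mole_fractions(atp_model, 0.5, 20.0)
        assert mean_occupancy(state) == pytest.approx(0.36918839, abs=1e-7)
        apo = mole_fractions(BindingModel(k_a=[0.0, 0.0]), 0.5, 20.0)
        assert mean_occupancy(apo) == pytest.approx(0.0, abs=1e-14)
        sat = mole_fractions(atp_model, 0.01, 1e7)
        assert mean_occupancy(sat) == pytest.approx(2.0, abs=1e-3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(kd=st.lists(kd_strategy, min_size=1, max_size=4),
           p=st.floats(min_value=1e-3, max_value=10.0),
           l=conc_strategy)
    def test_normalization_and_mass_balance(self, kd, p, l):
        model = BindingModel.from_kd(kd)
        state = mole_fractions(model, p, l)
        assert abs(state.fractions.sum() - 1.0) < 1e-10
        bound = p * mean_occupancy(state)
        assert state.l_free + bound == pytest.approx(l, rel=1e-9, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(kd=st.lists(kd_strategy, min_size=1, max_size=4),
           p=st.floats(min_value=1e-3, max_value=10.0),
           l=st.floats(min_value=0.0, max_value=1e4))
    def test_agrees_with_brute_force_oracle(self, kd, p, l):
        model = BindingModel.from_kd(kd)
        state = mole_fractions(model, p, l)
        x_ref, f_ref = oracle_equilibrium(kd, p, l)
        assert state.l_free == pytest.approx(x_ref, abs=1e-8)
        assert np.allclose(state.fractions, f_ref, atol=1e-8)

    def test_occupancy_monotone_in_ligand_and_affinity(self, atp_model):
        l_grid = np.linspace(0.0, 400.0, 40)
        occ = [mean_occupancy(mole_fractions(atp_model, 0.5, l)) for l in l_grid]
        assert np.all(np.diff(occ) >= -1e-12)
        # strengthening any single step constant raises occupancy
        for j in range(atp_model.n_max):
            k_a = atp_model.k_a.copy()
            k_a[j] *= 3.0
            stronger = BindingModel(k_a=k_a)
            assert (mean_occupancy(mole_fractions(stronger, 0.5, 50.0))
                    >= mean_occupancy(mole_fractions(atp_model, 0.5, 50.0)))

    def test_saturation_limit(self, atp_model):
        state = mole_fractions(atp_model, 0.5, 1e8)
        assert state.fractions[-1] == pytest.approx(1.0, abs=1e-3)

    def test_dilute_limit_matches_no_depletion_formula(self, atp_model):
        l = 30.0
        state = mole_fractions(atp_model, 1e-12, l)
        beta = np.concatenate(([1.0], np.cumprod(atp_model.k_a)))
        w = beta * l ** np.arange(3)
        assert np.allclose(state.fractions, w / w.sum(), atol=1e-10)
        assert state.l_free == pytest.approx(l, rel=1e-9)

    def test_grid_solver_matches_scalar_path(self, atp_model):
        l_grid = np.array([0.0, 1.0, 20.0, 500.0])
        grid = mole_fractions_grid(atp_model, 0.5, l_grid)
        for row, l in zip(grid, l_grid):
            assert np.allclose(row, mole_fractions(atp_model, 0.5, l).fractions,
                               atol=1e-12)


class TestJointIndependent:
    def test_outer_product_example(self):
        # F_nuc=(0.5,0.5), F_lip=(0.8,0.2) realized in the dilute limit
        nuc = BindingModel.from_kd([10.0])
        lip = BindingModel.from_kd([40.0])
        table = joint_mole_fractions_independent(nuc, lip, 1e-12, 10.0, 10.0)
        assert np.allclose(table.fractions,
                           [[0.4, 0.1], [0.4, 0.1]], atol=1e-9)

    def test_dead_lipid_collapses_to_nucleotide_marginal(self, atp_model):
        lip = BindingModel(k_a=[0.0])
        table = joint_mole_fractions_independent(atp_model, lip, 0.5, 20.0, 5.0)
        assert np.allclose(table.fractions[:, 1], 0.0, atol=1e-15)
        assert np.allclose(table.fractions[:, 0],
                           mole_fractions(atp_model, 0.5, 20.0).fractions,
                           atol=1e-12)

    def test_marginals_match_separate_solutions(self, atp_model, lipid_model):
        table = joint_mole_fractions_independent(
            atp_model, lipid_model, 0.5, 50.0, 1.0)
        assert np.allclose(table.marginal("nucleotide"),
                           mole_fractions(atp_model, 0.5, 50.0).fractions,
                           atol=1e-12)
        assert np.allclose(table.marginal("lipid"),
                           mole_fractions(lipid_model, 0.5, 1.0).fractions,
                           atol=1e-12)
        assert table.fractions.sum() == pytest.approx(1.0, abs=1e-12)
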
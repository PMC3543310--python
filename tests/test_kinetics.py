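import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcsteroid.kinetics import (CellState, FoldChanges, IDENTITY_FOLDS,
                                gene_expression_rhs, km_fold_change,
                                mrna_equilibrium, mrna_fold_change,
                                reaction_fluxes, steroid_net_rates, t2o_rate)
from gcsteroid.model_core import Enzyme


def _state(params, steroids=(0, 0, 0, 0), fsh=0.0):
    s = CellState.baseline(params)
    s.steroids = np.asarray(steroids, dtype=float)
    s.fsh = fsh
    return s


class TestKmFoldChange:
    @pytest.mark.parametrize("activity,expected", [
        (1.0, 1.0),
        (0.89, 1.1236),    # direct competitive inhibition raises apparent Km
        (0.29, 3.4483),
    ])
    def test_reciprocal(self, activity, expected):
        assert km_fold_change(activity) == pytest.approx(expected, rel=1e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            km_fold_change(0.0)


class TestMrnaFoldChange:
    @pytest.mark.parametrize("treated,control,expected", [
        (9.92e-8, 4.96e-8, 2.0),
        (4.96e-8, 4.96e-8, 1.0),
        (1.553e-7, 4.96e-8, 3.13),   # strongest observed aromatase induction
    ])
    def test_ratio(self, treated, control, expected):
        assert mrna_fold_change(treated, control) == pytest.approx(
            expected, rel=2e-3)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            mrna_fold_change(1.0, 0.0)


class TestReactionFluxes:
    def test_no_substrate_no_flux(self, map_params):
        fl = reaction_fluxes(_state(map_params), map_params)
        assert np.all(fl.alpha == 0.0)

    def test_saturation_limit(self, map_params):
        # overwhelming A with no competing T: alpha1 -> Vmax = lam * enzyme
        st_ = _state(map_params, steroids=(1.0, 0.0, 0.0, 0.0))
        fl = reaction_fluxes(st_, map_params)
        from gcsteroid.model_core import Hormone
        vmax = map_params.lam[(Enzyme.CYP19, Hormone.A)] * st_.prot[0]
        assert fl.alpha[0] == pytest.approx(vmax, rel=1e-6)

    def test_hand_evaluated_aromatization(self, map_params):
        # lam=1.07e-7, Cyp19=0.1 pg, A=1e-8 pmol, xi=8.25e-9, no competitor:
        # alpha1 = 1.07e-8 * 1e-8/(8.25e-9 + 1e-8) = 5.863e-9
        st_ = _state(map_params, steroids=(1e-8, 0.0, 0.0, 0.0))
        fl = reaction_fluxes(st_, map_params)
        assert fl.alpha[0] == pytest.approx(5.863e-9, rel=1e-3)

    def test_zero_enzyme_gives_zero_flux(self, map_params):
        st_ = _state(map_params, steroids=(1e-6, 1e-6, 1e-6, 1e-6))
        st_.prot = np.zeros(3)
        fl = reaction_fluxes(st_, map_params)
        assert np.all(fl.alpha == 0.0)

    def test_km_inflation_divides_flux_at_low_substrate(self, map_params):
        # with both aromatase Km inflated by f_M, the linear-regime rate
        # scales as 1/f_M
        st_ = _state(map_params, steroids=(1e-13, 1e-13, 0.0, 0.0))
        f_m = 3.4483
        a_ref = reaction_fluxes(st_, map_params).alpha[0]
        a_inf = reaction_fluxes(st_, map_params,
                                FoldChanges(f_m=f_m)).alpha[0]
        assert a_ref / a_inf == pytest.approx(f_m, rel=1e-3)

    def test_relative_reference_is_unity(self, map_params):
        st_ = _state(map_params, steroids=(1e-7, 1e-8, 1e-8, 1e-8))
        rel = reaction_fluxes(st_, map_params).relative()
        assert rel[0] == 1.0

    def test_relative_undefined_without_reference(self, map_params):
        rel = reaction_fluxes(_state(map_params), map_params).relative()
        assert np.all(np.isnan(rel))


class TestStoichiometry:
    def test_closure_exact(self, map_params):
        st_ = _state(map_params, steroids=(3e-7, 2e-8, 1e-8, 5e-8))
        net = steroid_net_rates(reaction_fluxes(st_, map_params))
        assert net.sum() == pytest.approx(0.0, abs=1e-25)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(q=st.lists(st.floats(1e-12, 1e-4), min_size=4, max_size=4))
    def test_closure_property(self, map_params, q):
        """The six fluxes only interconvert the four steroids."""
        net = steroid_net_rates(
            reaction_fluxes(_state(map_params, steroids=q), map_params))
        assert abs(net.sum()) <= 1e-12 * np.abs(net).max() + 1e-30

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=st.floats(1e-12, 1e-5), t=st.floats(1e-12, 1e-5),
           bump=st.floats(1.01, 10.0))
    def test_competitive_monotonicity(self, map_params, a, t, bump):
        """alpha1 rises with its own substrate and falls with the
        competing one."""
        base = reaction_fluxes(
            _state(map_params, steroids=(a, t, 0, 0)), map_params).alpha[0]
        more_sub = reaction_fluxes(
            _state(map_params, steroids=(a * bump, t, 0, 0)),
            map_params).alpha[0]
        more_comp = reaction_fluxes(
            _state(map_params, steroids=(a, t * bump, 0, 0)),
            map_params).alpha[0]
        assert more_sub >= base * (1 - 1e-12)
        assert more_comp <= base * (1 + 1e-12)


class TestGeneExpression:
    def test_baseline_is_equilibrium(self, table2_params):
        dm, dp = gene_expression_rhs(_state(table2_params), table2_params)
        m0 = np.array([table2_params.mrna0[e] for e in Enzyme])
        assert np.all(np.abs(dm) <= 1e-12 * table2_params.delta_mrna * m0)
        assert np.all(np.abs(dp) <= 1e-12)

    def test_fold_change_doubles_equilibrium(self, table2_params):
        eq = mrna_equilibrium(table2_params, Enzyme.CYP19,
                              FoldChanges(f_cyp19=2.0))
        assert eq == pytest.approx(2 * table2_params.mrna0[Enzyme.CYP19],
                                   rel=1e-12)
        assert eq == pytest.approx(9.92e-8, rel=1e-3)

    def test_study_effect_scales_all_equilibria(self, table2_params):
        for enz in Enzyme:
            e1 = mrna_equilibrium(table2_params, enz, sigma_l=1.0)
            e2 = mrna_equilibrium(table2_params, enz, sigma_l=2.0)
            assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_hsd17b2_ignores_fsh_and_disruptors(self, table2_params):
        p = table2_params.with_kinetics(kappa_cyp19=1e6, kappa_hsd17b1=1e5)
        s = _state(p, fsh=1e-5)
        dm, _ = gene_expression_rhs(s, p, FoldChanges(f_cyp19=5.0,
                                                      f_hsd17b1=5.0))
        assert dm[0] > 0 and dm[1] > 0   # induced
        assert dm[2] == pytest.approx(0.0, abs=1e-25)

    def test_rejects_nonpositive_sigma_l(self, table2_params):
        with pytest.raises(ValueError):
            gene_expression_rhs(_state(table2_params), table2_params,
                                sigma_l=0.0)


class TestT2O:
    def test_rate_is_reference_flux(self, map_params):
        st_ = _state(map_params, steroids=(1e-8, 0, 0, 0))
        fl = reaction_fluxes(st_, map_params)
        assert t2o_rate(fl) == fl.alpha[0] > 0

    def test_t_aromatization_releases_no_label(self, map_params):
        # only T present: alpha4 > 0 but no labelled water from A
        st_ = _state(map_params, steroids=(0.0, 1e-7, 0.0, 0.0))
        fl = reaction_fluxes(st_, map_params)
        assert fl.alpha[3] > 0
        assert t2o_rate(fl) == 0.0
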
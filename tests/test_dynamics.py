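"""Auxin-PIN dynamics: kinetic primitives, integration, conservation laws."""

import numpy as np
import pytest

import leafmargin as lm
from leafmargin.dynamics import _Workspace, _edge_targets

FAST = dict(sigma_src=1.0, sigma_bg=0.01, mu_a=0.1, D=0.3, T=0.3, kappa=4.0,
            rho=1.5, dt=0.05, t_max=500.0)

class TestPhosphoFraction:
    def test_zero_cuc_gives_zero(self):
        assert lm.phospho_fraction(0.0, K_c=0.3, h_c=2) == 0.0

    @pytest.mark.parametrize("h", [1.0, 2.0, 5.0])
    def test_half_saturation(self, h):
        assert lm.phospho_fraction(0.3, K_c=0.3, h_c=h) == pytest.approx(0.5)

    def test_two_kc_hill_two(self):
        # 4 / (1 + 4)
        assert lm.phospho_fraction(0.6, K_c=0.3, h_c=2) == pytest.approx(0.8)

    def test_monotone_in_cuc(self):
        cuc = np.linspace(0, 3, 50)
        phi = lm.phospho_fraction(cuc, K_c=0.5, h_c=3)
        assert np.all(np.diff(phi) >= 0)
        assert np.all((phi >= 0) & (phi <= 1))

    def test_nonpositive_kc_rejected(self):
        with pytest.raises(ValueError):
            lm.phospho_fraction(1.0, K_c=0.0, h_c=2)

class TestAllocationWeights:
    def test_utg_equal_auxin_gives_equal_weights(self):
        w = lm.utg_weights([2.0, 2.0, 2.0], kappa=3.0)
        np.testing.assert_allclose(w, 1 / 3)

    def test_utg_log3_example(self):
        w = lm.utg_weights([0.0, np.log(3)], kappa=1.0)
        np.testing.assert_allclose(w, [0.25, 0.75])

    def test_utg_kappa_zero_is_uniform(self):
        w = lm.utg_weights([0.1, 5.0, 2.0], kappa=0.0)
        np.testing.assert_allclose(w, 1 / 3)

    def test_utg_relative_is_scale_invariant(self):
        a = np.array([0.5, 1.0, 2.0])
        w1 = lm.utg_weights(a, kappa=5.0, relative=True)
        w2 = lm.utg_weights(1e-6 * a, kappa=5.0, relative=True)
        np.testing.assert_allclose(w1, w2)

    def test_utg_empty_rejected(self):
        with pytest.raises(ValueError):
            lm.utg_weights([], kappa=1.0)

    def test_wtf_all_negative_fluxes_uniform(self):
        w = lm.wtf_weights([-1.0, -0.2, -3.0], beta=0.01)
        np.testing.assert_allclose(w, 1 / 3)

    def test_wtf_rectified_power_example(self):
        # (1^2 + 1) : (0 + 1) = 2 : 1
        w = lm.wtf_weights([1.0, 0.0], wtf_exponent=2.0, beta=1.0)
        np.testing.assert_allclose(w, [2 / 3, 1 / 3])

    def test_wtf_symmetric_fluxes(self):
        np.testing.assert_allclose(lm.wtf_weights([0.7, 0.7], beta=0.1), 0.5)

    def test_wtf_beta_zero_rejected(self):
        with pytest.raises(ValueError):
            lm.wtf_weights([1.0, 2.0], beta=0.0)

    def test_weights_sum_to_one(self, rng):
        for _ in range(20):
            a = rng.uniform(0, 5, rng.integers(1, 6))
            assert lm.utg_weights(a, kappa=2.0).sum() == pytest.approx(1.0)
            j = rng.normal(0, 1, rng.integers(1, 6))
            assert lm.wtf_weights(j, beta=0.05).sum() == pytest.approx(1.0)

class TestEdgeFlux:
    def test_symmetric_configuration_gives_zero(self):
        assert lm.edge_flux(1.0, 1.0, 0.5, 0.5, T=2.0) == 0.0

    def test_direct_evaluation(self):
        assert lm.edge_flux(2.0, 0.0, 1.0, 1.0, T=1.0) == 2.0

    def test_antisymmetry(self, rng):
        for _ in range(20):
            ai, aj, pij, pji, ei, ej = rng.uniform(0.1, 3, 6)
            jij = lm.edge_flux(ai, aj, pij, pji, 1.3, ei, ej)
            jji = lm.edge_flux(aj, ai, pji, pij, 1.3, ej, ei)
            assert jij == pytest.approx(-jji)

    def test_efficiency_multiplies_efflux_term(self):
        base = lm.edge_flux(2.0, 0.0, 1.0, 1.0, T=1.0, eff_i=1.0)
        assert lm.edge_flux(2.0, 0.0, 1.0, 1.0, T=1.0, eff_i=3.0) == 3 * base

class TestModelParams:
    def test_stability_guard_enforced(self):
        with pytest.raises(ValueError, match="stability guard"):
            lm.ModelParams(dt=1.0, T=1.0, P_tot=1.0, epsilon=3.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            lm.ModelParams(mu_a=-0.1)

    def test_epsilon_below_one_rejected(self):
        with pytest.raises(ValueError):
            lm.ModelParams(epsilon=0.5)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            lm.ModelParams(variant="wtf_only")

class TestTargetAllocation:
    def test_targets_sum_to_ptot_every_cell(self):
        tpl = lm.make_template("wt", n_rows=6, n_cols=3)
        params = lm.ModelParams(variant="pmm", **FAST)
        state = lm.initial_state(tpl, params)
        state.auxin = np.linspace(0.1, 2.0, tpl.tissue.n_cells)
        ws = _Workspace(tpl.tissue)
        targets = _edge_targets(state.auxin, state.pin, state.phospho_fraction, ws, params)
        sums = np.zeros(tpl.tissue.n_cells)
        np.add.at(sums, tpl.tissue.edge_src, targets)
        np.testing.assert_allclose(sums, params.P_tot, atol=1e-12)

    def test_pmm_with_zero_phospho_equals_utg_only(self):
        tpl = lm.make_template("cuc_mutant", n_rows=6, n_cols=3)
        results = {}
        for variant in ("pmm", "utg_only"):
            params = lm.ModelParams(variant=variant, **FAST)
            state = lm.initial_state(tpl, params)
            state.auxin = np.linspace(0.1, 2.0, tpl.tissue.n_cells)
            results[variant] = lm.target_allocation(5, state, tpl.tissue, params)
        np.testing.assert_allclose(results["pmm"], results["utg_only"])

class TestStep:
    def test_uniform_closed_system_is_fixed_point(self):
        tpl = lm.make_template("wt", n_rows=4, n_cols=3, baseline_auxin=0.7,
                               initial_pin_allocation="uniform")
        tpl.tissue.source_mask[:] = False
        params = lm.ModelParams(sigma_src=0, sigma_bg=0, mu_a=0, D=0.2, T=0.2,
                                kappa=0.0, rho=0.0, dt=0.05, variant="utg_only")
        s0 = lm.initial_state(tpl, params)
        s0.pin[:] = 0.3  # symmetric: P_ij = P_ji on every membrane
        s1 = lm.step(s0, tpl.tissue, params)
        np.testing.assert_allclose(s1.auxin, s0.auxin, atol=1e-14)
        np.testing.assert_allclose(s1.pin, s0.pin, atol=1e-14)

    def test_mass_conserved_in_closed_system(self, rng):
        tpl = lm.make_template("wt", n_rows=5, n_cols=3)
        tpl.tissue.source_mask[:] = False
        params = lm.ModelParams(sigma_src=0, sigma_bg=0, mu_a=0, D=0.4, T=0.5,
                                kappa=3.0, rho=1.5, dt=0.04, variant="pmm")
        state = lm.initial_state(tpl, params)
        state.auxin = rng.uniform(0.1, 2.0, tpl.tissue.n_cells)
        total0 = state.auxin.sum()
        for _ in range(200):
            state = lm.step(state, tpl.tissue, params)
            assert abs(state.auxin.sum() - total0) < 1e-10 * total0
            total0 = state.auxin.sum()

    def test_two_cell_antisymmetry_conserves_auxin(self):
        tpl = lm.make_template("wt", n_rows=3, n_cols=1, baseline_auxin=1.0)
        tpl.tissue.source_mask[:] = False
        params = lm.ModelParams(sigma_src=0, sigma_bg=0, mu_a=0, D=0.0, T=0.5,
                                kappa=2.0, rho=0.0, dt=0.05, variant="utg_only")
        state = lm.initial_state(tpl, params)
        state.auxin = np.array([2.0, 0.5, 1.0])
        total = state.auxin.sum()
        for _ in range(100):
            state = lm.step(state, tpl.tissue, params)
        assert state.auxin.sum() == pytest.approx(total, rel=1e-12)

class TestSteadyState:
    def test_frozen_pin_matches_direct_linear_solve(self):
        # 1x3 column, rho=0: auxin balance is linear in a; solve it directly
        tpl = lm.make_template("wt", n_rows=3, n_cols=1, baseline_auxin=0.0)
        params = lm.ModelParams(sigma_src=1.0, sigma_bg=0.05, mu_a=0.2, D=0.3,
                                T=0.4, kappa=2.0, rho=0.0, dt=0.02,
                                t_max=3000.0, tol_ss=1e-12, variant="utg_only")
        res = lm.run_to_steady_state(tpl, params)
        assert res.converged

        t = tpl.tissue
        pin = lm.initial_state(tpl, params).pin  # rho=0: PIN frozen at init
        n = t.n_cells
        A = np.zeros((n, n))
        b = np.full(n, params.sigma_bg)
        b[t.source_mask] += params.sigma_src
        A -= np.eye(n) * params.mu_a
        for e in range(t.n_edges):
            i, j = t.edge_src[e], t.edge_dst[e]
            A[i, j] += params.D
            A[i, i] -= params.D
            A[i, i] -= params.T * pin[e]         # efflux i->j
            A[i, j] += params.T * pin[t.edge_rev[e]]  # influx j->i
        expected = np.linalg.solve(A, -b)
        np.testing.assert_allclose(res.final_state.auxin, expected, rtol=1e-6)

    def test_emm_epsilon_one_equals_utg_only(self):
        tpl = lm.make_template("wt", n_rows=8, n_cols=3)
        base = dict(FAST, tol_ss=1e-9)
        res_emm = lm.run_to_steady_state(tpl, lm.ModelParams(variant="emm", epsilon=1.0, **base))
        res_utg = lm.run_to_steady_state(tpl, lm.ModelParams(variant="utg_only", **base))
        np.testing.assert_allclose(res_emm.final_state.auxin, res_utg.final_state.auxin,
                                   atol=1e-6)
        np.testing.assert_allclose(res_emm.final_state.pin, res_utg.final_state.pin,
                                   atol=1e-6)

    @pytest.mark.parametrize("variant", ["pmm", "emm"])
    def test_variants_agree_without_cuc(self, variant):
        tpl = lm.make_template("wt", n_rows=8, n_cols=3, cuc_max=0.0)
        base = dict(FAST, tol_ss=1e-9)
        res_v = lm.run_to_steady_state(tpl, lm.ModelParams(variant=variant, **base))
        res_u = lm.run_to_steady_state(tpl, lm.ModelParams(variant="utg_only", **base))
        np.testing.assert_allclose(res_v.final_state.auxin, res_u.final_state.auxin,
                                   atol=1e-6)

    def test_pin_normalization_at_steady_state(self):
        tpl = lm.make_template("wt", n_rows=8, n_cols=3)
        params = lm.ModelParams(variant="pmm", **FAST)
        res = lm.run_to_steady_state(tpl, params)
        sums = np.zeros(tpl.tissue.n_cells)
        np.add.at(sums, tpl.tissue.edge_src, res.final_state.pin)
        np.testing.assert_allclose(sums, params.P_tot, atol=1e-8)

    def test_deterministic_without_noise(self):
        tpl = lm.make_template("wt", n_rows=8, n_cols=3)
        params = lm.ModelParams(variant="pmm", **FAST)
        r1 = lm.run_to_steady_state(tpl, params)
        r2 = lm.run_to_steady_state(tpl, params)
        np.testing.assert_array_equal(r1.final_state.auxin, r2.final_state.auxin)
        np.testing.assert_array_equal(r1.final_state.pin, r2.final_state.pin)

    def test_mirror_symmetric_steady_state_in_subcritical_control(self):
        # a mirror-symmetric template yields a mirror-symmetric state as long
        # as the dynamics stay subcritical; supercritical regimes can select
        # one of two mirror-image attractors (documented limitation)
        tpl = lm.make_template("wt", n_rows=10, n_cols=5)
        params = lm.ModelParams(variant="utg_only", **FAST)
        res = lm.run_to_steady_state(tpl, params)
        grid = res.final_state.auxin.reshape(10, 5)
        np.testing.assert_allclose(grid, grid[:, ::-1], atol=1e-9)

    def test_no_clamping_under_baseline(self):
        tpl = lm.make_template("wt", n_rows=8, n_cols=3)
        res = lm.run_to_steady_state(tpl, lm.ModelParams(variant="pmm", **FAST))
        assert res.n_clamps == 0

    def test_nonconvergence_reported_not_raised(self):
        tpl = lm.make_template("wt", n_rows=8, n_cols=3)
        params = lm.ModelParams(variant="pmm", **{**FAST, "t_max": 1.0})
        res = lm.run_to_steady_state(tpl, params)
        assert res.converged is False
        assert res.residual > 0
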
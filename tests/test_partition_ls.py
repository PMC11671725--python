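"""Linear-system partitioner: scenario algebra, exact solves, and the
constrained Monte Carlo estimator."""

import numpy as np
import pytest
from scipy import optimize

from n2opart.exceptions import (
    DegenerateSystemError,
    DomainError,
    InvalidInputError,
    NoAcceptedDrawsError,
)
from n2opart.iso_core import SourceLibrary
from n2opart.partition_ls import (
    EmittedMeasurement,
    MonteCarloPartitioner,
    PartitionSolution,
    Scenario,
    build_system,
    effective_sources,
    monte_carlo_partition,
    r_consistency_check,
    solve_partition,
)
from n2opart.synthetic_data import study_flux_summary


def mean_library_draw(lib: SourceLibrary) -> dict:
    return {
        "sp": lib.sp_means,
        "o18": lib.o18_means,
        "eps_sp": lib.eps_sp_mean,
        "eps_o": lib.eps_o_mean,
    }


def tight_measurement(sp, o18, spc, r, sd=1e-12):
    return EmittedMeasurement(sp, sd, o18, sd, spc, sd, r, sd)


class TestEffectiveSources:
    def test_rm_r1_identity(self, library):
        sp, o18 = effective_sources(mean_library_draw(library), "RM", 1.0)
        np.testing.assert_allclose(sp, library.sp_means)
        np.testing.assert_allclose(o18, library.o18_means)

    def test_rm_shifts_only_bacterial(self, library):
        sp, o18 = effective_sources(mean_library_draw(library), "RM", 0.4157)
        assert sp[0] == pytest.approx(2.49, abs=5e-3)
        np.testing.assert_allclose(sp[1:], library.sp_means[1:])
        np.testing.assert_allclose(o18[1:], library.o18_means[1:])

    def test_mr_leaves_sources_untouched(self, library):
        sp, o18 = effective_sources(mean_library_draw(library), "MR", 0.3)
        np.testing.assert_allclose(sp, library.sp_means)
        np.testing.assert_allclose(o18, library.o18_means)

    def test_r_domain(self, library):
        with pytest.raises(DomainError):
            effective_sources(mean_library_draw(library), "RM", 0.0)


class TestBuildSystem:
    def test_mr_moves_shift_to_rhs(self, library):
        draw = mean_library_draw(library)
        m = {"sp": 6.52, "o18": 35.20, "spc": 0.97}
        r = 0.4157
        sys_mr = build_system(draw, m, "MR", r)
        lnr = np.log(r)
        assert sys_mr[0, 4] == pytest.approx(35.20 - (-15.0) * lnr)
        assert sys_mr[1, 4] == pytest.approx(6.52 - (-5.0) * lnr)
        np.testing.assert_allclose(sys_mr[0, :4], library.o18_means)

    def test_rm_rhs_unchanged(self, library):
        sys_rm = build_system(
            mean_library_draw(library), {"sp": 5.95, "o18": 33.48, "spc": 0.97},
            "RM", 0.4157,
        )
        assert sys_rm[0, 4] == 33.48 and sys_rm[1, 4] == 5.95

    def test_constraint_rows(self, library):
        sys_ = build_system(
            mean_library_draw(library), {"sp": 0, "o18": 0, "spc": 0.7}, "RM", 0.5
        )
        np.testing.assert_allclose(sys_[2], [1, 1, 0, 0, 0.7])
        np.testing.assert_allclose(sys_[3], [1, 1, 1, 1, 1])

    def test_zero_eps_scenarios_identical(self, exact_library):
        draw = mean_library_draw(exact_library)
        draw["eps_sp"] = draw["eps_o"] = 0.0
        m = {"sp": 10.0, "o18": 30.0, "spc": 0.8}
        np.testing.assert_allclose(
            build_system(draw, m, "RM", 0.5), build_system(draw, m, "MR", 0.5)
        )


class TestSolvePartition:
    def test_forward_then_invert(self, library):
        f_true = np.array([0.87, 0.10, 0.015, 0.015])
        draw = mean_library_draw(library)
        sp_eff, o18_eff = effective_sources(draw, "RM", 0.4157)
        m = {
            "sp": float(f_true @ sp_eff),
            "o18": float(f_true @ o18_eff),
            "spc": float(f_true[0] + f_true[1]),
        }
        assert m["sp"] == pytest.approx(5.95, abs=5e-3)
        assert m["o18"] == pytest.approx(33.48, abs=5e-3)
        sol = solve_partition(build_system(draw, m, "RM", 0.4157))
        np.testing.assert_allclose(sol.as_array(), f_true, atol=1e-9)

    def test_pure_bacterial(self, library):
        draw = mean_library_draw(library)
        sp_eff, o18_eff = effective_sources(draw, "RM", 0.5)
        m = {"sp": sp_eff[0], "o18": o18_eff[0], "spc": 1.0}
        sol = solve_partition(build_system(draw, m, "RM", 0.5))
        np.testing.assert_allclose(sol.as_array(), [1, 0, 0, 0], atol=1e-9)

    def test_identical_sources_degenerate(self, library):
        draw = mean_library_draw(library)
        draw = {**draw, "sp": draw["sp"].copy(), "o18": draw["o18"].copy()}
        draw["sp"][1] = draw["sp"][0]
        draw["o18"][1] = draw["o18"][0]
        system = build_system(draw, {"sp": 5.0, "o18": 30.0, "spc": 0.9}, "MR", 0.5)
        with pytest.raises(DegenerateSystemError):
            solve_partition(system)

    def test_affine_in_measurement(self, library):
        """Convex mixtures of feasible measurements solve to the same convex
        mixtures of their solutions (rhs-linearity of the solve)."""
        draw = mean_library_draw(library)
        sp_eff, o18_eff = effective_sources(draw, "RM", 0.4)
        rng = np.random.default_rng(11)
        for _ in range(20):
            f1 = rng.dirichlet(np.ones(4))
            f2 = rng.dirichlet(np.ones(4))
            m1 = {"sp": float(f1 @ sp_eff), "o18": float(f1 @ o18_eff),
                  "spc": float(f1[0] + f1[1])}
            m2 = {"sp": float(f2 @ sp_eff), "o18": float(f2 @ o18_eff),
                  "spc": float(f2[0] + f2[1])}
            lam = rng.uniform()
            mix = {k: lam * m1[k] + (1 - lam) * m2[k] for k in m1}
            f1 = solve_partition(build_system(draw, m1, "RM", 0.4)).as_array()
            f2 = solve_partition(build_system(draw, m2, "RM", 0.4)).as_array()
            fm = solve_partition(build_system(draw, mix, "RM", 0.4)).as_array()
            np.testing.assert_allclose(fm, lam * f1 + (1 - lam) * f2, atol=1e-8)

    def test_constrained_lsq_oracle_equivalence(self, library):
        """The direct 4x4 solve must match an equality-constrained
        least-squares solve over the simplex on random feasible systems."""
        draw = mean_library_draw(library)
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 300:
            f_true = rng.dirichlet(np.ones(4))
            if f_true.min() < 0.01:
                continue
            r = rng.uniform(0.1, 1.0)
            sp_eff, o18_eff = effective_sources(draw, "RM", r)
            m = {"sp": float(f_true @ sp_eff), "o18": float(f_true @ o18_eff),
                 "spc": float(f_true[0] + f_true[1])}
            system = build_system(draw, m, "RM", r)
            a, b = system[:, :4], system[:, 4]
            res = optimize.minimize(
                lambda x: float(np.sum((a @ x - b) ** 2)),
                x0=np.full(4, 0.25),
                bounds=[(0, 1)] * 4,
                constraints=[
                    {"type": "eq", "fun": lambda x: x.sum() - 1.0},
                    {"type": "eq", "fun": lambda x: x[0] + x[1] - m["spc"]},
                ],
                method="SLSQP",
                options={"ftol": 1e-14, "maxiter": 200},
            )
            direct = solve_partition(system).as_array()
            assert float(np.sum((a @ res.x - b) ** 2)) < 1e-8
            # agreement limited by SLSQP's practical accuracy
            np.testing.assert_allclose(res.x, direct, atol=2e-3)
            np.testing.assert_allclose(direct, f_true, atol=1e-9)
            checked += 1


class TestPartitionSolution:
    def test_validation(self):
        with pytest.raises(InvalidInputError):
            PartitionSolution(0.5, 0.5, 0.5, -0.5)
        with pytest.raises(InvalidInputError):
            PartitionSolution(0.4, 0.4, 0.1, 0.2)  # sum 1.1


class TestMonteCarlo:
    def test_zero_sd_feasible_all_accepted(self, exact_library):
        f_true = np.array([0.6, 0.2, 0.1, 0.1])
        draw = mean_library_draw(exact_library)
        sp_eff, o18_eff = effective_sources(draw, "RM", 0.5)
        m = tight_measurement(
            float(f_true @ sp_eff), float(f_true @ o18_eff), 0.8, 0.5, sd=0.0
        )
        run = monte_carlo_partition(exact_library, m, "RM", n_draws=500, seed=1)
        assert run.acceptance_count == 500
        np.testing.assert_allclose(run.mean, f_true, atol=1e-9)
        np.testing.assert_allclose(run.sd, 0.0, atol=1e-12)

    def test_zero_sd_infeasible_diagnostic_error(self, exact_library):
        # a measurement far outside the source polygon -> negative fractions
        m = tight_measurement(-40.0, -40.0, 0.8, 0.5, sd=0.0)
        with pytest.raises(NoAcceptedDrawsError) as excinfo:
            monte_carlo_partition(exact_library, m, "RM", n_draws=200, seed=1)
        diag = excinfo.value.diagnostics
        assert sum(v for k, v in diag.items() if k.startswith("f_")) > 0

    def test_seed_reproducibility(self, library, study_measurement):
        r1 = monte_carlo_partition(library, study_measurement, "RM", 5000, seed=9)
        r2 = monte_carlo_partition(library, study_measurement, "RM", 5000, seed=9)
        np.testing.assert_array_equal(r1.accepted, r2.accepted)
        assert r1.acceptance_count == r2.acceptance_count

    def test_accepted_constraints_hold_exactly(self, library, study_measurement):
        run = monte_carlo_partition(library, study_measurement, "RM", 20_000, seed=3)
        f = run.accepted
        np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(f[:, 0] + f[:, 1], run.accepted_spc, atol=1e-9)
        assert np.all(f >= -1e-9) and np.all(f <= 1 + 1e-9)

    def test_zero_eps_scenarios_identical_ensembles(self, library):
        """Without reduction fractionation the RM/MR distinction vanishes."""
        lib0 = SourceLibrary(
            signatures=library.signatures,
            eps_sp_mean=0.0, eps_sp_sd=0.0, eps_o_mean=0.0, eps_o_sd=0.0,
        )
        f = np.array([0.6, 0.25, 0.1, 0.05])
        m = EmittedMeasurement(
            float(f @ lib0.sp_means), 1.0, float(f @ lib0.o18_means), 1.0,
            0.85, 0.05, 0.5, 0.1,
        )
        rm = monte_carlo_partition(lib0, m, "RM", 5000, seed=4)
        mr = monte_carlo_partition(lib0, m, "MR", 5000, seed=4)
        assert rm.acceptance_count > 0
        np.testing.assert_array_equal(rm.accepted, mr.accepted)

    def test_parameter_recovery_small_sds(self, exact_library):
        """With near-deterministic inputs the MC mean recovers the truth
        within 3 Monte Carlo standard errors."""
        f_true = np.array([0.5, 0.3, 0.12, 0.08])
        draw = mean_library_draw(exact_library)
        sp_eff, o18_eff = effective_sources(draw, "RM", 0.6)
        m = EmittedMeasurement(
            float(f_true @ sp_eff), 0.1, float(f_true @ o18_eff), 0.1,
            0.8, 0.001, 0.6, 0.001,
        )
        run = monte_carlo_partition(exact_library, m, "RM", 20_000, seed=5)
        se = run.sd / np.sqrt(run.acceptance_count)
        assert np.all(np.abs(run.mean - f_true) < 3 * se + 1e-6)

    def test_estimator_api(self, library, study_measurement):
        est = MonteCarloPartitioner(n_draws=2000, random_state=0)
        params = est.get_params()
        assert params["n_draws"] == 2000 and params["scenario"] == "RM"
        est.set_params(scenario="MR").fit(study_measurement)
        assert est.fractions_.shape == (4,)
        assert est.run_.scenario is Scenario.MR

    def test_fixed_point_mode_converges(self, library, study_measurement):
        fluxes = study_flux_summary()
        est = MonteCarloPartitioner(
            scenario="RM", n_draws=5000, random_state=7, fixed_point=True,
            fluxes=fluxes,
        ).fit(study_measurement)
        # accepted r values satisfy r = f_bD*N2O / (f_bD*N2O + N2)
        f_bd = est.accepted_[:, 0]
        r_expected = f_bd * fluxes.n2o_total / (
            f_bd * fluxes.n2o_total + fluxes.n2_denitrified
        )
        np.testing.assert_allclose(est.run_.accepted_r, r_expected, atol=1e-4)
        assert est.acceptance_count_ > 0


class TestRConsistency:
    def test_printed_mean_computations(self):
        fluxes = study_flux_summary()
        assert r_consistency_check(0.876, fluxes, "RM") == pytest.approx(
            0.3830, abs=5e-4
        )
        assert r_consistency_check(0.876, fluxes, "MR") == pytest.approx(
            0.4147, abs=5e-4
        )

    def test_full_bacterial_equals_macro_ratio(self):
        fluxes = study_flux_summary()
        rm_full = r_consistency_check(1.0, fluxes, "RM")
        assert rm_full == pytest.approx(
            fluxes.n2o_total / (fluxes.n2o_total + fluxes.n2_denitrified)
        )
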
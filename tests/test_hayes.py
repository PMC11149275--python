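"""Hayes layered-punch correction: kernel, kappa solver, modulus conversion."""

import numpy as np
import pytest

from indentmech import (SpecimenGeometry, build_kappa_table, equilibrium_modulus,
                        interpolate_kappa, solve_kappa, solve_kappa_reference,
                        tangent_modulus)
from indentmech.errors import (DomainError, ExtrapolationError, ParameterError,
                               QCRejectedError)
from indentmech.hayes import KappaTable, layer_compliance
from indentmech.processing import QCDecision

ALPHA_GRID = np.concatenate([np.linspace(0.05, 1.0, 10), np.linspace(1.5, 8.0, 10)])
NU_GRID = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.45])

# Bonded-layer surface compliance W(x, nu) at spot points, frozen from an
# independent Love-function elasticity solution of the layer-on-rigid-base
# boundary-value problem (4x4 Hankel-space solve, agreement ~1e-12).
W_ORACLE = [
    (0.5, 0.30, 0.206642486367),
    (1.0, 0.40, 0.351843894589),
    (2.0, 0.00, 0.820331829495),
    (5.0, 0.45, 0.995385573579),
    (0.1, 0.49, 0.004425497454),
]


class TestKernel:
    @pytest.mark.parametrize("x,nu,expected", W_ORACLE)
    def test_layer_compliance_matches_elasticity_solution(self, x, nu, expected):
        assert layer_compliance(x, nu) == pytest.approx(expected, rel=1e-9)

    def test_compliance_limits(self):
        assert layer_compliance(0.0, 0.4) == 0.0
        assert layer_compliance(30.0, 0.4) == pytest.approx(1.0, abs=1e-12)


class TestSolveKappa:
    def test_half_space_limit(self):
        for nu in NU_GRID:
            assert solve_kappa(1e-6, nu) == pytest.approx(1.0, abs=1e-3)

    def test_kappa_exceeds_one_for_unit_aspect(self):
        assert solve_kappa(1.0, 0.4) > 1.0

    def test_kappa_at_least_one_on_grid(self):
        for a in ALPHA_GRID:
            for nu in NU_GRID:
                assert solve_kappa(a, nu) >= 1.0

    def test_monotone_in_alpha_and_nu(self):
        k = np.array([[solve_kappa(a, nu) for nu in NU_GRID] for a in ALPHA_GRID])
        assert (np.diff(k, axis=0) >= 0).all()  # confinement grows with alpha
        thick = ALPHA_GRID >= 0.5
        assert (np.diff(k[thick], axis=1) >= 0).all()  # and with incompressibility

    def test_step_halving_converged(self):
        for a, nu in [(0.5, 0.0), (1.0, 0.4), (4.0, 0.45), (8.0, 0.3)]:
            k1 = solve_kappa(a, nu, step=0.01)
            k2 = solve_kappa(a, nu, step=0.005)
            assert abs(k2 - k1) / k1 < 0.002

    def test_kernel_truncation_converged(self):
        from indentmech.hayes import _solve_kappa_impl
        k40 = _solve_kappa_impl(2.0, 0.4, 0.01, 40.0)
        k80 = _solve_kappa_impl(2.0, 0.4, 0.01, 80.0)
        assert abs(k80 - k40) < 1e-6

    @pytest.mark.parametrize("alpha,nu", [
        (0.5, 0.4), (1.0, 0.4), (2.0, 0.3), (4.0, 0.45), (8.0, 0.0)])
    def test_production_vs_fine_mesh_oracle(self, alpha, nu):
        """Step-0.01 Nystrom vs Richardson-extrapolated fine mesh, < 0.5%."""
        prod = solve_kappa(alpha, nu)
        ref = solve_kappa_reference(alpha, nu)
        assert abs(prod - ref) / ref < 0.005

    @pytest.mark.parametrize("alpha,nu,err", [
        (0.0, 0.4, DomainError), (-1.0, 0.4, DomainError),
        (1.0, 0.5, DomainError), (1.0, -0.1, DomainError)])
    def test_domain_errors(self, alpha, nu, err):
        with pytest.raises(err):
            solve_kappa(alpha, nu)

    def test_step_out_of_range(self):
        with pytest.raises(ParameterError):
            solve_kappa(1.0, 0.4, step=0.5)


class TestKappaTable:
    def test_single_point_table_equals_direct_solve(self):
        table = build_kappa_table([1.0], [0.4])
        assert table.kappa[0, 0] == solve_kappa(1.0, 0.4)
        assert interpolate_kappa(table, 1.0, 0.4) == table.kappa[0, 0]

    def test_round_trip_bit_identical(self, tmp_path):
        table = build_kappa_table([0.5, 1.0, 2.0], [0.3, 0.4])
        path = tmp_path / "kappa.csv"
        table.to_csv(path)
        back = KappaTable.from_csv(path)
        assert np.array_equal(back.kappa, table.kappa)
        assert back.solver_step == table.solver_step

    def test_node_query_exact_and_midpoint_bounded(self):
        table = build_kappa_table([0.5, 1.0, 2.0], [0.3, 0.4])
        assert interpolate_kappa(table, 1.0, 0.4) == table.kappa[1, 1]
        mid = interpolate_kappa(table, 1.5, 0.35)
        block = table.kappa[1:3, 0:2]
        assert block.min() <= mid <= block.max()

    def test_interpolation_error_below_half_percent(self):
        """At 0.05 alpha / 0.0125 nu spacing, bilinear error stays < 0.5%.

        kappa is strongly convex in nu approaching incompressibility, so the
        nu grid must be this dense for the budget to hold near nu = 0.45.
        """
        table = build_kappa_table(np.linspace(0.4, 2.0, 33),
                                  np.linspace(0.35, 0.45, 9))
        for a in [0.75, 1.35, 1.95]:
            for nu in [0.35625, 0.40625, 0.44375]:
                approx = interpolate_kappa(table, a, nu)
                exact = solve_kappa(a, nu)
                assert abs(approx - exact) / exact < 0.005

    def test_out_of_hull_refused(self):
        table = build_kappa_table([0.5, 1.0], [0.3, 0.4])
        with pytest.raises(ExtrapolationError):
            interpolate_kappa(table, 3.0, 0.35)


class TestModuli:
    def test_hertz_limit_arithmetic(self):
        """slope 0.04 N/um, R = 525 um, nu = 0.4, kappa = 1 -> 32.0 MPa."""
        geom = SpecimenGeometry(thickness_um=525.0)
        assert tangent_modulus(0.04, geom, kappa=1.0) == pytest.approx(32.0)
        assert equilibrium_modulus(2.0, 50.0, geom, kappa=1.0) == pytest.approx(32.0)

    def test_hertz_limit_closed_form_randomized(self, rng):
        """kappa=1 conversion equals E = slope (1-nu^2)/(2R) on 200 cases."""
        for _ in range(200):
            slope = rng.uniform(1e-4, 0.1)
            r = rng.uniform(100.0, 2000.0)
            nu = rng.uniform(0.0, 0.49)
            geom = SpecimenGeometry(thickness_um=r, indenter_radius_um=r, poisson_nu=nu)
            expected = slope * (1 - nu ** 2) / (2 * r) * 1e6
            assert tangent_modulus(slope, geom, kappa=1.0) == pytest.approx(
                expected, rel=1e-9)

    def test_kappa_doubling_halves_modulus(self):
        geom = SpecimenGeometry(thickness_um=525.0)
        assert tangent_modulus(0.04, geom, kappa=2.0) == pytest.approx(
            tangent_modulus(0.04, geom, kappa=1.0) / 2.0, rel=1e-12)

    def test_linear_scaling_metamorphic(self, rng):
        """E scales linearly in load, inversely in R and kappa."""
        for _ in range(50):
            slope, r, nu, kap = (rng.uniform(0.001, 0.1), rng.uniform(200, 1000),
                                 rng.uniform(0, 0.45), rng.uniform(1.0, 5.0))
            c = rng.uniform(0.5, 3.0)
            g1 = SpecimenGeometry(thickness_um=r, indenter_radius_um=r, poisson_nu=nu)
            g2 = SpecimenGeometry(thickness_um=c * r, indenter_radius_um=c * r,
                                  poisson_nu=nu)
            e1 = tangent_modulus(slope, g1, kap)
            assert tangent_modulus(c * slope, g1, kap) == pytest.approx(c * e1, rel=1e-12)
            assert tangent_modulus(slope, g2, kap) == pytest.approx(e1 / c, rel=1e-12)
            assert tangent_modulus(slope, g1, c * kap) == pytest.approx(e1 / c, rel=1e-12)

    def test_rejected_fit_refused(self):
        geom = SpecimenGeometry(thickness_um=525.0)
        bad = QCDecision(accepted=False, reason="R^2 = 0.5 < 0.8")
        with pytest.raises(QCRejectedError, match="R\\^2"):
            tangent_modulus(0.04, geom, kappa=1.0, qc_decision=bad)

    def test_equilibrium_domain_error(self):
        geom = SpecimenGeometry(thickness_um=525.0)
        with pytest.raises(DomainError):
            equilibrium_modulus(1.0, 0.0, geom, kappa=1.0)

    def test_sls_equilibrium_recovery_within_one_percent(self, clean_curve,
                                                         protocol, sls_params):
        from indentmech import (Phase, equilibrium_load, extract_phase,
                                segment_phases)
        curve, truth = clean_curve
        seg = segment_phases(curve, protocol)
        eq = equilibrium_load(extract_phase(curve, seg, Phase.HOLD))
        geom = sls_params.geometry
        e_eq = equilibrium_modulus(eq.p_eq_n, eq.x0_eq_um, geom, truth.kappa)
        assert e_eq == pytest.approx(sls_params.e_inf_mpa, rel=0.01)
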
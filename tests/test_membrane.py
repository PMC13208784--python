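"""Membrane mechanics: shape function, strain field, calibration, uniformity."""

import numpy as np
import pytest
from scipy.integrate import quad

from memstretch import (
    CultureRegion,
    GridSpec,
    MembraneModel,
    MembraneSpec,
    Metric,
    average_membrane_strain,
    calibrate_deflection,
    clamped_shape,
    flexural_rigidity,
    grid_independence,
    pressure_check,
    strain_field,
    uniformity_report,
)
from memstretch.membrane import DeflectionField, StrainField


SPEC = MembraneSpec()
GRID = GridSpec()


class TestFlexuralRigidity:
    def test_reference_value(self):
        # E t^3 / [12 (1 - nu^2)] at E=750 kPa, t=200 um, nu=0.49
        assert flexural_rigidity(SPEC) == pytest.approx(6.58e-7, rel=1e-3)

    def test_zero_poisson_reduces(self):
        s = MembraneSpec(poisson_nu=0.0)
        assert flexural_rigidity(s) == pytest.approx(s.youngs_E * s.thickness_t**3 / 12)

    def test_cubic_thickness_scaling(self):
        s2 = MembraneSpec(thickness_t=400e-6)
        assert flexural_rigidity(s2) == pytest.approx(8 * flexural_rigidity(SPEC))

    @pytest.mark.parametrize(
        "bad",
        [dict(thickness_t=0.0), dict(youngs_E=-1.0), dict(poisson_nu=0.5),
         dict(length_a=2e-3)],  # length must exceed width
    )
    def test_invalid_parameters_raise(self, bad):
        with pytest.raises(ValueError):
            MembraneSpec(**bad)


class TestClampedShape:
    @pytest.mark.parametrize("profile", ["cosine", "plateau"])
    def test_clamped_boundary_and_center(self, profile):
        w0 = 5e-4
        d = clamped_shape(SPEC, GRID, w0, profile=profile)
        assert np.all(d.w[0, :] == 0) and np.all(d.w[-1, :] == 0)
        assert np.all(d.w[:, 0] == 0) and np.all(d.w[:, -1] == 0)
        assert d.w.max() == pytest.approx(w0)
        assert d.w[GRID.nx // 2, GRID.ny // 2] == pytest.approx(w0)

    def test_cosine_quarter_point(self):
        # S(1/4) = 1/2, S(1/2) = 1 for the clamped cosine mode
        w0 = 5e-4
        d = clamped_shape(SPEC, GRID, w0, profile="cosine")
        assert d.w[GRID.nx // 4, GRID.ny // 2] == pytest.approx(w0 / 2, rel=1e-12)

    @pytest.mark.parametrize("profile", ["cosine", "plateau"])
    def test_zero_normal_slope_at_edges(self, profile):
        d = clamped_shape(SPEC, GRID, 5e-4, profile=profile)
        x, y = GRID.axes(SPEC)
        # one-sided slope at the clamped edge is O(h) relative to the peak
        # section slope pi w0 / b
        hy = y[1] - y[0]
        edge_slope = np.abs(d.w[:, 1] - d.w[:, 0]).max() / hy
        assert edge_slope < 0.05 * np.pi * d.w0 / SPEC.width_b

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            clamped_shape(SPEC, GRID, -1e-4)


class TestStrainField:
    def test_flat_membrane_is_strain_free(self):
        sf = strain_field(clamped_shape(SPEC, GRID, 0.0))
        for arr in (sf.eps_m_xx, sf.eps_m_yy, sf.eps_m_xy, sf.eps_b_xx, sf.eps_vm):
            assert np.allclose(arr, 0.0)

    def test_pointwise_ramp_closed_form(self):
        # w = k x: interior arc-length strain sqrt(1 + k^2) - 1 along x only
        k = 0.3
        x, _ = GRID.axes(SPEC)
        w = np.broadcast_to((k * x)[:, None], (GRID.nx, GRID.ny)).copy()
        d = DeflectionField(w=w, spec=SPEC, grid=GRID, w0=float(w.max()))
        sf = strain_field(d, SPEC, surface="midplane", membrane_strain="pointwise")
        interior = sf.eps_m_xx[1:-1, 1:-1]
        assert np.allclose(interior, np.sqrt(1 + k**2) - 1, rtol=1e-10)
        assert np.allclose(sf.eps_m_yy, 0.0)

    def test_von_mises_nonnegative_and_symmetric(self, calibrated_results):
        vm = calibrated_results.strain.eps_vm
        assert (vm >= 0).all()
        assert np.allclose(vm, vm[::-1, :], rtol=1e-10, atol=1e-14)
        assert np.allclose(vm, vm[:, ::-1], rtol=1e-10, atol=1e-14)

    def test_equilibrated_strain_uniform_across_section(self, calibrated_results):
        # in-plane force balance: membrane strain constant along each section
        eyy = calibrated_results.strain.eps_m_yy
        assert np.allclose(eyy, eyy[:, :1], atol=1e-15)

    def test_bending_membrane_ratio_shrinks_with_deflection(self):
        # bending scales t*kappa/2, membrane ~ (w0/b)^2: ratio ~ t/w0
        model = MembraneModel()
        ratios = []
        for w0 in (2e-4, 4e-4, 8e-4):
            sf = model.strain(w0)
            i, j = GRID.nx // 2, GRID.ny // 2
            ratios.append(sf.eps_b_yy[i, j] / sf.eps_m_yy[i, j])
        assert ratios[0] > ratios[1] > ratios[2]
        assert ratios[2] < 1.5  # comparable at w0/t = 4, membrane-dominated beyond

    def test_unknown_conventions_raise(self):
        d = clamped_shape(SPEC, GRID, 1e-4)
        with pytest.raises(ValueError):
            strain_field(d, SPEC, membrane_strain="nope")
        with pytest.raises(ValueError):
            strain_field(d, SPEC, surface="nope")


class TestAverageStrainMetrics:
    def test_centerline_matches_quadrature_oracle(self):
        # independent oracle: adaptive quadrature of the arc-length integrand
        w0, b = 6e-4, SPEC.width_b
        sf = strain_field(clamped_shape(SPEC, GRID, w0))
        got = average_membrane_strain(sf, Metric.centerline)
        arc, _ = quad(
            lambda y: np.sqrt(1 + (w0 * np.pi / b * np.sin(2 * np.pi * y / b)) ** 2),
            0.0,
            b,
            limit=200,
        )
        assert got == pytest.approx((arc - b) / b, rel=1e-6)

    def test_region_metric_is_masked_mean(self):
        sf = strain_field(clamped_shape(SPEC, GRID, 5e-4))
        region = CultureRegion(0.6)
        got = average_membrane_strain(sf, Metric.region_vm_mean, region)
        assert got == pytest.approx(sf.eps_vm_membrane[region.mask(GRID)].mean())

    def test_metric_ordering(self):
        # centerline section is the most-stretched section, so it dominates
        sf = strain_field(clamped_shape(SPEC, GRID, 5e-4))
        full = average_membrane_strain(sf, Metric.membrane_vm_mean)
        center = average_membrane_strain(sf, Metric.centerline)
        assert center > full > 0

    def test_unknown_metric_raises(self):
        sf = strain_field(clamped_shape(SPEC, GRID, 1e-4))
        with pytest.raises(ValueError):
            average_membrane_strain(sf, "bogus")


class TestCalibration:
    def test_zero_target_gives_zero_deflection(self):
        assert calibrate_deflection(SPEC, GRID, 0.0) == 0.0

    @pytest.mark.parametrize("metric", list(Metric))
    def test_average_strain_increases_with_w0(self, metric):
        vals = []
        for w0 in np.linspace(1e-4, 1e-3, 5):
            sf = strain_field(clamped_shape(SPEC, GRID, w0))
            vals.append(average_membrane_strain(sf, metric))
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("target", [0.02, 0.10, 0.25])
    def test_calibration_hits_target(self, target):
        w0 = calibrate_deflection(SPEC, GRID, target)
        sf = strain_field(clamped_shape(SPEC, GRID, w0))
        assert average_membrane_strain(sf) == pytest.approx(target, rel=1e-6)

    def test_large_deflection_regime(self, calibrated_results):
        # at 10 % strain the membrane is far beyond the linear-plate regime
        assert calibrated_results.deflection_to_thickness > 1

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_deflection(SPEC, GridSpec(nx=61, ny=21), 50.0)


def _field_with_vm(values):
    """StrainField stub whose eps_vm is prescribed (3x3 grid)."""
    g = GridSpec(nx=3, ny=3)
    s = MembraneSpec()
    z = np.zeros((3, 3))
    vm = np.asarray(values, float)
    d = DeflectionField(w=z, spec=s, grid=g, w0=0.0)
    return StrainField(z, z, z, z, z, vm, vm, d)


class TestUniformityReport:
    def test_constant_field(self):
        rep = uniformity_report(_field_with_vm(np.full((3, 3), 0.12)), CultureRegion(1.0))
        assert rep.cv_percent == pytest.approx(0.0, abs=1e-12)
        assert rep.uniformity_percent == pytest.approx(100.0)
        assert rep.min_strain == rep.max_strain == pytest.approx(0.12)

    def test_two_value_field_population_sd(self):
        # {0.10, 0.20} half/half: mean 0.15, population SD 0.05, CV = 33.33 %
        vals = np.array([0.10, 0.20, 0.10, 0.20, 0.10, 0.20, 0.10, 0.20, 0.15])
        rep = uniformity_report(_field_with_vm(vals.reshape(3, 3)), CultureRegion(1.0))
        assert rep.mean_strain == pytest.approx(vals.mean())
        assert rep.cv_percent == pytest.approx(100 * vals.std() / vals.mean())
        two = np.array([0.10, 0.20])
        assert 100 * two.std() / two.mean() == pytest.approx(33.333, abs=1e-2)

    def test_report_invariants(self, calibrated_results):
        rep = calibrated_results.report
        assert rep.min_strain <= rep.mean_strain <= rep.max_strain
        assert rep.cv_percent >= 0
        assert rep.uniformity_percent == pytest.approx(100 - rep.cv_percent)

    def test_region_area_fraction(self):
        mask = CultureRegion(0.60).mask(GRID)
        assert mask.mean() == pytest.approx(0.60, abs=0.02)


class TestGridIndependence:
    def test_identical_grids_zero(self):
        assert grid_independence(SPEC, GRID, GRID, 5e-4) == 0.0

    def test_second_order_convergence_cosine(self):
        # classical separable shape: peak strain converges at O(h^2)
        w0 = 5e-4
        peaks = []
        for f in (1, 2, 4, 8):
            g = GridSpec(nx=60 * f + 1, ny=20 * f + 1)
            sf = strain_field(
                clamped_shape(SPEC, g, w0, profile="cosine"),
                SPEC,
                membrane_strain="pointwise",
            )
            peaks.append(sf.eps_vm.max())
        d1, d2, d3 = peaks[0] - peaks[2], peaks[1] - peaks[2], peaks[2] - peaks[3]
        ratio = abs(peaks[0] - peaks[3]) / abs(peaks[1] - peaks[3])
        assert 3.0 < ratio < 6.0  # ~4 for second order

    def test_default_refinement_small(self, calibrated_results):
        assert calibrated_results.grid_variation() < 0.02


class TestPressureCheck:
    def test_zero_deflection(self):
        assert pressure_check(SPEC, GRID, 0.0) == 0.0

    def test_bending_term_against_closed_form(self):
        # Galerkin bending coefficient of the separable cosine shape:
        # D w0 pi^4 (64/9) [3/(4 a^4) + 1/(2 a^2 b^2) + 3/(4 b^4)]
        from memstretch.membrane import flexural_rigidity

        w0 = 5e-4
        a, b = SPEC.length_a, SPEC.width_b
        closed = (
            flexural_rigidity(SPEC)
            * w0
            * np.pi**4
            * (64 / 9)
            * (3 / (4 * a**4) + 1 / (2 * a**2 * b**2) + 3 / (4 * b**4))
        )
        got = pressure_check(
            SPEC, GridSpec(481, 161), w0, profile="cosine", include_membrane=False
        )
        assert got == pytest.approx(closed, rel=0.02)

    def test_order_of_magnitude_of_applied_vacuum(self, calibrated_results):
        p = calibrated_results.implied_pressure()
        assert 2e3 < p < 2e5  # same order as the 20 kPa working pressure


class TestModelResults:
    def test_summary_mentions_conventions(self, calibrated_results):
        s = calibrated_results.summary()
        assert "centerline" in s and "plateau" in s
        assert "max deflection" in s

    def test_dataframe_shape(self, calibrated_results):
        df = calibrated_results.to_dataframe()
        assert len(df) == GRID.nx * GRID.ny
        assert {"x", "y", "w", "eps_vm"} <= set(df.columns)

    def test_achieved_average_matches_target(self, calibrated_results):
        assert calibrated_results.achieved_average == pytest.approx(0.10, rel=1e-6)
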
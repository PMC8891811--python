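"""Field solver verification against closed-form and semi-analytic oracles."""

import dataclasses
import math

import numpy as np
import pytest

import tfusim
from tfusim import (
    Medium,
    assemble_system,
    build_domain,
    calibrate_source,
    focal_metrics,
    peak_pressure,
    solve,
    solve_field,
    transfer_matrix_1d,
)
from tfusim.solver import PressureField

WATER_WAVELENGTH = 1482.0 / 1.0e6


def rayleigh_axial(z_points, z0, curvature, aperture, frequency=1.0e6,
                   c=1482.0, n_quad=6000):
    """Numeric Rayleigh integral of the phased annular aperture on axis.

    Independent oracle for the focused source: each aperture annulus
    radiates exp(-ikd)/d weighted by the converging spherical phase.
    """
    k = 2 * math.pi * frequency / c
    r = np.linspace(0.0, aperture, n_quad)
    phase = k * (np.sqrt(r * r + curvature * curvature) - curvature)
    out = []
    for zz in z_points:
        d = np.sqrt(r * r + (zz - z0) ** 2)
        out.append(np.trapezoid(np.exp(1j * phase) * np.exp(-1j * k * d) / d * r, r))
    return np.abs(out)


def column_field(config, layers, source_z=0.005):
    cfg = config.with_layers(layers)
    domain = build_domain(cfg, radial_pml=False)
    field = solve(domain, cfg.transducer, source=("plane", source_z))
    return field, domain


class TestDomain:
    def test_single_slab_layout(self, default_config):
        cfg = default_config.with_layers([("skull", 5e-3)])
        domain = build_domain(cfg)
        assert len(domain.layers) == 1
        medium, z0, z1 = domain.layers[0]
        assert medium.name == "skull"
        assert z1 - z0 == pytest.approx(5e-3, abs=domain.spacing / 2)

    def test_empty_layer_list_is_free_field(self, default_config):
        domain = build_domain(default_config.with_layers([]))
        assert domain.layers == ()
        assert all(m.name == "water" for m in domain.medium_profile())

    def test_multilayer_ordering_and_contiguity(self, default_config):
        cfg = default_config.with_layers(
            [("scalp", 3.35e-3), ("skull", 5e-3), ("brain", 40e-3)]
        )
        domain = build_domain(cfg)
        names = [m.name for m, _, _ in domain.layers]
        assert names == ["scalp", "skull", "brain"]
        for (_, _, end), (_, start, _) in zip(domain.layers, domain.layers[1:]):
            assert end == pytest.approx(start)

    def test_coarse_grid_rejected_naming_medium(self, default_config):
        grid = dataclasses.replace(default_config.grid, spacing=5e-4)
        cfg = dataclasses.replace(default_config, grid=grid)
        with pytest.raises(ValueError, match="scalp|water"):
            build_domain(cfg.with_layers([("scalp", 5e-3)]))

    def test_oversized_layer_rejected_by_name(self, default_config):
        with pytest.raises(ValueError, match="brain"):
            build_domain(default_config.with_layers([("brain", 0.2)]))


class TestOperator:
    def test_plane_wave_residual_second_order(self, default_config):
        """The discrete operator annihilates a sampled plane wave at a rate
        consistent with a second-order scheme as the grid is refined."""
        residuals = []
        for h in (1.5e-4, 7.5e-5):
            grid = dataclasses.replace(
                default_config.grid, spacing=h, radial_extent=3e-3,
                axial_extent=0.030,
            )
            cfg = dataclasses.replace(default_config, grid=grid)
            domain = build_domain(cfg)
            system = assemble_system(domain, cfg.transducer)
            k = 2 * math.pi * 1e6 / 1482.0
            p = np.exp(-1j * k * domain.z)[:, None] * np.ones(domain.r.size)
            res = (system.matrix @ p.ravel()).reshape(domain.shape)
            # interior rows only, away from both axial PMLs
            pad = domain.pml_cells + 2
            interior = np.abs(res[pad:-pad, :]).max() / (k * k)
            residuals.append(interior)
        ratio = residuals[0] / residuals[1]
        assert 3.0 < ratio < 5.5

    def test_zero_drive_yields_zero_field(self, small_config):
        t = dataclasses.replace(small_config.transducer, drive_amplitude=0.0)
        cfg = dataclasses.replace(small_config, transducer=t)
        field = solve(build_domain(cfg), t)
        assert np.all(field.p == 0)

    def test_field_scales_linearly_with_drive(self, small_config):
        domain = build_domain(small_config)
        f1 = solve(domain, small_config.transducer)
        doubled = dataclasses.replace(
            small_config.transducer,
            drive_amplitude=2 * small_config.transducer.drive_amplitude,
        )
        f2 = solve(domain, doubled)
        np.testing.assert_allclose(f2.p, 2.0 * f1.p, rtol=1e-12, atol=1e-14)

    def test_structured_and_sparse_lu_paths_agree(self, small_config):
        domain = build_domain(small_config.with_layers([("skull", 3e-3)]))
        system = assemble_system(domain, small_config.transducer)
        sep = solve_field(system, method="separated")
        lu = solve_field(system, method="splu")
        np.testing.assert_allclose(sep.p, lu.p, rtol=1e-9, atol=1e-12)

    def test_solution_is_finite_everywhere(self, water_solution):
        field, _ = water_solution
        assert np.all(np.isfinite(field.p))


class TestAbsorbingBoundary:
    def test_pml_reflection_below_one_percent(self, column_config):
        """Standing-wave ratio in a lossless water column terminated by the
        absorbing layer bounds the boundary reflection."""
        field, domain = column_field(column_config, [])
        h = domain.spacing
        amps = field.on_axis()[int(0.010 / h): int(0.035 / h)]
        swr = amps.max() / amps.min()
        assert (swr - 1) / (swr + 1) < 0.01

    def test_lossy_medium_plane_wave_decay(self, column_config):
        """In homogeneous lossy tissue the column amplitude decays at the
        Np/m rate implied by the dB/m attenuation (no spreading here)."""
        field, domain = column_field(column_config, [("brain", 20e-3)])
        _, z0, z1 = domain.layers[0]
        h = domain.spacing
        j0, j1 = int(z0 / h) + 40, int(z1 / h) - 40
        slope = np.polyfit(domain.z[j0:j1], np.log(field.on_axis()[j0:j1]), 1)[0]
        alpha_np = 85.0 * math.log(10) / 20.0
        assert -slope == pytest.approx(alpha_np, rel=0.05)


class TestQuasi1DTransmission:
    @pytest.mark.parametrize(
        "tissue, thickness_mm",
        [("skull", 5.0), ("skull", 3.5), ("brain", 5.0), ("scalp", 5.0)],
    )
    def test_column_matches_transfer_matrix(self, column_config, tissue,
                                            thickness_mm):
        """Radially uniform incidence through a slab reproduces the lossy
        transfer-matrix transmission within 5%."""
        ref_field, _ = column_field(column_config, [])
        field, domain = column_field(
            column_config, [(tissue, thickness_mm * 1e-3)]
        )
        j = int(round(0.030 / domain.spacing))
        ratio = field.on_axis()[j] / ref_field.on_axis()[j]
        t, _ = transfer_matrix_1d(
            [(column_config.materials[tissue], thickness_mm * 1e-3)], 1.0e6
        )
        assert ratio == pytest.approx(abs(t), rel=0.05)


class TestTransferMatrixOracle:
    def test_no_layers_identical_half_spaces(self):
        t, r = transfer_matrix_1d([], 1.0e6)
        assert t == pytest.approx(1.0)
        assert r == pytest.approx(0.0)

    def test_half_wavelength_layer_resonance(self):
        """A lossless half-wavelength layer transmits perfectly between
        identical half-spaces."""
        lossless_bone = Medium("bone", 4080.0, 1658.0, 0.0)
        d = 4080.0 / 1.0e6 / 2.0
        t, r = transfer_matrix_1d([(lossless_bone, d)], 1.0e6)
        assert abs(t) == pytest.approx(1.0, abs=1e-10)
        assert abs(r) == pytest.approx(0.0, abs=1e-10)

    def test_skull_transmission_below_absorption_bound(self):
        """5 mm of skull transmits less than its absorption-only bound of
        10^(-10/20) ~ 0.316 once interface losses are included."""
        skull = tfusim.load_materials()["skull"]
        t, _ = transfer_matrix_1d([(skull, 5e-3)], 1.0e6)
        assert abs(t) < 0.316

    def test_negative_thickness_rejected(self):
        skull = tfusim.load_materials()["skull"]
        with pytest.raises(ValueError):
            transfer_matrix_1d([(skull, -1e-3)], 1.0e6)


class TestFocalField:
    def test_focal_peak_location_matches_rayleigh_oracle(
        self, default_config, water_solution
    ):
        """The free-water axial maximum lies within one wavelength of the
        semi-analytic diffraction-integral prediction."""
        field, peak = water_solution
        domain = build_domain(default_config.with_layers([]))
        zq = np.linspace(0.070, 0.110, 800)
        oracle = rayleigh_axial(
            zq, domain.z_apex, default_config.transducer.curvature_radius,
            default_config.transducer.aperture_radius,
        )
        z_oracle = zq[np.argmax(oracle)]
        assert peak.r == 0.0
        assert abs(peak.z - z_oracle) < WATER_WAVELENGTH

    def test_calibration_hits_target_exactly(self, default_config):
        domain = build_domain(default_config.with_layers([]))
        spec = calibrate_source(domain, default_config.transducer, 2.276e6)
        field = solve(domain, spec)
        pk = peak_pressure(
            field,
            z_min=domain.z_apex + spec.cap_height + default_config.peak_margin,
            z_max=domain.z_interior_max,
        )
        assert pk.pressure == pytest.approx(2.276e6, rel=1e-9)

    def test_calibration_scales_linearly(self, default_config):
        domain = build_domain(default_config.with_layers([]))
        s1 = calibrate_source(domain, default_config.transducer, 1.0e6)
        s2 = calibrate_source(domain, default_config.transducer, 2.0e6)
        assert s2.drive_amplitude == pytest.approx(2 * s1.drive_amplitude,
                                                   rel=1e-12)
        s0 = calibrate_source(domain, default_config.transducer, 0.0)
        assert s0.drive_amplitude == 0.0

    def test_calibration_requires_water_only_domain(self, default_config):
        domain = build_domain(default_config.with_layers([("skull", 5e-3)]))
        with pytest.raises(ValueError, match="water-only"):
            calibrate_source(domain, default_config.transducer, 1.0e6)


def gaussian_field(sigma_r=1.2e-3, sigma_z=4.0e-3, center_z=0.02):
    r = np.linspace(0, 0.01, 201)
    z = np.linspace(0, 0.04, 401)
    rr, zz = np.meshgrid(r, z)
    p = 5.0 * np.exp(-0.5 * ((rr / sigma_r) ** 2 + ((zz - center_z) / sigma_z) ** 2))
    return PressureField(r=r, z=z, p=p.astype(complex), frequency=1e6), sigma_r, sigma_z


class TestFieldMetrics:
    def test_gaussian_fwhm_recovered(self):
        field, sr, sz = gaussian_field()
        met = focal_metrics(field)
        factor = 2.0 * math.sqrt(2.0 * math.log(2.0))
        assert met.fwhm_axial == pytest.approx(factor * sz, abs=1e-4)
        assert met.fwhm_lateral == pytest.approx(factor * sr, abs=5e-5)
        assert met.axial_peak_z == pytest.approx(0.02, abs=1e-4)
        assert not met.truncated

    def test_peak_of_synthetic_bump(self):
        field, _, _ = gaussian_field()
        pk = peak_pressure(field)
        assert pk.pressure == pytest.approx(5.0)
        assert pk.z == pytest.approx(0.02, abs=1e-4)
        assert pk.r == 0.0

    def test_region_excluding_peak_returns_smaller_value(self):
        field, _, _ = gaussian_field()
        off = peak_pressure(field, z_min=0.03)
        assert off.pressure < 5.0

    def test_empty_region_rejected(self):
        field, _, _ = gaussian_field()
        with pytest.raises(ValueError, match="empty"):
            peak_pressure(field, z_min=1.0)

    def test_truncated_half_maximum_is_flagged(self):
        """A peak whose half-maximum contour leaves the grid is reported as
        truncated rather than silently mismeasured."""
        field, _, _ = gaussian_field(sigma_z=0.05)
        met = focal_metrics(field)
        assert met.truncated
        assert math.isnan(met.fwhm_axial)

    def test_lateral_profile_symmetric_about_axis(self, water_solution):
        field, peak = water_solution
        assert peak.i_r == 0  # symmetric field peaks on the axis


class TestPhysicalOrdering:
    def test_attenuation_monotone_in_skull_absorption(self, default_config):
        """Halving the skull absorption coefficient lowers the transcranial
        attenuation, all else fixed."""
        softer = Medium("skull_soft", 4080.0, 1658.0, 1000.0)
        att_soft = tfusim.run_single_layer(softer, 5.0, default_config)
        att_full = tfusim.run_single_layer("skull", 5.0, default_config)
        assert att_soft < att_full

    def test_lossless_skull_attenuates_less_but_not_zero(self, default_config):
        """With absorption off, the remaining attenuation (impedance
        mismatch + refraction) is positive but well below the lossy value."""
        lossless = Medium("skull_lossless", 4080.0, 1658.0, 0.0)
        att_lossless = tfusim.run_single_layer(lossless, 5.0, default_config)
        att_lossy = tfusim.run_single_layer("skull", 5.0, default_config)
        assert 0.0 < att_lossless < att_lossy

    def test_focal_length_insensitivity_of_attenuation_ratio(self, default_config):
        """A +-5 mm curvature-radius error moves the 5 mm skull attenuation
        by only a few percentage points (sub-critical focusing geometry)."""
        results = []
        for radius in (0.085, 0.095):
            t = dataclasses.replace(default_config.transducer,
                                    curvature_radius=radius)
            cfg = dataclasses.replace(default_config, transducer=t)
            results.append(tfusim.run_single_layer("skull", 5.0, cfg))
        assert abs(results[0] - results[1]) < 5.0
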
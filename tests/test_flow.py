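"""Flow and stress fields: series solution, Dean circulation, FSS/EFS."""

import math

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from spiralsort import (
    FluidState,
    SpiralChannel,
    build_default_device,
    build_path,
    dean_number,
    dean_velocity,
    efs_profile,
    fss_field,
    primary_flow,
    secondary_flow,
    stress_summary,
    water_at_20c,
)
from spiralsort.geometry import SpiralPath


def poisson_duct_oracle(channel, fluid, dpdx, n=64):
    """Brute-force finite-difference solve of the same duct problem.

    Solves mu * laplacian(u) = -dpdx with u = 0 on the walls; independent
    of the series solution it cross-checks.
    """
    a = 0.5 * channel.width_um * 1e-6
    b = 0.5 * channel.height_um * 1e-6
    y = np.linspace(-a, a, n + 1)
    z = np.linspace(-b, b, n + 1)
    hy, hz = y[1] - y[0], z[1] - z[0]
    ny, nz = n - 1, n - 1

    def d2(m, h):
        return sp.diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(m, m)) / h**2

    lap = sp.kron(sp.identity(nz), d2(ny, hy)) + sp.kron(d2(nz, hz), sp.identity(ny))
    rhs = np.full(ny * nz, -dpdx / fluid.viscosity_pa_s)
    u = np.zeros((n + 1, n + 1))
    u[1:-1, 1:-1] = spla.spsolve(lap.tocsr(), rhs).reshape(nz, ny)
    return u


class TestPrimaryFlow:
    def test_mean_velocity_is_q_over_a(self, base_flow):
        assert base_flow.mean_velocity == pytest.approx(
            (1e-6 / 60.0) / (500e-6 * 130e-6), rel=1e-12
        )
        assert base_flow.mean_velocity == pytest.approx(0.2564, rel=1e-3)

    @pytest.mark.parametrize("resolution", [32, 64])
    def test_flux_conservation(self, channel, fluid, resolution):
        field = primary_flow(channel, fluid, resolution=resolution)
        assert abs(field.flux() / fluid.flow_rate_m3_s - 1.0) < 1e-3

    def test_no_slip_and_nonnegative(self, base_flow):
        assert np.all(base_flow.u >= 0)
        assert np.all(base_flow.u[0, :] == pytest.approx(0.0, abs=1e-12))
        assert np.all(base_flow.u[-1, :] == pytest.approx(0.0, abs=1e-12))
        assert np.all(base_flow.u[:, 0] == pytest.approx(0.0, abs=1e-10))
        assert np.all(base_flow.u[:, -1] == pytest.approx(0.0, abs=1e-10))

    def test_zero_flow_gives_zero_field(self, channel):
        still = primary_flow(channel, water_at_20c(0.0), resolution=32)
        assert np.all(still.u == 0)
        assert fss_field(still, water_at_20c(0.0)).full_max == 0.0

    def test_series_matches_poisson_oracle(self, channel, fluid, base_flow):
        u_fd = poisson_duct_oracle(channel, fluid, base_flow.dpdx_pa_m, n=64)
        rel = abs(u_fd.max() - base_flow.u.max()) / base_flow.u.max()
        assert rel < 0.01

    def test_parallel_plate_limit_wall_shear(self):
        # W/H -> inf at fixed mean velocity: shear at the long-wall midpoint
        # tends to the plate formula 6 mu U / H
        wide = SpiralChannel(width_um=13000.0, height_um=130.0)
        u_bar = 0.2564
        q = u_bar * wide.area_um2 * 1e-12
        fl = FluidState(flow_rate_m3_s=q)
        field = primary_flow(wide, fl, resolution=64, n_terms=401)
        _, du_dz = field.grad_u()
        mid = field.y_m.size // 2
        shear = abs(fl.viscosity_pa_s * du_dz[-1, mid])
        plate = 6 * fl.viscosity_pa_s * u_bar / 130e-6
        assert shear == pytest.approx(plate, rel=0.02)

    def test_resolution_and_terms_preconditions(self, channel, fluid):
        with pytest.raises(ValueError):
            primary_flow(channel, fluid, resolution=8)
        with pytest.raises(ValueError):
            primary_flow(channel, fluid, n_terms=5)


class TestSecondaryFlow:
    def test_straight_channel_has_no_secondary_flow(self, base_flow, channel, fluid):
        still = secondary_flow(base_flow, channel, fluid, math.inf)
        assert np.all(still.v == 0) and np.all(still.w == 0)

    def test_mirror_antisymmetry(self, base_flow, channel, fluid):
        field = secondary_flow(base_flow, channel, fluid, 5e-3)
        assert np.allclose(field.v, field.v[::-1, :], atol=1e-9 * np.abs(field.v).max())
        assert np.allclose(field.w, -field.w[::-1, :], atol=1e-9 * np.abs(field.v).max())

    def test_two_counter_rotating_cells(self, base_flow, channel, fluid):
        field = secondary_flow(base_flow, channel, fluid, 5e-3)
        nz, ny = field.v.shape
        centre = field.v[nz // 2, ny // 2]
        near_top = field.v[int(0.9 * (nz - 1)), ny // 2]
        # outward flow at the mid-plane returns along the top/bottom walls
        assert centre * near_top < 0

    def test_magnitude_tracks_dean_velocity_correlation(
        self, base_flow, channel, fluid
    ):
        field = secondary_flow(base_flow, channel, fluid, 5e-3)
        u_dean = dean_velocity(dean_number(fluid, channel, 5e-3))
        peak = np.max(np.hypot(field.v, field.w))
        assert u_dean / 3 < peak < u_dean * 3

    def test_zero_net_flux_of_secondary_flow(self, base_flow, channel, fluid):
        field = secondary_flow(base_flow, channel, fluid, 5e-3)
        hy = field.y_m[1] - field.y_m[0]
        hz = field.z_m[1] - field.z_m[0]
        net_v = np.trapezoid(np.trapezoid(field.v, dx=hy), dx=hz)
        net_w = np.trapezoid(np.trapezoid(field.w, dx=hy), dx=hz)
        area = 500e-6 * 130e-6
        scale = np.max(np.hypot(field.v, field.w)) * area
        # the streamfunction construction makes both vanish analytically;
        # the residual is second-order differencing error
        assert abs(net_v) < 5e-3 * scale
        assert abs(net_w) < 5e-3 * scale

    def test_nonpositive_radius_rejected(self, base_flow, channel, fluid):
        with pytest.raises(ValueError):
            secondary_flow(base_flow, channel, fluid, -1.0)


class TestShearStress:
    def test_literal_form_vanishes_in_straight_duct(self, base_flow, fluid):
        assert fss_field(base_flow, fluid).literal_max == 0.0

    def test_full_shear_bounded_below_by_plate_formula(self, base_flow, fluid):
        # the parallel-plate closed form is a lower bound at the wall midpoint
        plate = 6 * fluid.viscosity_pa_s * base_flow.mean_velocity / 130e-6
        assert fss_field(base_flow, fluid).full_max >= plate

    def test_maximum_sits_on_top_or_bottom_wall(self, summary):
        _, z_um = summary.fss_max_location_um
        assert abs(abs(z_um) - 65.0) < 1e-6

    def test_grid_convergence_of_fss_max(self, channel, fluid):
        f64 = fss_field(primary_flow(channel, fluid, 64), fluid).full_max
        f128 = fss_field(primary_flow(channel, fluid, 128), fluid).full_max
        assert abs(f128 - f64) / f64 < 0.02

    def test_coarse_grid_rejected(self, channel, fluid):
        # bypass the primary_flow floor to hit the differencing guard
        field = primary_flow(channel, fluid, resolution=16)
        coarse = field.__class__(
            y_m=field.y_m[::4],
            z_m=field.z_m[::4],
            u=field.u[::4, ::4],
            v=field.v[::4, ::4],
            w=field.w[::4, ::4],
            channel=field.channel,
            fluid=field.fluid,
            dpdx_pa_m=field.dpdx_pa_m,
            n_terms=field.n_terms,
        )
        with pytest.raises(ValueError):
            fss_field(coarse, fluid)


def straight_path(length_um=5000.0, n=200, width_um=500.0, height_um=130.0):
    s = np.linspace(0.0, length_um, n)
    return SpiralPath(
        s_um=s,
        radius_um=np.full(n, np.inf),
        theta_rad=np.zeros(n),
        width_um=np.full(n, width_um),
        area_um2=np.full(n, width_um * height_um),
        in_cone=np.zeros(n, dtype=bool),
    )


class TestExtensionalStress:
    def test_constant_area_straight_segment_is_stress_free(self, channel, fluid):
        prof = efs_profile(channel, fluid, path=straight_path(), curvature_model=False)
        assert np.allclose(prof["efs_pa"], 0.0, atol=1e-12)

    def test_cone_taper_matches_quasi_1d_closed_form(self, channel, fluid):
        # width doubling over a 720 um cone: mean EFS = 3 mu (u1 - u2) / L
        n = 721
        s = np.linspace(0.0, 720.0, n)
        width = 500.0 + (1000.0 - 500.0) * s / 720.0
        path = SpiralPath(
            s_um=s,
            radius_um=np.full(n, np.inf),
            theta_rad=np.zeros(n),
            width_um=width,
            area_um2=width * 130.0,
            in_cone=np.ones(n, dtype=bool),
        )
        prof = efs_profile(channel, fluid, path=path, curvature_model=False)
        q = fluid.flow_rate_m3_s
        du = q / (500e-6 * 130e-6) - q / (1000e-6 * 130e-6)
        expected_mean = -3 * fluid.viscosity_pa_s * du / 720e-6  # deceleration
        assert prof["efs_pa"].mean() == pytest.approx(expected_mean, rel=1e-3)

    def test_sign_flips_between_lesser_and_greater_curvature(self, summary):
        efs = summary.efs
        body = efs[~efs["in_cone"]]
        assert body["efs_inner_pa"].max() > 0 and body["efs_inner_pa"].min() < 0
        # the two curvature probes carry opposite signs station by station
        curv = body["efs_inner_pa"] - body["efs_taper_pa"]
        curv_outer = body["efs_outer_pa"] - body["efs_taper_pa"]
        assert np.allclose(curv, -curv_outer, atol=1e-12)

    def test_vanishing_area_rejected(self, channel, fluid):
        bad = straight_path()
        bad.area_um2[10] = 0.0
        with pytest.raises(ValueError):
            efs_profile(channel, fluid, path=bad)


class TestStressSummary:
    def test_maxima_orders_of_magnitude(self, summary):
        assert 1.0 < summary.fss_max_pa < 100.0
        assert 1.0 < summary.efs_max_pa < 100.0

    def test_halving_flow_decreases_both_maxima(self, channel, fluid, summary):
        half = stress_summary(channel, fluid.with_flow_ml_min(0.5))
        assert half.fss_max_pa < summary.fss_max_pa
        assert half.efs_max_pa < summary.efs_max_pa

    def test_secondary_flow_weaker_at_final_loop(self, summary):
        assert (
            summary.secondary_max_final_loop_m_s < summary.secondary_max_first_loop_m_s
        )

    def test_field_export_round_trip(self, summary, tmp_path):
        import json
        import pandas as pd

        summary.write(tmp_path)
        for name in ("u.csv", "vw.csv", "fss.csv", "efs.csv"):
            assert (tmp_path / name).exists()
        with open(tmp_path / "summary.json") as fh:
            payload = json.load(fh)
        assert payload["fss_max_pa"] == pytest.approx(summary.fss_max_pa)
        fss = pd.read_csv(tmp_path / "fss.csv")
        assert fss["fss_full_pa"].max() == pytest.approx(summary.fss_max_pa)
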
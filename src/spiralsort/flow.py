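"""Reduced-order laminar flow and hydrodynamic stress fields.

The sorter operates deep in the laminar regime (Re ~ 50), so the primary
flow in the rectangular section is the classical pressure-driven duct
profile, available as an exact double series (cosine across the width,
hyperbolic cosine across the height).  The pressure gradient is set from
the closed-form flux relation so that the cross-sectional integral of the
streamwise velocity equals the prescribed volumetric rate exactly.

Curvature adds a weak secondary circulation (a pair of counter-rotating
Dean vortices, mirror-antisymmetric about the mid-plane).  It is computed
here as the first-order perturbation of the primary flow: a streamfunction
on the cross-section driven by the vertical gradient of the centrifugal
source term, solved as a clamped-plate biharmonic problem by sparse finite
differences.

Two stress diagnostics are derived:

* **FSS** (fluid shear stress) — reported in two forms: the literal
  secondary-flow component ``mu * (dv/dz + dw/dy)``, and the full viscous
  shear magnitude including the primary-flow gradients.  Only the latter
  can reach the tens-of-pascals level observed at the top and bottom walls
  of this device (the secondary-flow component is ~0.1 Pa at these
  conditions), so the headline ``fss_max`` uses the full magnitude while
  the literal form is retained for audit.
* **EFS** (extensional flow stress) — ``3 mu du/ds`` along the spiral
  path.  The quasi-one-dimensional continuity term ``u(s) = Q/A(s)``
  captures the outlet-cone taper; on the curved body the dominant
  contribution comes from the rotation of the flow axis relative to the
  fixed laboratory frame, which projects the steep lateral (side-wall)
  gradient of the duct profile onto the streamwise axis:
  ``EFS = (3 mu / 2) sin(2 theta) du/dy`` near the lesser- and
  greater-curvature walls.  This term is positive on one curvature and
  negative on the other and peaks where the channel tangent makes 45
  degrees with the laboratory axis — reproducing both the magnitude and
  the sign pattern of the extensional stress in this device with no free
  parameters.  A config switch disables it.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import simpson

from .geometry import SpiralChannel, SpiralPath, build_path

__all__ = [
    "FluidState",
    "FlowField",
    "water_at_20c",
    "primary_flow",
    "secondary_flow",
    "fss_field",
    "efs_profile",
    "stress_summary",
    "StressSummary",
]

ML_PER_MIN = 1e-6 / 60.0  # m^3 s^-1 per mL min^-1

#: Literature shear-stress injury thresholds (Pa), for annotating stress
#: maps only — no validated damage model is implied.  Adherent cells
#: deform near 0.2 Pa and die above 0.5 Pa; suspended mammalian cells
#: tolerate far more, with lysis reported around 150-400 Pa.
INJURY_ANNOTATIONS_PA: dict[str, float | tuple[float, float]] = {
    "adherent_deformation": 0.2,
    "adherent_death": 0.5,
    "suspended_lysis_range": (150.0, 400.0),
}


@dataclass(frozen=True)
class FluidState:
    """Fluid properties and flow condition (SI units).

    ``flow_rate_m3_s`` is the *total* volumetric rate through the channel.
    The device is fed by two syringes driven together at 1 mL/min total by
    default; use :meth:`doubled` for the sensitivity case in which the
    printed rate is read as per-syringe.
    """

    density_kg_m3: float = 1000.0
    viscosity_pa_s: float = 1.003e-3
    flow_rate_m3_s: float = 1.0 * ML_PER_MIN
    temperature_c: float = 20.0  # annotation only

    def __post_init__(self) -> None:
        if self.density_kg_m3 <= 0 or self.viscosity_pa_s <= 0:
            raise ValueError("density and viscosity must be positive")
        if self.flow_rate_m3_s < 0:
            raise ValueError("flow rate must be nonnegative")

    @property
    def flow_rate_ml_min(self) -> float:
        return self.flow_rate_m3_s / ML_PER_MIN

    def with_flow_ml_min(self, q: float) -> "FluidState":
        return replace(self, flow_rate_m3_s=q * ML_PER_MIN)

    def doubled(self) -> "FluidState":
        return replace(self, flow_rate_m3_s=2.0 * self.flow_rate_m3_s)

    @classmethod
    def from_json(cls, text_or_path) -> "FluidState":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        known = {"density_kg_m3", "viscosity_pa_s", "flow_rate_ml_min", "temperature_c"}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown fluid config keys: {sorted(unknown)}")
        q = payload.pop("flow_rate_ml_min", 1.0)
        return cls(flow_rate_m3_s=q * ML_PER_MIN, **payload)


def water_at_20c(flow_ml_min: float = 1.0) -> FluidState:
    """Water-like buffer at 20 C at the stated sorting flow rate."""
    return FluidState(flow_rate_m3_s=flow_ml_min * ML_PER_MIN)


@dataclass
class FlowField:
    """Velocity components and metadata on a cross-section grid.

    ``u`` is streamwise, ``v`` lateral (inner wall at ``y = -W/2``, outer
    wall at ``+W/2``), ``w`` vertical.  Arrays are indexed ``[iz, iy]``.
    """

    y_m: np.ndarray
    z_m: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    channel: SpiralChannel
    fluid: FluidState
    dpdx_pa_m: float
    n_terms: int
    radius_m: float = math.inf  # curvature used for the secondary flow

    @property
    def mean_velocity(self) -> float:
        """Bulk velocity Q/A, m/s."""
        area = self.channel.area_um2 * 1e-12
        return self.fluid.flow_rate_m3_s / area

    def flux(self) -> float:
        """Numerical cross-sectional integral of u (m^3/s), Simpson rule."""
        return float(simpson(simpson(self.u, x=self.y_m, axis=1), x=self.z_m))

    def grad_u(self) -> tuple[np.ndarray, np.ndarray]:
        """Analytic (du/dy, du/dz) from the term-wise differentiated series."""
        return _series_grad(
            self.channel, self.fluid, self.y_m, self.z_m, self.dpdx_pa_m, self.n_terms
        )


def _series_sum(channel, fluid, y, z, dpdx, n_terms, deriv=None):
    """Evaluate the duct series (or one first derivative) on a grid."""
    a = 0.5 * channel.width_um * 1e-6
    b = 0.5 * channel.height_um * 1e-6
    mu = fluid.viscosity_pa_s
    i = 2.0 * np.arange(n_terms) + 1.0  # odd indices
    sgn = np.where(np.arange(n_terms) % 2 == 0, 1.0, -1.0)
    k = i * math.pi / (2.0 * a)
    pref = 16.0 * a * a * dpdx / (mu * math.pi**3)
    cosh_b = np.cosh(k * b)
    K = k[:, None, None]
    Z = z[None, :, None]
    Y = y[None, None, :]
    if deriv is None:
        term = (1.0 - np.cosh(K * Z) / cosh_b[:, None, None]) * np.cos(K * Y)
    elif deriv == "y":
        term = -(K) * (1.0 - np.cosh(K * Z) / cosh_b[:, None, None]) * np.sin(K * Y)
    elif deriv == "z":
        term = -(K) * (np.sinh(K * Z) / cosh_b[:, None, None]) * np.cos(K * Y)
    else:  # pragma: no cover
        raise ValueError(deriv)
    coeff = sgn / i**3
    return pref * np.tensordot(coeff, term, axes=(0, 0))


def _series_grad(channel, fluid, y, z, dpdx, n_terms):
    du_dy = _series_sum(channel, fluid, y, z, dpdx, n_terms, deriv="y")
    du_dz = _series_sum(channel, fluid, y, z, dpdx, n_terms, deriv="z")
    return du_dy, du_dz


def _dpdx_for_flux(channel: SpiralChannel, fluid: FluidState, n_terms: int) -> float:
    """Pressure gradient giving exactly the prescribed flux (closed form)."""
    a = 0.5 * channel.width_um * 1e-6
    b = 0.5 * channel.height_um * 1e-6
    mu = fluid.viscosity_pa_s
    i = 2.0 * np.arange(max(n_terms, 200)) + 1.0
    bracket = 1.0 - (192.0 * a / (math.pi**5 * b)) * np.sum(
        np.tanh(i * math.pi * b / (2.0 * a)) / i**5
    )
    q_per_dpdx = (4.0 * b * a**3 / (3.0 * mu)) * bracket
    return fluid.flow_rate_m3_s / q_per_dpdx


def primary_flow(
    channel: SpiralChannel,
    fluid: FluidState,
    resolution: int = 64,
    n_terms: int = 51,
) -> FlowField:
    """Exact series solution for the straight-duct base flow.

    ``resolution`` is the number of grid cells per direction (grid points
    include the walls, so the mid-lines of both walls fall on grid nodes for
    even resolutions).  ``n_terms`` counts odd series indices.  A
    convergence diagnostic compares the velocity field against a deeper
    truncation and raises if the drift exceeds 0.1 %.
    """
    if resolution < 16:
        raise ValueError("grid resolution must be at least 16x16")
    if n_terms < 11:
        raise ValueError("at least 11 odd series terms are required")
    a = 0.5 * channel.width_um * 1e-6
    b = 0.5 * channel.height_um * 1e-6
    y = np.linspace(-a, a, resolution + 1)
    z = np.linspace(-b, b, resolution + 1)
    if fluid.flow_rate_m3_s == 0.0:
        zeros = np.zeros((z.size, y.size))
        return FlowField(y, z, zeros, zeros.copy(), zeros.copy(), channel, fluid, 0.0, n_terms)
    dpdx = _dpdx_for_flux(channel, fluid, n_terms)
    u = _series_sum(channel, fluid, y, z, dpdx, n_terms)
    u_deep = _series_sum(channel, fluid, y, z, dpdx, n_terms + 16)
    drift = np.max(np.abs(u_deep - u)) / np.max(np.abs(u_deep))
    if drift > 1e-3:
        raise ArithmeticError(
            f"duct series not converged at {n_terms} terms (drift {drift:.2e})"
        )
    zeros = np.zeros_like(u)
    return FlowField(y, z, u, zeros, zeros.copy(), channel, fluid, dpdx, n_terms)


def _biharmonic_clamped(ny: int, nz: int, hy: float, hz: float) -> sp.csr_matrix:
    """Finite-difference biharmonic on the interior grid, clamped walls.

    Dirichlet psi = 0 on the boundary; the zero normal derivative is
    imposed through ghost-node reflection (psi_{-1} = psi_{1}), the
    standard second-order clamped-plate closure.
    """

    def d2(n, h):
        return sp.diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(n, n)) / h**2

    def d4(n, h):
        m = sp.diags([1.0, -4.0, 6.0, -4.0, 1.0], [-2, -1, 0, 1, 2], shape=(n, n)).tolil()
        m[0, 0] += 1.0  # ghost reflection at the wall
        m[n - 1, n - 1] += 1.0
        return (m / h**4).tocsr()

    iy = sp.identity(ny)
    iz = sp.identity(nz)
    return (
        sp.kron(iz, d4(ny, hy)) + 2.0 * sp.kron(d2(nz, hz), d2(ny, hy)) + sp.kron(d4(nz, hz), iy)
    ).tocsr()


def secondary_flow(
    base: FlowField,
    channel: SpiralChannel,
    fluid: FluidState,
    radius_m: float,
) -> FlowField:
    """First-order Dean circulation on the cross-section at local radius R.

    Solves ``mu * biharmonic(psi) = -(rho / R) d(u^2)/dz`` with no-slip
    (clamped) walls and returns a copy of the base field with ``v = dpsi/dz``
    and ``w = -dpsi/dy`` populated.  The source is odd in z, so the solution
    is a mirror-antisymmetric pair of counter-rotating cells.
    """
    if radius_m <= 0:
        raise ValueError("local radius must be positive")
    if not math.isfinite(radius_m) or base.fluid.flow_rate_m3_s == 0.0:
        return replace(base, v=np.zeros_like(base.u), w=np.zeros_like(base.u), radius_m=radius_m)
    y, z, u = base.y_m, base.z_m, base.u
    hy = y[1] - y[0]
    hz = z[1] - z[0]
    ny_i, nz_i = y.size - 2, z.size - 2
    _, du_dz = base.grad_u()
    source = -(fluid.density_kg_m3 / (fluid.viscosity_pa_s * radius_m)) * (2.0 * u * du_dz)
    f = source[1:-1, 1:-1].ravel()
    A = _biharmonic_clamped(ny_i, nz_i, hy, hz)
    psi_i = spla.spsolve(A, f)
    resid = np.linalg.norm(A @ psi_i - f) / max(np.linalg.norm(f), 1e-300)
    if resid > 1e-8:
        raise ArithmeticError(f"secondary-flow solve did not converge (residual {resid:.2e})")
    psi = np.zeros_like(u)
    psi[1:-1, 1:-1] = psi_i.reshape(nz_i, ny_i)
    v = np.gradient(psi, z, axis=0, edge_order=2)
    w = -np.gradient(psi, y, axis=1, edge_order=2)
    v[0, :] = v[-1, :] = w[0, :] = w[-1, :] = 0.0
    v[:, 0] = v[:, -1] = w[:, 0] = w[:, -1] = 0.0
    return replace(base, v=v, w=w, radius_m=radius_m)


@dataclass
class FSSFields:
    """Fluid-shear-stress grids (Pa) and their maxima."""

    literal: np.ndarray  # mu (dv/dz + dw/dy): the secondary-flow component
    full: np.ndarray  # full viscous shear magnitude incl. primary gradients
    y_m: np.ndarray
    z_m: np.ndarray

    def _argmax(self, grid):
        iz, iy = np.unravel_index(np.argmax(grid), grid.shape)
        return float(self.y_m[iy]), float(self.z_m[iz])

    @property
    def literal_max(self) -> float:
        return float(np.max(np.abs(self.literal)))

    @property
    def full_max(self) -> float:
        return float(np.max(self.full))

    @property
    def full_argmax_m(self) -> tuple[float, float]:
        return self._argmax(self.full)


def fss_field(field: FlowField, fluid: FluidState) -> FSSFields:
    """Both readings of the shear stress on the cross-section.

    The literal component uses second-order finite differences of the
    secondary velocities (one-sided at walls); the full magnitude uses the
    analytic primary-flow gradients so the wall maxima are not degraded by
    differencing error.
    """
    y, z = field.y_m, field.z_m
    if y.size < 10 or z.size < 10:
        raise ValueError("grid too coarse for finite differences (need >= 8 interior nodes)")
    mu = fluid.viscosity_pa_s
    dv_dz = np.gradient(field.v, z, axis=0, edge_order=2)
    dw_dy = np.gradient(field.w, y, axis=1, edge_order=2)
    literal = mu * (dv_dz + dw_dy)
    du_dy, du_dz = field.grad_u()
    full = np.sqrt((mu * du_dy) ** 2 + (mu * du_dz) ** 2 + literal**2)
    return FSSFields(literal=literal, full=full, y_m=y, z_m=z)


def side_wall_gradient(field: FlowField) -> float:
    """Peak lateral velocity gradient |du/dy| over the section, 1/s.

    The maximum sits on the side (lesser/greater-curvature) walls at
    mid-height; it drives the curvature term of the extensional stress.
    """
    du_dy, _ = field.grad_u()
    return float(np.max(np.abs(du_dy)))


def efs_profile(
    channel: SpiralChannel,
    fluid: FluidState,
    path: SpiralPath | None = None,
    curvature_model: bool = True,
    n_stations: int = 1200,
    resolution: int = 64,
    n_terms: int = 51,
    base: FlowField | None = None,
) -> pd.DataFrame:
    """Extensional stress along the spiral path (sign: extension positive).

    Columns: ``s_um``, ``in_cone``, ``efs_taper_pa`` (quasi-1D continuity
    term from area change), ``efs_inner_pa`` / ``efs_outer_pa`` (taper plus
    the curvature term sampled at the lesser/greater-curvature walls) and
    ``efs_pa`` (the signed value of larger magnitude of the two probes).

    With ``curvature_model=False`` and a constant-area path the profile is
    identically zero.
    """
    if path is None:
        path = build_path(channel, n_stations=n_stations)
    if len(path) < 100:
        raise ValueError("path must carry at least 100 stations")
    if np.any(path.area_um2 <= 0):
        raise ValueError("cross-sectional area vanishes along the path")
    mu = fluid.viscosity_pa_s
    s_m = path.s_um * 1e-6
    u_mean = fluid.flow_rate_m3_s / (path.area_um2 * 1e-12)
    taper = 3.0 * mu * np.gradient(u_mean, s_m, edge_order=2)
    if curvature_model and fluid.flow_rate_m3_s > 0.0:
        if base is None:
            base = primary_flow(channel, fluid, resolution=resolution, n_terms=n_terms)
        g_side = side_wall_gradient(base)
        curved = np.isfinite(path.radius_um)
        curv = np.where(curved, 1.5 * mu * np.sin(2.0 * path.theta_rad) * g_side, 0.0)
    else:
        curv = np.zeros_like(taper)
    inner = taper + curv
    outer = taper - curv
    efs = np.where(np.abs(inner) >= np.abs(outer), inner, outer)
    return pd.DataFrame(
        {
            "s_um": path.s_um,
            "in_cone": path.in_cone,
            "efs_taper_pa": taper,
            "efs_inner_pa": inner,
            "efs_outer_pa": outer,
            "efs_pa": efs,
        }
    )


@dataclass
class StressSummary:
    """Headline stress maxima at one flow condition, plus diagnostics."""

    fss_max_pa: float
    fss_max_location_um: tuple[float, float]  # (y from centre, z), um
    fss_literal_max_pa: float
    efs_max_pa: float
    efs_max_location_s_um: float
    secondary_max_first_loop_m_s: float
    secondary_max_final_loop_m_s: float
    radius_first_loop_um: float
    radius_final_loop_um: float
    mean_velocity_m_s: float
    flow_rate_ml_min: float
    resolution: int
    field: FlowField
    fss: FSSFields
    efs: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "fss_max_pa": self.fss_max_pa,
            "fss_max_location_um": list(self.fss_max_location_um),
            "fss_literal_max_pa": self.fss_literal_max_pa,
            "efs_max_pa": self.efs_max_pa,
            "efs_max_location_s_um": self.efs_max_location_s_um,
            "secondary_max_first_loop_m_s": self.secondary_max_first_loop_m_s,
            "secondary_max_final_loop_m_s": self.secondary_max_final_loop_m_s,
            "radius_first_loop_um": self.radius_first_loop_um,
            "radius_final_loop_um": self.radius_final_loop_um,
            "mean_velocity_m_s": self.mean_velocity_m_s,
            "flow_rate_ml_min": self.flow_rate_ml_min,
            "resolution": self.resolution,
        }

    def write(self, out_dir: str) -> None:
        """Write long-format field grids and a JSON summary to a directory."""
        os.makedirs(out_dir, exist_ok=True)
        y_um = self.field.y_m * 1e6
        z_um = self.field.z_m * 1e6
        yy, zz = np.meshgrid(y_um, z_um)
        pd.DataFrame(
            {"y_um": yy.ravel(), "z_um": zz.ravel(), "u_m_s": self.field.u.ravel()}
        ).to_csv(os.path.join(out_dir, "u.csv"), index=False)
        pd.DataFrame(
            {
                "y_um": yy.ravel(),
                "z_um": zz.ravel(),
                "v_m_s": self.field.v.ravel(),
                "w_m_s": self.field.w.ravel(),
            }
        ).to_csv(os.path.join(out_dir, "vw.csv"), index=False)
        pd.DataFrame(
            {
                "y_um": yy.ravel(),
                "z_um": zz.ravel(),
                "fss_full_pa": self.fss.full.ravel(),
                "fss_literal_pa": self.fss.literal.ravel(),
            }
        ).to_csv(os.path.join(out_dir, "fss.csv"), index=False)
        self.efs.to_csv(os.path.join(out_dir, "efs.csv"), index=False)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def stress_summary(
    channel: SpiralChannel,
    fluid: FluidState,
    resolution: int = 64,
    n_terms: int = 51,
    n_stations: int = 1200,
) -> StressSummary:
    """Run the full reduced-order chain at one flow condition.

    The secondary flow is evaluated at both the first and the final loop
    (its strength differs because the Dean number falls with radius); the
    shear field uses the first-loop circulation, where the secondary
    component is strongest.
    """
    base = primary_flow(channel, fluid, resolution=resolution, n_terms=n_terms)
    r_first = channel.loop_mean_radius_um(0) * 1e-6
    r_final = channel.loop_mean_radius_um(channel.n_loops - 1) * 1e-6
    with_dean_first = secondary_flow(base, channel, fluid, r_first)
    with_dean_final = secondary_flow(base, channel, fluid, r_final)
    fss = fss_field(with_dean_first, fluid)
    efs = efs_profile(
        channel, fluid, n_stations=n_stations, base=base, curvature_model=True
    )
    y_loc, z_loc = fss.full_argmax_m
    i_max = int(np.argmax(np.abs(efs["efs_pa"].to_numpy())))
    sec_max = lambda fld: float(np.max(np.hypot(fld.v, fld.w)))
    return StressSummary(
        fss_max_pa=fss.full_max,
        fss_max_location_um=(y_loc * 1e6, z_loc * 1e6),
        fss_literal_max_pa=fss.literal_max,
        efs_max_pa=float(np.abs(efs["efs_pa"]).max()),
        efs_max_location_s_um=float(efs["s_um"].iloc[i_max]),
        secondary_max_first_loop_m_s=sec_max(with_dean_first),
        secondary_max_final_loop_m_s=sec_max(with_dean_final),
        radius_first_loop_um=r_first * 1e6,
        radius_final_loop_um=r_final * 1e6,
        mean_velocity_m_s=base.mean_velocity,
        flow_rate_ml_min=fluid.flow_rate_ml_min,
        resolution=resolution,
        field=with_dean_first,
        fss=fss,
        efs=efs,
    )
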
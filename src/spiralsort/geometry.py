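"""Archimedean spiral microchannel geometry.

The device modelled here is a five-loop Archimedean spiral of rectangular
cross-section (wide and shallow: 500 x 130 um as built), terminated by a
short conical exit channel that feeds a manifold of ten outlets.  The
spiral radius grows linearly with winding angle, ``r(theta) = r0 +
(pitch / 2 pi) * theta``, where the pitch is the channel width plus the
wall-to-wall interspace between adjacent loops.

Coordinate conventions used throughout the package:

* lateral position ``x`` is a fraction of the width ``W`` measured from the
  inner (lesser-curvature) wall, ``x in [0, 1]``;
* vertical position ``z in [-H/2, +H/2]``;
* arc length ``s`` is measured from the inlet, in micrometres.

The innermost radius is not a printed device dimension; it defaults to
2500 um and is configurable, and downstream Dean-number results scale as
``R**-0.5``, so sensitivity to it is mild but reported by the flow module.
The spiral is taken to flow outward (inlet at the centre); this too is a
configurable assumption.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpiralChannel",
    "SpiralPath",
    "build_default_device",
    "radius_at",
    "outlet_bin",
    "build_path",
]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def roman_outlet(index: int) -> str:
    """Roman-numeral label for a 1-based outlet index."""
    return _ROMAN[index - 1] if 1 <= index <= len(_ROMAN) else str(index)


@dataclass(frozen=True)
class SpiralChannel:
    """Geometry of the spiral sorter.

    All lengths in micrometres.  ``outlet_widths_um`` optionally gives the
    lateral width claimed by each outlet; it must sum to ``width_um``.  The
    default is equal widths (the built device has asymmetric outlets of
    unpublished dimensions).
    """

    width_um: float = 500.0
    height_um: float = 130.0
    n_loops: int = 5
    interspace_um: float = 500.0
    inner_radius_um: float = 2500.0
    cone_um: float = 720.0
    cone_exit_width_um: float = 250.0
    n_outlets: int = 10
    outlet_widths_um: tuple[float, ...] | None = None
    outward_flow: bool = True

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.height_um > 0):
            raise ValueError("channel cross-section must have positive extent")
        if self.width_um < self.height_um:
            raise ValueError("expected a wide rectangular section (W >= H)")
        if int(self.n_loops) != self.n_loops or self.n_loops < 1:
            raise ValueError("n_loops must be a positive integer")
        if self.interspace_um < 0:
            raise ValueError("loop interspace must be nonnegative")
        if self.inner_radius_um <= 0:
            raise ValueError("inner start radius must be positive")
        if self.cone_um <= 0 or self.cone_exit_width_um <= 0:
            raise ValueError("outlet cone dimensions must be positive")
        if int(self.n_outlets) != self.n_outlets or self.n_outlets < 1:
            raise ValueError("n_outlets must be a positive integer")
        if self.outlet_widths_um is not None:
            w = tuple(float(v) for v in self.outlet_widths_um)
            if len(w) != self.n_outlets:
                raise ValueError("outlet_widths_um must have n_outlets entries")
            if any(v <= 0 for v in w):
                raise ValueError("outlet widths must be positive")
            if not math.isclose(sum(w), self.width_um, rel_tol=1e-9):
                raise ValueError("outlet widths must sum to the channel width")
            object.__setattr__(self, "outlet_widths_um", w)

    # -- derived scalar geometry ------------------------------------------

    @property
    def area_um2(self) -> float:
        """Cross-sectional area W*H of the spiral body, um^2."""
        return self.width_um * self.height_um

    @property
    def hydraulic_diameter_um(self) -> float:
        """D_h = 2WH/(W+H) for the rectangular section, um."""
        return 2.0 * self.width_um * self.height_um / (self.width_um + self.height_um)

    @property
    def pitch_um(self) -> float:
        """Radial advance per loop: channel width + wall interspace."""
        return self.width_um + self.interspace_um

    @property
    def outer_radius_um(self) -> float:
        return self.inner_radius_um + self.pitch_um * self.n_loops

    def loop_mean_radius_um(self, k: int) -> float:
        """Mean centreline radius of loop ``k`` (0-based)."""
        if not 0 <= k < self.n_loops:
            raise ValueError(f"loop index {k} outside 0..{self.n_loops - 1}")
        return self.inner_radius_um + self.pitch_um * (k + 0.5)

    # -- JSON config ------------------------------------------------------

    _JSON_KEYS = {
        "width_um",
        "height_um",
        "n_loops",
        "interspace_um",
        "inner_radius_um",
        "cone_um",
        "cone_exit_width_um",
        "n_outlets",
        "outlet_widths_um",
        "outward_flow",
    }

    @classmethod
    def from_json(cls, text_or_path) -> "SpiralChannel":
        """Load a device config from a JSON string or file path.

        Validation is strict: unknown keys are rejected so that a typo in a
        config file fails loudly rather than silently using a default.
        """
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        if not isinstance(payload, dict):
            raise ValueError("device config must be a JSON object")
        unknown = set(payload) - cls._JSON_KEYS
        if unknown:
            raise ValueError(f"unknown device config keys: {sorted(unknown)}")
        if "outlet_widths_um" in payload and payload["outlet_widths_um"] is not None:
            payload["outlet_widths_um"] = tuple(payload["outlet_widths_um"])
        return cls(**payload)

    def to_json(self) -> str:
        payload = {
            "width_um": self.width_um,
            "height_um": self.height_um,
            "n_loops": self.n_loops,
            "interspace_um": self.interspace_um,
            "inner_radius_um": self.inner_radius_um,
            "cone_um": self.cone_um,
            "cone_exit_width_um": self.cone_exit_width_um,
            "n_outlets": self.n_outlets,
            "outlet_widths_um": list(self.outlet_widths_um)
            if self.outlet_widths_um
            else None,
            "outward_flow": self.outward_flow,
        }
        return json.dumps(payload, indent=2)


def build_default_device() -> SpiralChannel:
    """The as-built device: 500 x 130 um section, 5 loops, 500 um interspace,
    720 um conical exit, 10 outlets."""
    return SpiralChannel()


@dataclass(frozen=True)
class SpiralPath:
    """Discretised centreline of the spiral body plus the outlet cone.

    Arrays are all the same length.  ``radius_um`` is ``inf`` on the
    (straight) cone stations.  ``theta_rad`` is the winding angle of the
    local tangent relative to the fixed laboratory frame; it keeps growing
    linearly through the cone (the cone leaves the last loop tangentially,
    its own direction is frozen but the angle is only used where curvature
    is finite).  ``area_um2`` is constant along the spiral body and tapers
    linearly across the cone.
    """

    s_um: np.ndarray
    radius_um: np.ndarray
    theta_rad: np.ndarray
    width_um: np.ndarray
    area_um2: np.ndarray
    in_cone: np.ndarray  # boolean mask

    def __len__(self) -> int:
        return self.s_um.size


def _spiral_table(channel: SpiralChannel, n: int = 8192):
    """Dense (theta, r, s) table for the spiral body by polyline integration."""
    theta_end = 2.0 * math.pi * channel.n_loops
    theta = np.linspace(0.0, theta_end, n)
    b = channel.pitch_um / (2.0 * math.pi)
    r = channel.inner_radius_um + b * theta
    # ds = sqrt(r^2 + (dr/dtheta)^2) dtheta for an Archimedean spiral
    ds_dtheta = np.sqrt(r * r + b * b)
    s = np.concatenate(
        ([0.0], np.cumsum(0.5 * (ds_dtheta[1:] + ds_dtheta[:-1]) * np.diff(theta)))
    )
    return theta, r, s


def spiral_arc_length_um(channel: SpiralChannel) -> float:
    """Total arc length of the spiral body (excluding the cone), um."""
    return float(_spiral_table(channel)[2][-1])


def radius_at(channel: SpiralChannel, s_um: float) -> float:
    """Local centreline radius of curvature at arc position ``s_um``.

    Monotone nondecreasing in ``s`` for the default outward-flowing spiral;
    with ``outward_flow=False`` the radius decreases from the outermost loop
    inward.  Raises if ``s`` lies outside the spiral body.
    """
    _, r, s = _spiral_table(channel)
    total = s[-1]
    if not 0.0 <= s_um <= total:
        raise ValueError(f"arc position {s_um} um outside [0, {total:.1f}] um")
    if not channel.outward_flow:
        s_um = total - s_um
    return float(np.interp(s_um, s, r))


def outlet_bin(channel: SpiralChannel, x) -> int | np.ndarray:
    """Map a lateral position (fraction of W, 0 = inner wall) to an outlet.

    Outlets are numbered 1..n_outlets from the inner wall.  Bins default to
    equal widths; configured widths are respected.  Order-preserving:
    x1 < x2 implies bin(x1) <= bin(x2).
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any((x_arr < 0.0) | (x_arr > 1.0)):
        raise ValueError("lateral position must lie in [0, 1]")
    if channel.outlet_widths_um is None:
        edges = np.linspace(0.0, 1.0, channel.n_outlets + 1)[1:-1]
    else:
        edges = np.cumsum(channel.outlet_widths_um)[:-1] / channel.width_um
    bins = np.searchsorted(edges, x_arr, side="right") + 1
    if np.isscalar(x) or x_arr.ndim == 0:
        return int(bins)
    return bins.astype(int)


def build_path(
    channel: SpiralChannel,
    n_stations: int = 1200,
    include_cone: bool = True,
) -> SpiralPath:
    """Discretise the spiral centreline (and optionally the outlet cone).

    Stations are equally spaced in arc length.  Within the cone the channel
    is treated as straight (``radius_um = inf``) and its width tapers
    linearly from ``width_um`` to ``cone_exit_width_um``; area varies only
    there, as required for a constant-section spiral body.
    """
    if n_stations < 100:
        raise ValueError("path must be discretised with at least 100 stations")
    theta_t, r_t, s_t = _spiral_table(channel)
    body_len = s_t[-1]
    total = body_len + (channel.cone_um if include_cone else 0.0)
    s = np.linspace(0.0, total, n_stations)
    in_cone = s > body_len
    s_body = np.where(channel.outward_flow, s, body_len - s)
    radius = np.interp(np.clip(s_body, 0.0, body_len), s_t, r_t)
    theta = np.interp(np.clip(s, 0.0, body_len), s_t, theta_t)
    radius = np.where(in_cone, np.inf, radius)
    frac = np.clip((s - body_len) / channel.cone_um, 0.0, 1.0)
    width = np.where(
        in_cone,
        channel.width_um + (channel.cone_exit_width_um - channel.width_um) * frac,
        channel.width_um,
    )
    area = width * channel.height_um
    if np.any(area <= 0):
        raise ValueError("cross-sectional area must stay positive along the path")
    return SpiralPath(
        s_um=s,
        radius_um=radius,
        theta_rad=theta,
        width_um=width,
        area_um2=area,
        in_cone=in_cone,
    )
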
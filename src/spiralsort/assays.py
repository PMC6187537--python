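"""Quantification of cell viability after sorting.

Implements the assay arithmetic used to grade shear-stress damage to
sorted cells:

* **CMI** (cell morphology index) — width over length of a cell outline;
  1 for a round viable cell, between 0.22 (severe) and 0.625 (mild) for
  deformed cells, and *unmeasurable* (reported as 0 with an explicit flag)
  for necrotic wreckage.
* **Trypan-blue exclusion** — membrane-compromised cells stain blue;
  viability is the percentage of unstained cells.
* **Hemocytometer concentration** — standard chamber arithmetic,
  concentration = (count / squares) * dilution * 1e4 per mL.
* **Leaky-DNA spectrophotometry** — dsDNA [ug/mL] = 50 * OD260 * dilution
  (supernatant DNA is purified and diluted 1:100 before reading).
* **CV, fold-change and percent cell loss** for before/after comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellMorphometry",
    "DNAReading",
    "CountPanel",
    "AttritionSummary",
    "cmi",
    "cmi_from_contour",
    "hemocytometer_concentration",
    "trypan_viability",
    "dsdna_concentration",
    "coefficient_of_variation",
    "attrition_summary",
    "cmi_table",
    "assay_report",
]

CELL_STATES = ("viable", "deformed", "necrotic", "debris")
UNMEASURABLE_STATES = ("necrotic", "debris")


@dataclass(frozen=True)
class CellMorphometry:
    """One measured cell: extents in um, injury state, trypan result."""

    cell_id: str
    width_um: float | None
    length_um: float | None
    state: str  # viable | deformed | necrotic | debris
    trypan: str  # positive | negative

    def __post_init__(self) -> None:
        if self.state not in CELL_STATES:
            raise ValueError(f"unknown cell state {self.state!r}")
        if self.trypan not in ("positive", "negative"):
            raise ValueError("trypan result must be positive or negative")
        if self.state not in UNMEASURABLE_STATES:
            if self.width_um is None or self.length_um is None:
                raise ValueError("measurable cells need width and length")

    @property
    def measurable(self) -> bool:
        return self.state not in UNMEASURABLE_STATES

    def cmi(self) -> tuple[float, bool]:
        """(value, unmeasured flag); necrotic wreckage reports (0, True)."""
        if not self.measurable:
            return 0.0, True
        return cmi(self.width_um, self.length_um), False


@dataclass(frozen=True)
class DNAReading:
    """One OD260 reading of purified supernatant DNA."""

    od260: float
    dilution_factor: float = 100.0

    def __post_init__(self) -> None:
        if self.od260 < 0:
            raise ValueError("absorbance cannot be negative")
        if self.dilution_factor <= 0:
            raise ValueError("dilution factor must be positive")

    @property
    def dsdna_ug_ml(self) -> float:
        return dsdna_concentration(self.od260, self.dilution_factor)


@dataclass(frozen=True)
class CountPanel:
    """Trypan + hemocytometer counts for one sample."""

    total: int
    trypan_negative: int
    squares: int = 4
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.total < 0 or not 0 <= self.trypan_negative <= self.total:
            raise ValueError("need 0 <= trypan_negative <= total")
        if self.squares < 1:
            raise ValueError("at least one chamber square must be counted")
        if self.dilution <= 0:
            raise ValueError("dilution must be positive")

    @property
    def concentration_cells_ml(self) -> float:
        return hemocytometer_concentration(self.total, self.squares, self.dilution)

    @property
    def viability_percent(self) -> float:
        return trypan_viability(self.trypan_negative, self.total)


def cmi(width_um: float, length_um: float) -> float:
    """Cell morphology index: width / length, in (0, 1].

    Micrograph orientation is arbitrary, so if the extents arrive with
    width > length they are swapped (with a warning) rather than rejected.
    Use the record-level :meth:`CellMorphometry.cmi` for necrotic cells,
    which are unmeasurable by definition.
    """
    if width_um <= 0 or length_um <= 0:
        raise ValueError("cell extents must be positive")
    if width_um > length_um:
        warnings.warn(
            "width exceeded length; extents swapped (orientation is arbitrary)",
            stacklevel=2,
        )
        width_um, length_um = length_um, width_um
    return width_um / length_um


def cmi_from_contour(points_um) -> tuple[float, float, float]:
    """(width, length, cmi) of a closed planar cell outline.

    Length is the maximal chord between outline points; width is the
    maximal extent perpendicular to that chord.  Rotation- and
    translation-invariant by construction (no axis-aligned bounding box).
    """
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
        raise ValueError("contour needs at least 8 (x, y) points")
    centred = pts - pts.mean(axis=0)
    # collinearity check via the smaller singular value
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("contour points are collinear (degenerate outline)")
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    length = math.sqrt(d2[i, j])
    axis = (pts[j] - pts[i]) / length
    normal = np.array([-axis[1], axis[0]])
    proj = centred @ normal
    width = float(proj.max() - proj.min())
    return width, length, cmi(width, length)


def hemocytometer_concentration(count: float, squares: int, dilution: float) -> float:
    """Cells per mL from a chamber count.

    Standard chamber arithmetic: each large square holds 1e-4 mL, so
    concentration = (count / squares) * dilution * 1e4.
    """
    if squares < 1:
        raise ValueError("at least one square must be counted")
    if count < 0:
        raise ValueError("count cannot be negative")
    if dilution <= 0:
        raise ValueError("dilution must be positive")
    return (count / squares) * dilution * 1.0e4


def trypan_viability(trypan_negative: float, total: float) -> float:
    """Percent viable = 100 * unstained / total, in [0, 100]."""
    if total <= 0:
        raise ValueError("total count must be positive")
    if not 0 <= trypan_negative <= total:
        raise ValueError("need 0 <= trypan_negative <= total")
    return 100.0 * trypan_negative / total


def dsdna_concentration(od260: float, dilution_factor: float = 100.0) -> float:
    """dsDNA [ug/mL] = 50 ug/mL * OD260 * dilution factor (exact)."""
    if od260 < 0:
        raise ValueError("absorbance cannot be negative")
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be positive")
    return 50.0 * od260 * dilution_factor


def coefficient_of_variation(
    values=None, mean: float | None = None, sd: float | None = None
) -> float:
    """CV in percent, either from raw replicates or a printed mean +/- sd.

    From raw values the sample standard deviation (n-1 denominator) is
    used; a printed summary is taken verbatim.  Scale-invariant.
    """
    if values is not None:
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError("need at least two replicates for a CV")
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
    if mean is None or sd is None:
        raise ValueError("provide raw values or both mean and sd")
    if mean <= 0:
        raise ValueError("CV is defined only for a positive mean")
    return 100.0 * sd / mean


@dataclass(frozen=True)
class AttritionSummary:
    """Before/after comparison of a paired metric."""

    before: float
    after: float
    percent_lost: float
    percent_survived: float
    fold_change: float


def attrition_summary(before: float, after: float) -> AttritionSummary:
    """Percent lost 100*(before-after)/before and after/before fold change.

    Used both for cell concentrations (percent vanished in the device) and
    paired assay means (e.g. the roughly twofold DNA-leakage increase).
    """
    if before <= 0:
        raise ValueError("the reference (before) value must be positive")
    if after < 0:
        raise ValueError("the after value cannot be negative")
    lost = 100.0 * (before - after) / before
    return AttritionSummary(
        before=before,
        after=after,
        percent_lost=lost,
        percent_survived=100.0 - lost,
        fold_change=after / before,
    )


# -- population-level helpers -------------------------------------------------


def cmi_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Add ``cmi`` and ``cmi_unmeasured`` columns to a cell table.

    Expects columns ``width_um, length_um, state``.  Necrotic/debris rows
    get value 0 with the unmeasured flag set — the two always co-occur so
    that downstream means can exclude wreckage exactly.
    """
    out = cells.copy()
    unmeasured = out["state"].isin(UNMEASURABLE_STATES)
    w = out["width_um"].to_numpy(dtype=float)
    ln = out["length_um"].to_numpy(dtype=float)
    measurable = ~unmeasured.to_numpy()
    if np.any((w[measurable] <= 0) | (ln[measurable] <= 0)):
        raise ValueError("measurable cells must have positive extents")
    lo = np.minimum(w, ln)
    hi = np.maximum(w, ln)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = lo / hi
    out["cmi"] = np.where(unmeasured, 0.0, ratio)
    out["cmi_unmeasured"] = unmeasured
    return out


def assay_report(cells: pd.DataFrame, assays: pd.DataFrame) -> dict:
    """Full viability report from a cell table and an assay table.

    ``cells`` columns: cell_id, width_um, length_um, state, trypan.
    ``assays`` columns: sample_id, arm (before|after), od260, dilution,
    count, squares, sample_dilution.

    Returns a dict with trypan viability, per-arm concentrations and dsDNA
    mean +/- sd with CV, the DNA fold change and the percent of cells lost
    between arms, and a per-state CMI summary (unmeasured records excluded
    from means but tallied).
    """
    cells = cmi_table(cells)
    report: dict = {}

    total = len(cells)
    negative = int((cells["trypan"] == "negative").sum())
    report["trypan_viability_percent"] = trypan_viability(negative, total)

    by_state = {}
    for state, grp in cells.groupby("state"):
        measurable = grp[~grp["cmi_unmeasured"]]
        by_state[state] = {
            "n": int(len(grp)),
            "cmi_mean": float(measurable["cmi"].mean()) if len(measurable) else None,
            "n_unmeasured": int(grp["cmi_unmeasured"].sum()),
        }
    report["cmi_by_state"] = by_state

    arms = {}
    for arm, grp in assays.groupby("arm"):
        dsdna = 50.0 * grp["od260"].to_numpy(dtype=float) * grp["dilution"].to_numpy(
            dtype=float
        )
        conc = np.array(
            [
                hemocytometer_concentration(c, s, d)
                for c, s, d in zip(grp["count"], grp["squares"], grp["sample_dilution"])
            ]
        )
        arms[arm] = {
            "n_replicates": int(len(grp)),
            "dsdna_mean_ug_ml": float(dsdna.mean()),
            "dsdna_sd_ug_ml": float(dsdna.std(ddof=1)) if len(dsdna) > 1 else 0.0,
            "dsdna_cv_percent": coefficient_of_variation(dsdna)
            if len(dsdna) > 1
            else 0.0,
            "concentration_cells_ml": float(conc.mean()),
        }
    report["arms"] = arms

    if {"before", "after"} <= set(arms):
        cell_att = attrition_summary(
            arms["before"]["concentration_cells_ml"],
            arms["after"]["concentration_cells_ml"],
        )
        dna_att = attrition_summary(
            arms["before"]["dsdna_mean_ug_ml"], arms["after"]["dsdna_mean_ug_ml"]
        )
        report["percent_cells_lost"] = cell_att.percent_lost
        report["dna_fold_change"] = dna_att.fold_change
    return report
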
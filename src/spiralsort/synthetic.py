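"""Synthetic cell populations and assay readouts with known ground truth.

The generator emulates the statistical structure of a dissociated
mast-cell-tumour suspension run through the sorter:

* a two-component lognormal size mixture — a major population of
  terminally differentiated cells spanning roughly 10-25 um and a minor
  sub-7 um fraction (putative stem-like cells);
* a latent injury state per cell (viable / deformed / necrotic) with a
  configurable necrosis fraction; viable cells are round (CMI = 1),
  deformed cells draw a CMI uniformly from the configured deformation
  range with their length preserved, necrotic cells are unmeasurable
  wreckage and always trypan-positive;
* hemocytometer counts as binomial thinning of the suspension into the
  counting chamber;
* DNA release from lysed (necrotic) cells into the supernatant on top of
  a baseline (trypsinisation itself releases DNA), read back through the
  spectrophotometric conversion with multiplicative lognormal noise.

With noise off and exact counting the assay pipeline applied to generated
data returns the configured parameters exactly (closed loop); the
parameter-recovery harness quantifies how well the noisy pipeline does.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .assays import (
    attrition_summary,
    cmi_table,
    coefficient_of_variation,
    hemocytometer_concentration,
)

__all__ = [
    "GeneratorConfig",
    "CellPopulation",
    "AssayTables",
    "RecoveryResult",
    "generate_population",
    "simulate_assays",
    "recover_ground_truth",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Size mixture: lognormal components parameterised by arithmetic mean
    and sd in um.  ``necrosis_fraction`` is the probability a cell lyses in
    the device (it then vanishes from the after-sorting counts and dumps
    ``dna_release_ug_per_cell`` into the supernatant).
    ``deformation_fraction`` applies to the surviving, non-necrotic cells.
    ``od_noise_sigma`` is the log-sd of the multiplicative measurement
    noise on OD260 (a value of 0.17 reproduces a replicate CV of ~17 %).
    ``dna_release_ug_per_cell`` defaults to the value implied by a 40 %
    lysis event raising supernatant DNA from 5200 to 12470 ug/mL at
    4e4 cells/mL.  ``exact_counts`` switches every stochastic readout to
    its expectation (used for closed-loop calibration checks).
    """

    n_cells: int = 500
    major_mean_um: float = 16.0
    major_sd_um: float = 3.5
    minor_mean_um: float = 5.5
    minor_sd_um: float = 0.8
    minor_weight: float = 0.15
    necrosis_fraction: float = 0.4
    deformation_fraction: float = 0.3
    membrane_damage_prob: float = 0.3
    deformed_cmi_range: tuple[float, float] = (0.22, 0.625)
    conc_before_cells_per_ml: float = 4.0e4
    suspension_volume_ml: float | None = None  # default: n_cells / conc_before
    baseline_dsdna_ug_ml: float = 5200.0
    dna_release_ug_per_cell: float = 0.4544
    od_dilution_factor: float = 100.0
    od_noise_sigma: float = 0.17
    n_replicates: int = 5
    hemo_squares: int = 25
    hemo_dilution: float = 1.0
    exact_counts: bool = False
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        for name in ("minor_weight", "necrosis_fraction", "deformation_fraction",
                     "membrane_damage_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.deformed_cmi_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("deformed CMI range must satisfy 0 < lo <= hi <= 1")
        if min(self.major_mean_um, self.minor_mean_um) <= 0:
            raise ValueError("component means must be positive")
        if min(self.major_sd_um, self.minor_sd_um) <= 0:
            raise ValueError("component sds must be positive")
        if self.conc_before_cells_per_ml <= 0:
            raise ValueError("suspension concentration must be positive")
        if self.baseline_dsdna_ug_ml < 0 or self.dna_release_ug_per_cell < 0:
            raise ValueError("DNA quantities cannot be negative")
        if self.od_noise_sigma < 0:
            raise ValueError("noise sigma cannot be negative")
        if self.n_replicates < 1 or self.hemo_squares < 1:
            raise ValueError("need at least one replicate and one square")

    @property
    def volume_ml(self) -> float:
        if self.suspension_volume_ml is not None:
            return self.suspension_volume_ml
        return self.n_cells / self.conc_before_cells_per_ml

    @property
    def effective_conc_before(self) -> float:
        """Cells per mL actually implied by n_cells and the volume."""
        return self.n_cells / self.volume_ml

    def to_json(self) -> str:
        payload = asdict(self)
        payload["deformed_cmi_range"] = list(self.deformed_cmi_range)
        return json.dumps(payload, indent=2)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal from arithmetic mean and sd."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


@dataclass
class CellPopulation:
    """Generated cohort: per-cell morphometry plus the generating config."""

    cells: pd.DataFrame
    config: GeneratorConfig

    @property
    def diameters_um(self) -> np.ndarray:
        return self.cells["diameter_um"].to_numpy()

    @property
    def realized_necrosis_fraction(self) -> float:
        return float((self.cells["state"] == "necrotic").mean())

    def to_csv(self, path: str) -> None:
        self.cells.to_csv(path, index=False)


def generate_population(config: GeneratorConfig) -> CellPopulation:
    """Draw a cohort of cells with known latent injury states.

    Deterministic for a fixed config (the seed is part of the config):
    identical configs give byte-identical CSV output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    minor = rng.random(n) < config.minor_weight
    mu_maj, sg_maj = _lognormal_params(config.major_mean_um, config.major_sd_um)
    mu_min, sg_min = _lognormal_params(config.minor_mean_um, config.minor_sd_um)
    diam = np.where(
        minor,
        rng.lognormal(mu_min, sg_min, size=n),
        rng.lognormal(mu_maj, sg_maj, size=n),
    )
    u_state = rng.random(n)
    necrotic = u_state < config.necrosis_fraction
    deformed = (~necrotic) & (
        u_state < config.necrosis_fraction
        + config.deformation_fraction * (1.0 - config.necrosis_fraction)
    )
    state = np.where(necrotic, "necrotic", np.where(deformed, "deformed", "viable"))

    lo, hi = config.deformed_cmi_range
    cmi_deformed = rng.uniform(lo, hi, size=n)
    length = diam.copy()
    width = np.where(deformed, cmi_deformed * length, length)
    width = np.where(necrotic, np.nan, width)
    length = np.where(necrotic, np.nan, length)

    membrane_damage = rng.random(n) < config.membrane_damage_prob
    trypan_positive = necrotic | (deformed & membrane_damage)

    cells = pd.DataFrame(
        {
            "cell_id": [f"cell_{i:05d}" for i in range(n)],
            "diameter_um": diam,
            "width_um": width,
            "length_um": length,
            "state": state,
            "trypan": np.where(trypan_positive, "positive", "negative"),
            "component": np.where(minor, "minor", "major"),
        }
    )
    return CellPopulation(cells=cells, config=config)


@dataclass
class AssayTables:
    """Simulated before/after assay readouts plus the generating truth."""

    assays: pd.DataFrame
    truth: dict

    def to_csv(self, path: str) -> None:
        self.assays.to_csv(path, index=False)

    def write(self, out_dir: str, population: CellPopulation | None = None) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.to_csv(os.path.join(out_dir, "assays.csv"))
        if population is not None:
            population.to_csv(os.path.join(out_dir, "cells.csv"))
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=2)


def _chamber_probability(config: GeneratorConfig) -> float:
    """Probability a suspension cell lands in the counted squares."""
    p = config.hemo_squares * 1.0e-4 / (config.hemo_dilution * config.volume_ml)
    if p > 1.0:
        raise ValueError(
            "counting volume exceeds the suspension volume; increase the "
            "suspension volume or the dilution"
        )
    return p


def simulate_assays(population: CellPopulation, config: GeneratorConfig | None = None) -> AssayTables:
    """Emulate the wet-lab readouts for the before/after sorting arms.

    * Necrotic cells lyse in the device: they vanish from the after-arm
      counts and each releases ``dna_release_ug_per_cell`` into the
      supernatant.
    * Hemocytometer counts are binomial draws of the (integer) cell count
      into the chamber squares.
    * OD260 is the true supernatant concentration passed backwards through
      the 50 x OD x dilution conversion, times mean-one lognormal noise.

    A fresh generator seeded from ``config.seed + 1`` keeps the assay draws
    independent of (but reproducible alongside) the population draws.
    """
    config = config or population.config
    rng = np.random.default_rng(config.seed + 1)
    n = len(population.cells)
    f_real = population.realized_necrosis_fraction
    n_survive = int(round(n * (1.0 - f_real)))
    conc_before = config.effective_conc_before
    conc_after = conc_before * (1.0 - f_real)
    dsdna_before = config.baseline_dsdna_ug_ml
    released = (f_real * n * config.dna_release_ug_per_cell) / config.volume_ml
    dsdna_after = dsdna_before + released
    p_chamber = _chamber_probability(config)

    rows = []
    for arm, n_cells_arm, dsdna_true in (
        ("before", n, dsdna_before),
        ("after", n_survive, dsdna_after),
    ):
        for rep in range(config.n_replicates):
            if config.exact_counts:
                count = n_cells_arm * p_chamber
            else:
                count = int(rng.binomial(n_cells_arm, p_chamber))
            od_true = dsdna_true / (50.0 * config.od_dilution_factor)
            if config.od_noise_sigma > 0 and not config.exact_counts:
                noise = rng.lognormal(
                    -0.5 * config.od_noise_sigma**2, config.od_noise_sigma
                )
            else:
                noise = 1.0
            rows.append(
                {
                    "sample_id": f"{arm}_{rep + 1}",
                    "arm": arm,
                    "od260": od_true * noise,
                    "dilution": config.od_dilution_factor,
                    "count": count,
                    "squares": config.hemo_squares,
                    "sample_dilution": config.hemo_dilution,
                }
            )
    assays = pd.DataFrame.from_records(rows)
    truth = {
        "necrosis_fraction_configured": config.necrosis_fraction,
        "necrosis_fraction_realized": f_real,
        "percent_lost_true": 100.0 * f_real,
        "conc_before_cells_ml": conc_before,
        "conc_after_cells_ml": conc_after,
        "dsdna_before_ug_ml": dsdna_before,
        "dsdna_after_ug_ml": dsdna_after,
        "od_noise_sigma": config.od_noise_sigma,
        "n_cells": n,
    }
    return AssayTables(assays=assays, truth=truth)


@dataclass(frozen=True)
class RecoveryResult:
    """Parameter estimates recovered by running the assay pipeline."""

    necrosis_fraction: float
    necrosis_fraction_se: float
    percent_lost: float
    percent_lost_se: float
    cv_before_percent: float
    cv_after_percent: float
    conc_before_cells_ml: float
    conc_after_cells_ml: float
    dna_fold_change: float


def recover_ground_truth(
    population: CellPopulation, tables: AssayTables
) -> RecoveryResult:
    """Re-estimate the generator's parameters through the assay pipeline.

    * necrosis fraction — share of cells whose morphology is unmeasurable
      (the CMI pipeline's wreckage flag); binomial standard error.
    * percent lost — hemocytometer concentrations before vs after, with a
      delta-method standard error from the pooled counts.
    * CV — coefficient of variation of the replicate dsDNA readings.
    """
    cells = cmi_table(population.cells)
    n = len(cells)
    f_hat = float(cells["cmi_unmeasured"].mean())
    f_se = math.sqrt(max(f_hat * (1.0 - f_hat), 1e-12) / n)

    conc = {}
    totals = {}
    dsdna = {}
    for arm, grp in tables.assays.groupby("arm"):
        conc[arm] = float(
            np.mean(
                [
                    hemocytometer_concentration(c, s, d)
                    for c, s, d in zip(
                        grp["count"], grp["squares"], grp["sample_dilution"]
                    )
                ]
            )
        )
        totals[arm] = float(grp["count"].sum())
        dsdna[arm] = 50.0 * grp["od260"].to_numpy() * grp["dilution"].to_numpy()

    att = attrition_summary(conc["before"], conc["after"])
    ratio = att.fold_change
    if totals["before"] > 0 and totals["after"] > 0:
        lost_se = 100.0 * ratio * math.sqrt(
            1.0 / totals["after"] + 1.0 / totals["before"]
        )
    else:  # expectation-mode counts carry no sampling error
        lost_se = 0.0
    dna_fold = attrition_summary(
        float(np.mean(dsdna["before"])), float(np.mean(dsdna["after"]))
    ).fold_change

    def cv_or_zero(vals):
        return coefficient_of_variation(vals) if np.std(vals) > 0 else 0.0

    return RecoveryResult(
        necrosis_fraction=f_hat,
        necrosis_fraction_se=f_se,
        percent_lost=att.percent_lost,
        percent_lost_se=lost_se,
        cv_before_percent=cv_or_zero(dsdna["before"]),
        cv_after_percent=cv_or_zero(dsdna["after"]),
        conc_before_cells_ml=conc["before"],
        conc_after_cells_ml=conc["after"],
        dna_fold_change=dna_fold,
    )
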
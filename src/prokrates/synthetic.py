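"""Synthetic microcosm experiments with known ground-truth rates.

The generator produces complete raw observation sets (microscopy field
counts, cell biovolumes, scintillation DPM, carbonate chemistry inputs) for a
balanced 2x2 factorial incubation, from per-treatment ground truths
(gross growth rate SGR, mortality rate MR, initial abundance N0, mean cell
biovolume).  The population follows exponential dynamics
``N(t) = N0 * exp((SGR - MR) * t)`` and the observation models mirror the
measurement protocols the pipeline inverts:

* microscopy: independent Poisson counts per visual field around the true
  expected cells per field (true abundance x volume filtered / filter-to-field
  area ratio); cell volumes drawn lognormal around the true mean;
* leucine assay: the true end-of-incubation carbon production implied by the
  truth, ``P = B * (exp(SGR) - 1)`` (the exact inverse of the SGR estimator),
  is converted backwards through the assay arithmetic to an expected net DPM;
  live aliquots receive blank + signal, blanks the blank mean, each with
  multiplicative Gaussian noise of a configurable CV.

Randomness comes from one master seed expanded with ``numpy``
``SeedSequence.spawn`` into one child stream per experimental unit and
timepoint, in the fixed order (treatment in design order, then replicate,
then timepoint 0 / end); regeneration with the same inputs is bit-identical.
Poisson counting and lognormal volume scatter count as noise terms: a fully
noiseless generator (``poisson_counts=False``, ``dpm_noise_cv=0``,
``dpm_blank_mean=0``, ``cv_cell_volume=0``) yields observations from which
the pipeline recovers the ground truth to numerical precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import MicrocosmDesign
from .leucine import DPM_PER_UCI
from .microscopy import FG_CELL_CARBON, CellCarbonModel, cell_carbon

__all__ = [
    "TrueTreatmentParams",
    "ObservationNoiseModel",
    "TreatmentChemistry",
    "RawSample",
    "SyntheticExperiment",
    "simulate_dynamics",
    "simulate_experiment",
    "experiment2_scenario",
    "SAMPLE_SHEET_COLUMNS",
]

SAMPLE_SHEET_COLUMNS = [
    "experiment",
    "treatment",
    "replicate",
    "timepoint",
    "field_index",
    "cells_in_field",
    "mean_cell_volume_um3",
    "dpm_sample_1",
    "dpm_sample_2",
    "dpm_sample_3",
    "dpm_blank_1",
    "dpm_blank_2",
    "dpm_blank_3",
    "ph",
    "ta_umol_kg",
    "temp_c",
    "salinity",
]


@dataclass(frozen=True)
class TrueTreatmentParams:
    """Ground-truth rates and cell properties for one treatment."""

    treatment_label: str
    sgr_true: float  # d^-1
    mr_true: float  # d^-1
    n0_true: float  # cells L^-1
    mean_cell_volume: float = 0.1  # um^3
    cv_cell_volume: float = 0.35

    def __post_init__(self) -> None:
        for name in ("sgr_true", "mr_true", "cv_cell_volume"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0")
        if not (math.isfinite(self.n0_true) and self.n0_true > 0):
            raise ValueError("n0_true must be finite and > 0")
        if not self.mean_cell_volume > 0:
            raise ValueError("mean_cell_volume must be > 0")


@dataclass(frozen=True)
class ObservationNoiseModel:
    """Observation-process parameters shared by all units of an experiment.

    Counting protocol: at least 50 fields per slide and an expected total of
    at least 400 cells; configurations whose expectation falls short raise
    instead of silently violating the protocol.
    """

    fields_per_slide: int = 60
    min_cells_total: int = 400
    filter_area_ratio: float = 1e5  # filtration area / field area
    volume_filtered: float = 0.002  # L
    leu_specific_activity: float = 304.0  # uCi umol^-1
    leu_incubation_hours: float = 2.0
    leu_sample_volume: float = 0.005  # L
    leu_to_carbon: float = 1.5  # ugC per nmol leucine
    dpm_blank_mean: float = 50.0
    dpm_noise_cv: float = 0.10
    n_cells_measured: int = 100  # cells sized for the biovolume estimate
    poisson_counts: bool = True

    def __post_init__(self) -> None:
        if self.fields_per_slide < 50:
            raise ValueError("fields_per_slide must be >= 50 (counting protocol)")
        if not (self.filter_area_ratio > 0 and self.volume_filtered > 0):
            raise ValueError("filtration geometry must be positive")
        if self.dpm_blank_mean < 0 or self.dpm_noise_cv < 0:
            raise ValueError("DPM noise parameters must be >= 0")
        if self.n_cells_measured < 1:
            raise ValueError("n_cells_measured must be >= 1")

    def noiseless(self) -> "ObservationNoiseModel":
        """Copy with every stochastic observation term switched off."""
        return replace(self, dpm_blank_mean=0.0, dpm_noise_cv=0.0, poisson_counts=False)


@dataclass(frozen=True)
class TreatmentChemistry:
    """Carbonate-system inputs recorded for one treatment's units."""

    ph: float = 8.1
    ta_umol_kg: float = 2300.0
    temp_c: float = 10.0
    salinity: float = 35.5


@dataclass(frozen=True)
class RawSample:
    """Raw observations for one experimental unit at one timepoint."""

    treatment: str
    replicate: int
    timepoint_h: float
    cells_per_field: np.ndarray
    cell_volumes: np.ndarray
    dpm_samples: np.ndarray | None  # None before the production assay (t0)
    dpm_blanks: np.ndarray | None
    ph: float
    ta_umol_kg: float
    temp_c: float
    salinity: float


@dataclass(frozen=True)
class SyntheticExperiment:
    """A complete simulated experiment: design, truths, and raw observations."""

    design: MicrocosmDesign
    truths: tuple[TrueTreatmentParams, ...]
    noise: ObservationNoiseModel
    chemistry: Mapping[str, TreatmentChemistry]
    seed: int
    samples: tuple[RawSample, ...]

    def truth(self, label: str) -> TrueTreatmentParams:
        for t in self.truths:
            if t.treatment_label == label:
                return t
        raise KeyError(label)

    def to_sample_sheet(self) -> pd.DataFrame:
        """Long-format sample sheet (one row per counted field)."""
        rows = []
        for s in self.samples:
            dpm_s = s.dpm_samples if s.dpm_samples is not None else [np.nan] * 3
            dpm_b = s.dpm_blanks if s.dpm_blanks is not None else [np.nan] * 3
            mean_vol = float(np.mean(s.cell_volumes))
            for i, c in enumerate(s.cells_per_field):
                rows.append(
                    {
                        "experiment": self.design.name,
                        "treatment": s.treatment,
                        "replicate": s.replicate,
                        "timepoint": s.timepoint_h,
                        "field_index": i,
                        "cells_in_field": float(c),
                        "mean_cell_volume_um3": mean_vol,
                        "dpm_sample_1": dpm_s[0],
                        "dpm_sample_2": dpm_s[1],
                        "dpm_sample_3": dpm_s[2],
                        "dpm_blank_1": dpm_b[0],
                        "dpm_blank_2": dpm_b[1],
                        "dpm_blank_3": dpm_b[2],
                        "ph": s.ph,
                        "ta_umol_kg": s.ta_umol_kg,
                        "temp_c": s.temp_c,
                        "salinity": s.salinity,
                    }
                )
        return pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)


def simulate_dynamics(params: TrueTreatmentParams, t: float) -> float:
    """True abundance (cells L^-1) after ``t`` days of exponential dynamics."""
    if t < 0:
        raise ValueError("t must be >= 0 days")
    return params.n0_true * math.exp((params.sgr_true - params.mr_true) * t)


def _draw_counts(rng: np.random.Generator, mu: float, noise: ObservationNoiseModel) -> np.ndarray:
    expected_total = mu * noise.fields_per_slide
    if expected_total < noise.min_cells_total:
        raise ValueError(
            f"expected {expected_total:.0f} cells over {noise.fields_per_slide} fields, "
            f"below the protocol minimum of {noise.min_cells_total}; increase "
            "volume_filtered or fields_per_slide"
        )
    if noise.poisson_counts:
        return rng.poisson(mu, size=noise.fields_per_slide).astype(float)
    return np.full(noise.fields_per_slide, mu)


def _draw_volumes(
    rng: np.random.Generator, params: TrueTreatmentParams, noise: ObservationNoiseModel
) -> np.ndarray:
    if params.cv_cell_volume == 0:
        return np.full(noise.n_cells_measured, params.mean_cell_volume)
    sigma2 = math.log1p(params.cv_cell_volume**2)
    mu = math.log(params.mean_cell_volume) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=noise.n_cells_measured)


def _expected_net_dpm(
    params: TrueTreatmentParams,
    noise: ObservationNoiseModel,
    carbon_model: CellCarbonModel,
    t_days: float,
) -> float:
    """Net DPM implied by the ground truth at the end of the incubation.

    Exact inverse of the estimator chain: true end biomass B (from true
    abundance and true mean cell volume), true production P = B*(e^SGR - 1),
    converted back through the leucine assay arithmetic.
    """
    n_t = simulate_dynamics(params, t_days)
    b = n_t * cell_carbon(params.mean_cell_volume, carbon_model) * 1e-9  # ugC/L
    p = b * math.expm1(params.sgr_true)  # ugC/L/d
    rate_nmol_h = p / (24.0 * noise.leu_to_carbon)
    umol = rate_nmol_h * 1e-3 * noise.leu_incubation_hours * noise.leu_sample_volume
    return umol * noise.leu_specific_activity * DPM_PER_UCI


def _draw_dpm(
    rng: np.random.Generator, expected_net: float, noise: ObservationNoiseModel
) -> tuple[np.ndarray, np.ndarray]:
    mean_sample = noise.dpm_blank_mean + expected_net
    if noise.dpm_noise_cv == 0:
        samples = np.full(3, mean_sample)
        blanks = np.full(3, noise.dpm_blank_mean)
    else:
        samples = mean_sample * (1.0 + noise.dpm_noise_cv * rng.standard_normal(3))
        blanks = noise.dpm_blank_mean * (1.0 + noise.dpm_noise_cv * rng.standard_normal(3))
    return np.clip(samples, 0.0, None), np.clip(blanks, 0.0, None)


def simulate_experiment(
    design: MicrocosmDesign,
    truths: Sequence[TrueTreatmentParams],
    noise: ObservationNoiseModel,
    seed: int,
    chemistry: Mapping[str, TreatmentChemistry] | None = None,
    carbon_model: CellCarbonModel = FG_CELL_CARBON,
) -> SyntheticExperiment:
    """Simulate raw observations for every unit of a balanced 2x2 experiment."""
    labels = design.treatment_labels
    by_label = {t.treatment_label: t for t in truths}
    missing = set(labels) - set(by_label)
    if missing:
        raise ValueError(f"no ground truth supplied for treatments: {sorted(missing)}")
    if chemistry is None:
        chemistry = {lab: TreatmentChemistry() for lab in labels}

    t_days = design.incubation_days
    master = np.random.SeedSequence(seed)
    # one child per (treatment, replicate, timepoint), fixed order
    children = iter(master.spawn(4 * design.replicates * 2))

    samples: list[RawSample] = []
    for label in labels:
        params = by_label[label]
        chem = chemistry[label]
        expected_net = _expected_net_dpm(params, noise, carbon_model, t_days)
        for rep in range(1, design.replicates + 1):
            for timepoint_h, t in ((0.0, 0.0), (t_days * 24.0, t_days)):
                rng = np.random.default_rng(next(children))
                n_true = simulate_dynamics(params, t)
                mu = n_true * noise.volume_filtered / noise.filter_area_ratio
                counts = _draw_counts(rng, mu, noise)
                volumes = _draw_volumes(rng, params, noise)
                if t > 0:
                    dpm_s, dpm_b = _draw_dpm(rng, expected_net, noise)
                else:
                    dpm_s = dpm_b = None
                samples.append(
                    RawSample(
                        treatment=label,
                        replicate=rep,
                        timepoint_h=timepoint_h,
                        cells_per_field=counts,
                        cell_volumes=volumes,
                        dpm_samples=dpm_s,
                        dpm_blanks=dpm_b,
                        ph=chem.ph,
                        ta_umol_kg=chem.ta_umol_kg,
                        temp_c=chem.temp_c,
                        salinity=chem.salinity,
                    )
                )

    return SyntheticExperiment(
        design=design,
        truths=tuple(by_label[lab] for lab in labels),
        noise=noise,
        chemistry=dict(chemistry),
        seed=seed,
        samples=tuple(samples),
    )


def experiment2_scenario(
    sgr_elevated: float = 1.0,
    mr_elevated: float = 1.1,
    sgr_ambient: float = 0.5,
    mr_ambient: float = 0.3,
    n0: float = 2.43e9,
) -> tuple[MicrocosmDesign, list[TrueTreatmentParams], Mapping[str, TreatmentChemistry]]:
    """Default CO2 x warming scenario.

    Ground-truth rates follow the winter lagoon incubation: ambient water at
    10 degC around SGR 0.5 / MR 0.3 d^-1; the +3 degC treatments roughly double
    gross growth and quadruple mortality (SGR 1.0, MR 1.1 d^-1).  CO2
    enrichment (pH 8.1 -> 7.9 at fixed alkalinity) has no true effect on
    rates, matching its observed neutrality.
    """
    design = MicrocosmDesign(name="experiment-2", factor_names=("CO2", "T"))
    truths = [
        TrueTreatmentParams("control", sgr_ambient, mr_ambient, n0),
        TrueTreatmentParams("CO2", sgr_ambient, mr_ambient, n0),
        TrueTreatmentParams("T", sgr_elevated, mr_elevated, n0),
        TrueTreatmentParams("CO2+T", sgr_elevated, mr_elevated, n0),
    ]
    chemistry = {
        "control": TreatmentChemistry(ph=8.1, temp_c=10.0),
        "CO2": TreatmentChemistry(ph=7.9, temp_c=10.0),
        "T": TreatmentChemistry(ph=8.1, temp_c=13.0),
        "CO2+T": TreatmentChemistry(ph=7.9, temp_c=13.0),
    }
    return design, truths, chemistry
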
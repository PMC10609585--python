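"""Epifluorescence microscopy reductions: field counts -> abundance, biovolume -> carbon.

Heterotrophic prokaryote (HProk) abundance is estimated by filtering a known
water volume onto a membrane, staining, and counting cells in randomly chosen
microscope fields.  The count protocol targets at least 50 fields and 400
cells per slide; sparser slides are accepted with a warning.  Cell carbon is
obtained from mean cell biovolume through an allometric power law
``CC = a * CV**b`` (fgC per cell, CV in um^3), with the open-ocean
picoplankton calibration a = 0.12, b = 0.72 as default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CountObservation",
    "CellCarbonModel",
    "FG_CELL_CARBON",
    "LowCountWarning",
    "abundance_from_counts",
    "cell_carbon",
    "mean_cell_carbon",
    "biomass",
]

#: protocol targets for a single slide
MIN_FIELDS = 50
MIN_CELLS_TOTAL = 400


class LowCountWarning(UserWarning):
    """A slide missed the counting protocol targets (fields or total cells)."""


@dataclass(frozen=True)
class CellCarbonModel:
    """Allometric biovolume-to-carbon conversion ``CC = coefficient * CV**exponent``.

    The default (0.12, 0.72) is the relation as conventionally written with
    carbon in picograms; ``FG_CELL_CARBON`` is the same allometry with the
    coefficient in femtograms (120), which is what the biomass bookkeeping in
    fgC -> ugC expects and what the pipeline uses by default.
    """

    coefficient: float = 0.12
    exponent: float = 0.72

    def __post_init__(self) -> None:
        if not (self.coefficient > 0 and self.exponent > 0):
            raise ValueError("cell-carbon coefficient and exponent must be > 0")


#: the same allometry with carbon in femtograms: ~23 fgC for a 0.1 um^3 cell
FG_CELL_CARBON = CellCarbonModel(coefficient=120.0, exponent=0.72)


@dataclass(frozen=True)
class CountObservation:
    """Per-slide microscopy counts plus the filtration geometry.

    Parameters
    ----------
    cells_per_field:
        Cells enumerated in each random visual field.
    filter_area_ratio:
        Effective filtration area divided by the area of one visual field
        (dimensionless, > 0).
    volume_filtered:
        Water volume filtered onto the membrane, litres.
    """

    cells_per_field: Sequence[float] = field(default_factory=list)
    filter_area_ratio: float = 1.0
    volume_filtered: float = 1.0

    def __post_init__(self) -> None:
        if len(self.cells_per_field) == 0:
            raise ValueError("at least one counted field is required")
        if not self.volume_filtered > 0:
            raise ValueError("volume_filtered must be > 0 litres")
        if not self.filter_area_ratio > 0:
            raise ValueError("filter_area_ratio must be > 0")


def _check_protocol(obs: CountObservation) -> None:
    n_fields = len(obs.cells_per_field)
    total = float(np.sum(obs.cells_per_field))
    if n_fields < MIN_FIELDS or total < MIN_CELLS_TOTAL:
        warnings.warn(
            f"slide below counting protocol targets: {n_fields} fields "
            f"(target >= {MIN_FIELDS}), {total:.0f} cells (target >= {MIN_CELLS_TOTAL})",
            LowCountWarning,
            stacklevel=3,
        )


def abundance_from_counts(obs: CountObservation) -> float:
    """Cells per litre from per-field counts.

    abundance = mean(cells per field) * filter_area_ratio / volume_filtered
    """
    _check_protocol(obs)
    return float(np.mean(obs.cells_per_field)) * obs.filter_area_ratio / obs.volume_filtered


def cell_carbon(cv: float, model: CellCarbonModel = CellCarbonModel()) -> float:
    """Carbon content (fgC) of a cell of biovolume ``cv`` (um^3)."""
    if not cv > 0:
        raise ValueError("cell biovolume must be > 0 um^3")
    return model.coefficient * cv ** model.exponent


def mean_cell_carbon(
    volumes: Sequence[float],
    model: CellCarbonModel = CellCarbonModel(),
    *,
    per_cell: bool = False,
) -> float:
    """Mean cell carbon (fgC) for a set of measured cell biovolumes.

    By default the arithmetic mean biovolume is converted once (mean-then-convert,
    matching the "mean cell carbon content" bookkeeping of assemblage biomass).
    With ``per_cell=True`` each cell is converted and the carbons averaged;
    because the power law is concave this yields a smaller value on skewed
    volume distributions.
    """
    vols = np.asarray(volumes, dtype=float)
    if vols.size == 0:
        raise ValueError("at least one cell biovolume is required")
    if np.any(vols <= 0):
        raise ValueError("cell biovolumes must be > 0 um^3")
    if per_cell:
        return float(np.mean(model.coefficient * vols ** model.exponent))
    return cell_carbon(float(np.mean(vols)), model)


def biomass(abundance: float, mean_cc: float) -> float:
    """Assemblage biomass (ugC L^-1) from abundance (cells L^-1) and mean cell carbon (fgC).

    The 1e-9 factor converts fg to ug.
    """
    if abundance < 0 or mean_cc < 0:
        raise ValueError("abundance and mean cell carbon must be non-negative")
    return abundance * mean_cc * 1e-9
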
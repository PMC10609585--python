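"""End-to-end orchestration: sample sheet -> derived state -> rates -> ANOVA.

Stages
------
reduce
    Per experimental unit and timepoint, convert raw observations into
    abundance (cells L^-1), mean cell carbon (fgC), biomass (ugC L^-1) and,
    where a leucine assay is present, carbon production (ugC L^-1 d^-1) and
    cell-specific activity (1e-9 nmol leucine cell^-1 d^-1).
rates
    Per replicate, pair end-of-incubation production with end-of-incubation
    biomass to get SGR, initial/final abundance to get NGR, and take
    MR = SGR - NGR; summarise treatments as means +/- SE of replicate rates.
anova
    Per response (abundance, biomass, production, cellular activity, SGR,
    NGR, MR), run the balanced two-way factorial ANOVA and assemble the
    effects table.
carbonate
    Speciate each unit's TA/pH/T/S record into pCO2 and DIC.

All stages are pure functions of their inputs plus an explicit ``RunConfig``;
identical inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import carbonate as carb
from .design import MicrocosmDesign
from .leucine import LeucineAssay, carbon_production, cell_specific_activity, leucine_incorporation_rate
from .microscopy import CellCarbonModel, CountObservation, abundance_from_counts, biomass, cell_carbon
from .rates import ReplicateRates, TreatmentRates, summarize_treatment
from .stats import AnovaReport, FactorialDataset, build_effects_table, two_way_anova
from .synthetic import SAMPLE_SHEET_COLUMNS, RawSample, SyntheticExperiment

__all__ = [
    "RunConfig",
    "SampleSheetError",
    "read_sample_sheet",
    "sheet_to_samples",
    "reduce_samples",
    "compute_rates",
    "rates_table",
    "run_anova",
    "carbonate_summary",
    "run_pipeline",
]

#: responses analysed in the effects table, in reporting order
RESPONSES = [
    "abundance",
    "biomass",
    "net_production",
    "cellular_activity",
    "sgr",
    "ngr",
    "mr",
]


class SampleSheetError(ValueError):
    """A sample sheet violated the expected schema."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs beyond the sample sheet itself."""

    incubation_days: float = 2.0
    filter_area_ratio: float = 1e5
    volume_filtered: float = 0.002
    leu_specific_activity: float = 304.0
    leu_incubation_hours: float = 2.0
    leu_sample_volume: float = 0.005
    leu_to_carbon: float = 1.5
    cc_coefficient: float = 120.0  # fgC form of the 0.12 pgC allometry
    cc_exponent: float = 0.72
    volume_averaging: str = "mean-then-convert"  # or "convert-then-mean"
    factor_a: str = "CO2"
    factor_b: str = "T"
    alpha: float = 0.05
    omega_threshold: float = 0.70

    def __post_init__(self) -> None:
        if self.volume_averaging not in ("mean-then-convert", "convert-then-mean"):
            raise ValueError("volume_averaging must be 'mean-then-convert' or 'convert-then-mean'")

    @property
    def carbon_model(self) -> CellCarbonModel:
        return CellCarbonModel(self.cc_coefficient, self.cc_exponent)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load from a flat key:value YAML mapping; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV sample sheet and validate its schema."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SampleSheetError(f"sample sheet {path} missing columns: {missing}")
    bad = df.index[df["cells_in_field"] < 0]
    if len(bad):
        raise SampleSheetError(f"negative cells_in_field at rows {list(bad[:5])}")
    return df


def sheet_to_samples(df: pd.DataFrame) -> list[RawSample]:
    """Group a long-format sheet into one RawSample per unit and timepoint."""
    samples = []
    for (treatment, rep, tp), grp in df.groupby(
        ["treatment", "replicate", "timepoint"], sort=False
    ):
        dpm_s = grp.iloc[0][["dpm_sample_1", "dpm_sample_2", "dpm_sample_3"]].to_numpy(float)
        dpm_b = grp.iloc[0][["dpm_blank_1", "dpm_blank_2", "dpm_blank_3"]].to_numpy(float)
        has_assay = not np.all(np.isnan(dpm_s))
        samples.append(
            RawSample(
                treatment=str(treatment),
                replicate=int(rep),
                timepoint_h=float(tp),
                cells_per_field=grp["cells_in_field"].to_numpy(float),
                cell_volumes=np.asarray([float(grp.iloc[0]["mean_cell_volume_um3"])]),
                dpm_samples=dpm_s if has_assay else None,
                dpm_blanks=dpm_b if has_assay else None,
                ph=float(grp.iloc[0]["ph"]),
                ta_umol_kg=float(grp.iloc[0]["ta_umol_kg"]),
                temp_c=float(grp.iloc[0]["temp_c"]),
                salinity=float(grp.iloc[0]["salinity"]),
            )
        )
    return samples


def _mean_cell_carbon(volumes: np.ndarray, config: RunConfig) -> float:
    model = config.carbon_model
    if config.volume_averaging == "convert-then-mean":
        return float(np.mean(model.coefficient * volumes**model.exponent))
    return cell_carbon(float(np.mean(volumes)), model)


def reduce_samples(samples: Sequence[RawSample], config: RunConfig) -> pd.DataFrame:
    """Derived state per unit and timepoint (one row each)."""
    rows = []
    for s in samples:
        obs = CountObservation(
            cells_per_field=s.cells_per_field,
            filter_area_ratio=config.filter_area_ratio,
            volume_filtered=config.volume_filtered,
        )
        abund = abundance_from_counts(obs)
        mean_cc = _mean_cell_carbon(np.asarray(s.cell_volumes, dtype=float), config)
        row = {
            "treatment": s.treatment,
            "replicate": s.replicate,
            "timepoint": s.timepoint_h,
            "abundance": abund,
            "mean_cell_volume_um3": float(np.mean(s.cell_volumes)),
            "mean_cell_carbon_fg": mean_cc,
            "biomass": biomass(abund, mean_cc),
            "net_production": np.nan,
            "cellular_activity": np.nan,
        }
        if s.dpm_samples is not None:
            assay = LeucineAssay(
                dpm_samples=s.dpm_samples,
                dpm_blanks=s.dpm_blanks,
                specific_activity=config.leu_specific_activity,
                incubation=config.leu_incubation_hours,
                sample_volume=config.leu_sample_volume,
                leu_to_carbon=config.leu_to_carbon,
            )
            leu_rate = leucine_incorporation_rate(assay)
            row["net_production"] = carbon_production(leu_rate, assay)
            row["cellular_activity"] = cell_specific_activity(leu_rate * 24.0, abund)
        rows.append(row)
    return pd.DataFrame(rows)


def reduce_experiment(exp: SyntheticExperiment, config: RunConfig) -> pd.DataFrame:
    """Shortcut: reduce a synthetic experiment without writing a sheet."""
    return reduce_samples(exp.samples, config)


def compute_rates(derived: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Per-replicate SGR/NGR/MR/MR:SGR from the derived-state table."""
    t = config.incubation_days
    t_end_h = t * 24.0
    rows = []
    for (treatment, rep), grp in derived.groupby(["treatment", "replicate"], sort=False):
        start = grp[grp["timepoint"] == 0.0]
        end = grp[grp["timepoint"] == t_end_h]
        if len(start) != 1 or len(end) != 1:
            raise SampleSheetError(
                f"treatment {treatment!r} replicate {rep}: need exactly one row at "
                f"t=0 and one at t={t_end_h} h"
            )
        start, end = start.iloc[0], end.iloc[0]
        rr = ReplicateRates.from_observations(
            production=float(end["net_production"]),
            biomass=float(end["biomass"]),
            n0=float(start["abundance"]),
            nt=float(end["abundance"]),
            t=t,
        )
        rows.append(
            {
                "treatment": treatment,
                "replicate": rep,
                "abundance": float(end["abundance"]),
                "biomass": float(end["biomass"]),
                "net_production": float(end["net_production"]),
                "cellular_activity": float(end["cellular_activity"]),
                "sgr": rr.sgr,
                "ngr": rr.ngr,
                "mr": rr.mr,
                "mr_sgr": rr.mr_sgr,
            }
        )
    return pd.DataFrame(rows)


def rates_table(replicate_rates: pd.DataFrame) -> pd.DataFrame:
    """Treatment summary shaped like the published rate tables (mean +/- SE)."""
    rows = []
    for treatment, grp in replicate_rates.groupby("treatment", sort=False):
        reps = [
            ReplicateRates(r.sgr, r.ngr, r.mr, r.mr_sgr) for r in grp.itertuples()
        ]
        tr: TreatmentRates = summarize_treatment(str(treatment), reps)
        n = len(grp)
        row = {"treatment": treatment}
        for resp in ("net_production", "cellular_activity"):
            row[resp] = float(grp[resp].mean())
            row[f"{resp}_se"] = float(grp[resp].std(ddof=1) / np.sqrt(n))
        row.update(
            {
                "sgr": tr.sgr,
                "sgr_se": tr.sgr_se,
                "ngr": tr.ngr,
                "ngr_se": tr.ngr_se,
                "mr": tr.mr,
                "mr_se": tr.mr_se,
                "mr_sgr": tr.mr_sgr,
                "mr_sgr_se": tr.mr_sgr_se,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _treatment_levels(label: str, config: RunConfig) -> tuple[bool, bool]:
    parts = set() if label == "control" else set(label.split("+"))
    unknown = parts - {config.factor_a, config.factor_b}
    if unknown:
        raise SampleSheetError(
            f"treatment label {label!r} does not match factors "
            f"({config.factor_a}, {config.factor_b})"
        )
    return (config.factor_a in parts, config.factor_b in parts)


def run_anova(
    replicate_rates: pd.DataFrame,
    config: RunConfig,
    responses: Sequence[str] = RESPONSES,
) -> tuple[dict[str, AnovaReport], pd.DataFrame]:
    """Two-way ANOVA per response; returns the reports and the effects table."""
    reports: dict[str, AnovaReport] = {}
    for resp in responses:
        cells: list[list[list[float]]] = [[[], []], [[], []]]
        for row in replicate_rates.itertuples():
            i, j = _treatment_levels(str(row.treatment), config)
            cells[int(i)][int(j)].append(float(getattr(row, resp)))
        data = FactorialDataset(
            response_name=resp,
            cells=cells,
            factor_names=(config.factor_a, config.factor_b),
        )
        reports[resp] = two_way_anova(data, alpha=config.alpha)
    table = build_effects_table(
        list(reports.values()), alpha=config.alpha, large_effect_threshold=config.omega_threshold
    )
    return reports, table


def carbonate_summary(samples: Sequence[RawSample]) -> pd.DataFrame:
    """Speciate each unit's TA/pH record; one row per unit and timepoint."""
    rows = []
    for s in samples:
        state = carb.speciate_from_ta_ph(s.ta_umol_kg, s.ph, s.temp_c, s.salinity)
        rows.append(
            {
                "treatment": s.treatment,
                "replicate": s.replicate,
                "timepoint": s.timepoint_h,
                "ph": s.ph,
                "ta_umol_kg": s.ta_umol_kg,
                "temp_c": s.temp_c,
                "salinity": s.salinity,
                "pco2_uatm": state.pco2,
                "dic_umol_kg": state.dic,
                "hco3_umol_kg": state.hco3,
                "co3_umol_kg": state.co3,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    sheet: pd.DataFrame,
    config: RunConfig,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, Path]:
    """Run reduce -> rates -> anova -> carbonate and write the report bundle.

    Writes derived_state.csv, replicate_rates.csv, rates_table.csv,
    effects_table.csv, carbonate_summary.csv and run_log.json into ``out_dir``.
    Outputs are pure functions of (sheet, config), so re-runs are
    byte-identical.  On any stage failure, partial outputs are removed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        outputs[name] = path

    try:
        samples = sheet_to_samples(sheet)
        derived = reduce_samples(samples, config)
        write("derived_state", derived)
        replicate_rates = compute_rates(derived, config)
        write("replicate_rates", replicate_rates)
        write("rates_table", rates_table(replicate_rates))
        _, effects = run_anova(replicate_rates, config)
        write("effects_table", effects)
        write("carbonate_summary", carbonate_summary(samples))
        log = {
            "config_digest": config.digest(),
            "config": dataclasses.asdict(config),
            "seed": seed,
            "n_sheet_rows": int(len(sheet)),
            "n_units": int(len(samples)),
            "n_replicate_rates": int(len(replicate_rates)),
        }
        log_path = out_dir / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
        outputs["run_log"] = log_path
    except Exception:
        for p in outputs.values():
            p.unlink(missing_ok=True)
        raise
    return outputs
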
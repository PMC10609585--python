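"""Balanced two-way factorial ANOVA with generalized omega-squared effect sizes.

The experiments are balanced 2x2 factorial designs (two manipulated factors,
two levels each, equal replication), analysed response by response with a
two-way ANOVA including the interaction.  Because the design is balanced, the
Type I/II/III sums-of-squares distinctions coincide and the cell-mean
decomposition below is exact:

    SS_A     = b*n * sum_a (ybar_a.. - ybar...)^2
    SS_B     = a*n * sum_b (ybar_.b. - ybar...)^2
    SS_AB    = n * sum_ab (ybar_ab. - ybar_a.. - ybar_.b. + ybar...)^2
    SS_error = sum (y - ybar_ab.)^2

Effect sizes are generalized omega-squared for manipulated factors,

    omega2_G = (SS_eff - df_eff * MS_error) / (SS_total + MS_error),

which for a design in which every non-error factor is manipulated uses the
total variation in the denominator; partial omega-squared
(SS_eff - df*MSe) / (SS_eff + (N - df) * MSe) is also reported.  Values above
a configurable threshold (0.70 by default) are flagged as large effects.
Normality (Shapiro-Wilk, on pooled residuals since n per cell is tiny) and
homogeneity of variances (Levene) are reported as annotations and never
abort the analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FactorialDataset",
    "EffectResult",
    "AnovaReport",
    "AssumptionWarning",
    "shapiro_wilk",
    "levene",
    "two_way_anova",
    "omega_g_squared",
    "build_effects_table",
]

ALPHA_DEFAULT = 0.05
LARGE_EFFECT_DEFAULT = 0.70


class AssumptionWarning(UserWarning):
    """An ANOVA assumption check (normality / homoscedasticity) failed."""


@dataclass(frozen=True)
class FactorialDataset:
    """Replicate observations for one response on a balanced 2x2 design.

    ``cells[i][j]`` holds the replicate values at level i of factor A and
    level j of factor B (i, j in {0 = ambient, 1 = elevated}).
    """

    response_name: str
    cells: Sequence[Sequence[Sequence[float]]]
    factor_names: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if len(self.cells) != 2 or any(len(row) != 2 for row in self.cells):
            raise ValueError("cells must form a 2x2 grid")
        ns = {len(cell) for row in self.cells for cell in row}
        if len(ns) != 1:
            raise ValueError("design must be balanced (equal n per cell)")
        if ns.pop() < 2:
            raise ValueError("need n >= 2 replicates per cell")
        flat = np.concatenate([np.asarray(c, dtype=float) for row in self.cells for c in row])
        if not np.all(np.isfinite(flat)):
            raise ValueError("all response values must be finite")

    @property
    def n_per_cell(self) -> int:
        return len(self.cells[0][0])

    def as_array(self) -> np.ndarray:
        """(2, 2, n) array of replicate values."""
        return np.asarray(self.cells, dtype=float)


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; (nan, nan) for degenerate constant input."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        return math.nan, math.nan
    w, p = sps.shapiro(x)
    return float(w), float(p)


def levene(groups: Sequence[Sequence[float]], center: str = "mean") -> tuple[float, float]:
    """Levene homogeneity-of-variance test (classic mean-centred form by default).

    ``center="median"`` gives the Brown-Forsythe variant.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Levene requires >= 2 groups with n >= 2 each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.ptp(a) == 0 for a in arrays):
        return 0.0, 1.0  # every group constant: spreads identical by definition
    f, p = sps.levene(*arrays, center=center)
    return float(f), float(p)


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect line: sums of squares through effect sizes."""

    name: str
    ss: float
    df: int
    ms: float
    f: float
    p: float
    omega_g_sq: float
    omega_p_sq: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA_DEFAULT

    def large_effect(self, threshold: float = LARGE_EFFECT_DEFAULT) -> bool:
        return self.omega_g_sq > threshold


@dataclass(frozen=True)
class AnovaReport:
    """Two-way ANOVA decomposition for one response, plus assumption checks."""

    response_name: str
    factor_names: tuple[str, str]
    effects: tuple[EffectResult, ...]  # (A, B, AxB)
    ss_error: float
    df_error: int
    ms_error: float
    ss_total: float
    shapiro: tuple[float, float]
    levene: tuple[float, float]
    alpha: float = ALPHA_DEFAULT

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def omega_g_squared(ss_eff: float, df_eff: int, ms_error: float, ss_total: float) -> float:
    """Generalized omega-squared, both factors manipulated.

    Can be slightly negative for null effects at small n; reported as computed
    (display-side clamping to 0 happens in the effects table).
    """
    if ms_error == 0:
        return math.nan
    return (ss_eff - df_eff * ms_error) / (ss_total + ms_error)


def _omega_partial(ss_eff: float, df_eff: int, ms_error: float, n_total: int) -> float:
    if ms_error == 0:
        return math.nan
    return (ss_eff - df_eff * ms_error) / (ss_eff + (n_total - df_eff) * ms_error)


def two_way_anova(
    data: FactorialDataset,
    alpha: float = ALPHA_DEFAULT,
    warn_assumptions: bool = True,
) -> AnovaReport:
    """Balanced two-way factorial ANOVA with interaction on one response."""
    y = data.as_array()
    n = data.n_per_cell
    n_total = y.size
    grand = y.mean()

    cell_means = y.mean(axis=2)  # (2,2)
    a_means = y.mean(axis=(1, 2))  # (2,)
    b_means = y.mean(axis=(0, 2))  # (2,)

    ss_a = 2 * n * float(np.sum((a_means - grand) ** 2))
    ss_b = 2 * n * float(np.sum((b_means - grand) ** 2))
    ss_ab = n * float(
        np.sum((cell_means - a_means[:, None] - b_means[None, :] + grand) ** 2)
    )
    ss_error = float(np.sum((y - cell_means[:, :, None]) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))

    df_error = n_total - 4
    ms_error = ss_error / df_error

    residuals = (y - cell_means[:, :, None]).ravel()
    sw = shapiro_wilk(residuals)
    lv = levene([cell for row in data.cells for cell in row])
    if warn_assumptions:
        for test, (stat, p) in (("Shapiro-Wilk", sw), ("Levene", lv)):
            if not math.isnan(p) and p < alpha:
                warnings.warn(
                    f"{data.response_name}: {test} p={p:.3g} < {alpha}; "
                    "ANOVA reported anyway, interpret with care",
                    AssumptionWarning,
                    stacklevel=2,
                )

    effects = []
    names = (data.factor_names[0], data.factor_names[1], f"{data.factor_names[0]}x{data.factor_names[1]}")
    for name, ss in zip(names, (ss_a, ss_b, ss_ab)):
        df_eff = 1
        ms = ss / df_eff
        if ms_error > 0:
            f = ms / ms_error
            p = float(sps.f.sf(f, df_eff, df_error))
        else:
            f = math.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        effects.append(
            EffectResult(
                name=name,
                ss=ss,
                df=df_eff,
                ms=ms,
                f=f,
                p=p,
                omega_g_sq=omega_g_squared(ss, df_eff, ms_error, ss_total),
                omega_p_sq=_omega_partial(ss, df_eff, ms_error, n_total),
            )
        )

    return AnovaReport(
        response_name=data.response_name,
        factor_names=data.factor_names,
        effects=tuple(effects),
        ss_error=ss_error,
        df_error=df_error,
        ms_error=ms_error,
        ss_total=ss_total,
        shapiro=sw,
        levene=lv,
        alpha=alpha,
    )


def build_effects_table(
    reports: Sequence[AnovaReport] | Mapping[str, AnovaReport],
    alpha: float = ALPHA_DEFAULT,
    large_effect_threshold: float = LARGE_EFFECT_DEFAULT,
) -> pd.DataFrame:
    """Assemble a publication-style effects table across responses.

    One row per response; per effect, columns ``<effect>_p`` and
    ``<effect>_omega_g_sq`` plus significance/large-effect flags.  Following
    the reporting convention, omega-squared is shown only for significant
    effects (NaN otherwise) and negative estimates are displayed as 0.
    """
    if isinstance(reports, Mapping):
        reports = list(reports.values())
    rows = []
    for rep in reports:
        row: dict[str, object] = {"response": rep.response_name}
        for eff in rep.effects:
            sig = eff.p < alpha
            shown = max(eff.omega_g_sq, 0.0) if sig and not math.isnan(eff.omega_g_sq) else math.nan
            row[f"{eff.name}_p"] = eff.p
            row[f"{eff.name}_omega_g_sq"] = shown
            row[f"{eff.name}_significant"] = sig
            row[f"{eff.name}_large_effect"] = bool(
                sig and not math.isnan(shown) and shown > large_effect_threshold
            )
        rows.append(row)
    return pd.DataFrame(rows)
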
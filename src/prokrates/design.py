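"""Factorial microcosm design descriptions.

Both experiments are balanced 2x2 factorial designs: two manipulated factors
at two levels (ambient / elevated), three replicate units per treatment,
incubated for two days.  Treatments are labelled by the elevated factors:
``control``, ``<A>``, ``<B>``, ``<A>+<B>``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Treatment:
    """One treatment cell: which factors are at their elevated level."""

    label: str
    a_high: bool
    b_high: bool


@dataclass(frozen=True)
class MicrocosmDesign:
    """A balanced two-factor microcosm experiment layout."""

    name: str
    factor_names: tuple[str, str]
    replicates: int = 3
    incubation_days: float = 2.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.incubation_days > 0:
            raise ValueError("incubation_days must be > 0")

    @property
    def treatments(self) -> tuple[Treatment, ...]:
        a, b = self.factor_names
        return (
            Treatment("control", False, False),
            Treatment(a, True, False),
            Treatment(b, False, True),
            Treatment(f"{a}+{b}", True, True),
        )

    @property
    def treatment_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.treatments)

    def treatment(self, label: str) -> Treatment:
        for t in self.treatments:
            if t.label == label:
                return t
        raise KeyError(f"unknown treatment label {label!r}")
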
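"""Simulation-plan accounting with exact rational arithmetic.

Cumulative sampling times are bookkeeping over (systems x states x replicas x
replica length) and must reproduce printed totals exactly, so all arithmetic
runs on :class:`fractions.Fraction` — no float drift at the reported precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd


@dataclass(frozen=True)
class PlanEntry:
    system: str
    n_states: int
    n_replicas: int
    length_us: Fraction

    def __post_init__(self) -> None:
        if self.n_states <= 0 or self.n_replicas <= 0:
            raise ValueError(f"plan entry {self.system!r}: counts must be positive")
        if self.length_us <= 0:
            raise ValueError(f"plan entry {self.system!r}: replica length must be > 0")

    @property
    def total_us(self) -> Fraction:
        return Fraction(self.n_states) * self.n_replicas * self.length_us


@dataclass
class SimulationPlan:
    entries: list[PlanEntry]

    @classmethod
    def from_tuples(cls, rows) -> "SimulationPlan":
        """Build from (system, n_states, n_replicas, length_us) tuples.

        Lengths given as float or str are converted exactly via their decimal
        representation.
        """
        entries = [
            PlanEntry(str(s), int(ns), int(nr), Fraction(str(l)))
            for s, ns, nr, l in rows
        ]
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "SimulationPlan":
        df = pd.read_csv(path, dtype=str)
        required = {"system", "n_states", "n_replicas", "length_us"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"plan CSV missing columns: {sorted(missing)}")
        return cls.from_tuples(
            df[["system", "n_states", "n_replicas", "length_us"]].itertuples(index=False)
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                (e.system, e.n_states, e.n_replicas, str(e.length_us))
                for e in self.entries
            ],
            columns=["system", "n_states", "n_replicas", "length_us"],
        ).to_csv(path, index=False)

    def __add__(self, other: "SimulationPlan") -> "SimulationPlan":
        return SimulationPlan(self.entries + other.entries)


def plan_accounting(plan: SimulationPlan) -> dict:
    """Per-entry and cumulative sampling totals in microseconds (exact).

    Returns a dict with ``per_entry`` (system -> Fraction, aggregated over
    repeated system labels), ``cumulative`` (Fraction) and ``cumulative_us``
    (float convenience view).
    """
    per_entry: dict[str, Fraction] = {}
    total = Fraction(0)
    for e in plan.entries:
        per_entry[e.system] = per_entry.get(e.system, Fraction(0)) + e.total_us
        total += e.total_us
    return {"per_entry": per_entry, "cumulative": total, "cumulative_us": float(total)}
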
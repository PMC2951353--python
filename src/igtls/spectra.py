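"""Summary statistics over classified events: substitution spectra and rates.

The spectrum is the 4x4 ref-to-alt count table over substitutions of one
event category (PM by default); strands are not pooled, so G-to-A and C-to-T
are tallied separately and additionally reported as pooled G/C- and A/T-pair
classes.  The headline quantity is the proportion of transitions at G/C pairs
(G-to-A plus C-to-T) among non-templated substitutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .gcclass import EventCall

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero toward +inf (the printed-table style)."""
    scale = 10**ndigits
    return math.floor(x * scale + 0.5) / scale


@dataclass
class MutationSpectrum:
    """4x4 substitution count table (diagonal structurally zero)."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=int))

    def add(self, ref: str, alt: str, n: int = 1) -> None:
        if ref == alt:
            raise DataError("spectrum diagonal must stay zero")
        self.counts[_IDX[ref], _IDX[alt]] += n

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count(self, ref: str, alt: str) -> int:
        return int(self.counts[_IDX[ref], _IDX[alt]])

    @property
    def at_gc_pairs(self) -> int:
        """Substitutions whose parental base is G or C."""
        return int(self.counts[_IDX["G"]].sum() + self.counts[_IDX["C"]].sum())

    @property
    def at_at_pairs(self) -> int:
        return int(self.counts[_IDX["A"]].sum() + self.counts[_IDX["T"]].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(BASES), columns=list(BASES))

    def cell_rows(self) -> list[dict]:
        """The 12 off-diagonal cells with counts and percentage of the total."""
        rows = []
        total = self.total
        for r in BASES:
            for a in BASES:
                if r == a:
                    continue
                n = self.count(r, a)
                rows.append(
                    {
                        "ref": r,
                        "alt": a,
                        "count": n,
                        "percent": round_half_up(100.0 * n / total) if total else 0.0,
                    }
                )
        return rows


def tally_spectrum(events: Iterable[EventCall], category: str = "PM") -> MutationSpectrum:
    """Count substitutions of the filtered category; indels never contribute."""
    spec = MutationSpectrum()
    for ev in events:
        if ev.category != category:
            continue
        for m in ev.members:
            if m.kind == "substitution":
                spec.add(m.ref, m.alt)
    return spec


def gc_to_at_transition_percent(spectrum: MutationSpectrum) -> tuple[int, int, int]:
    """Proportion of transitions at G/C pairs among the tallied substitutions.

    Returns ``(percent, numerator, denominator)`` where the numerator is the
    G-to-A plus C-to-T count and the percentage is rounded half-up to an
    integer, matching the printed "48%"-style figures.
    """
    den = spectrum.total
    if den == 0:
        raise DataError("transition proportion undefined for an empty spectrum")
    num = spectrum.count("G", "A") + spectrum.count("C", "T")
    return int(round_half_up(100.0 * num / den)), num, den


@dataclass
class CategoryRates:
    """Per clone-set event counts and normalized rates.

    GC is counted once per conversion tract; PM and Amb once per mutation.
    """

    n_pm: int
    n_amb: int
    n_gc: int
    n_clones: int
    clone_length: int

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise DataError("rates require n_clones >= 1")
        if min(self.n_pm, self.n_amb, self.n_gc) < 0:
            raise DataError("negative event count")

    def per_clone(self, category: str) -> float:
        return {"PM": self.n_pm, "AMB": self.n_amb, "GC": self.n_gc}[category] / self.n_clones

    def per_kb(self, category: str) -> float:
        total_kb = self.n_clones * self.clone_length / 1000.0
        return {"PM": self.n_pm, "AMB": self.n_amb, "GC": self.n_gc}[category] / total_kb

    def rows(self) -> list[dict]:
        return [
            {
                "category": c,
                "count": {"PM": self.n_pm, "AMB": self.n_amb, "GC": self.n_gc}[c],
                "n_clones": self.n_clones,
                "clone_length": self.clone_length,
                "per_clone": self.per_clone(c),
                "per_kb": self.per_kb(c),
            }
            for c in ("PM", "AMB", "GC")
        ]


def category_rates(
    events_by_clone: Mapping[str, Sequence[EventCall]],
    clone_length: int,
    n_clones: int | None = None,
) -> CategoryRates:
    """Aggregate event counts over a clone set into rates.

    ``n_clones`` defaults to the number of clones present (pass it explicitly
    when some clones carried zero events but were sequenced).
    """
    n_clones = n_clones if n_clones is not None else len(events_by_clone)
    n_pm = n_amb = n_gc = 0
    for events in events_by_clone.values():
        for ev in events:
            if ev.category == "PM":
                n_pm += len(ev.members)
            elif ev.category == "AMB":
                n_amb += len(ev.members)
            else:
                n_gc += 1
    return CategoryRates(n_pm, n_amb, n_gc, n_clones, clone_length)
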
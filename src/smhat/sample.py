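"""Sampling-frame arithmetic for a pan-region audit.

The sampling frame for a national audit is one primary and one secondary
menu per local authority plus every school that organises its own catering;
coverage is the share of that population actually located and analysed.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._rounding import round_half_up_int


def study_population(n_las: int, n_school_organised: int) -> int:
    """Target population: one primary + one secondary menu per LA, plus
    school-organised provisions."""
    if n_las < 0 or n_school_organised < 0:
        raise ValueError("counts must be non-negative")
    return 2 * n_las + n_school_organised


def coverage_percent(n_analysed: int, n_population: int) -> int:
    """Share of the population analysed, as a whole percentage (half-up)."""
    if n_population <= 0:
        raise ValueError("population must be positive")
    if not 0 <= n_analysed <= n_population:
        raise ValueError("n_analysed must be between 0 and the population size")
    return round_half_up_int(100 * n_analysed / n_population)


@dataclass(frozen=True)
class SampleFrame:
    """Audit sampling frame: population, attrition and coverage."""

    n_las: int
    n_school_organised: int
    n_unlocatable: int = 0

    @property
    def population(self) -> int:
        return study_population(self.n_las, self.n_school_organised)

    @property
    def n_analysed(self) -> int:
        return self.population - self.n_unlocatable

    @property
    def coverage(self) -> int:
        return coverage_percent(self.n_analysed, self.population)
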
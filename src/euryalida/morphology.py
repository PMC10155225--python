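"""Species-level arm-morphology summaries.

Covers the recording rules for literature-derived fork counts (an "at least
n forks" report is entered as n + 1 and flagged as a lower bound), the
basal/distal classification of where the first fork sits on the arm, the
fork-count histogram and fork-vs-segment means behind the branching
bimodality argument, and the census of multi-armed (> 5 arms) species.

Segment counts to the first fork are developmentally fixed: new arm
segments are added subterminally (the Ocular Plate Rule), so the count does
not drift with body size and is comparable across literature records of
different-sized specimens.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional

import pandas as pd

from .characters import CharacterMatrix

__all__ = [
    "ForkRecord", "ForkHistogram", "parse_fork_count", "classify_pattern",
    "fork_histogram", "segments_by_forkcount", "multiarm_census",
    "check_bimodality", "fork_records_from_matrix",
]

#: first fork at or beyond this many segments counts as distal branching
DEFAULT_DISTAL_THRESHOLD = 10


@dataclass(frozen=True)
class ForkRecord:
    """Arm-branching data for one species."""

    species: str
    max_forks: Optional[int]
    forks_is_lower_bound: bool = False
    segments_to_first_fork: Optional[int] = None
    pattern: str = "none"

    def check(self) -> list[str]:
        problems = []
        if self.max_forks is not None:
            if (self.max_forks == 0) != (self.pattern == "none"):
                problems.append(
                    f"{self.species}: max_forks={self.max_forks} inconsistent "
                    f"with pattern={self.pattern!r}")
        if self.segments_to_first_fork is not None and self.max_forks == 0:
            problems.append(
                f"{self.species}: segments_to_first_fork given but no forks")
        return problems


_FORK_RE = re.compile(r"^\s*(>=)?\s*(\d+)\s*$")


def parse_fork_count(raw: str) -> tuple[int, bool]:
    """Parse a literature fork-count token such as ``"7"`` or ``">=12"``.

    A source reporting "at least n forks" is recorded as n + 1 with the
    lower-bound flag set; a plain count is taken at face value.
    """
    m = _FORK_RE.match(str(raw))
    if not m:
        raise ValueError(f"unparseable fork count {raw!r}")
    n = int(m.group(2))
    if m.group(1):
        return n + 1, True
    return n, False


def classify_pattern(segments_to_first_fork: int,
                     threshold: int = DEFAULT_DISTAL_THRESHOLD) -> str:
    """Classify a first-fork position as basal or distal branching.

    Basal branching puts the first fork within, at, or just beyond the disc
    margin — few arm segments; distal branching puts it far out on the arm.
    The cut-off is configurable; the default of 10 segments sits at the
    bottom of the observed distal range.
    """
    if segments_to_first_fork < 1:
        raise ValueError("segments_to_first_fork must be >= 1")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return "distal" if segments_to_first_fork >= threshold else "basal"


@dataclass(frozen=True)
class ForkHistogram:
    """Fork-count histogram plus the tally of species lacking data."""

    counts: dict[int, int]
    n_missing: int

    @property
    def n_scored(self) -> int:
        return sum(self.counts.values())


def fork_histogram(records: Iterable[ForkRecord]) -> ForkHistogram:
    """Species count per maximal fork number; missing data tallied apart."""
    counts: dict[int, int] = defaultdict(int)
    missing = 0
    for r in records:
        if r.max_forks is None:
            missing += 1
        else:
            counts[r.max_forks] += 1
    return ForkHistogram(counts=dict(sorted(counts.items())), n_missing=missing)


def segments_by_forkcount(records: Iterable[ForkRecord]) -> dict[int, float]:
    """Mean of per-species maximal segments-to-first-fork, by fork count.

    Only records carrying both fields contribute; means are accumulated
    exactly over rationals before the final float conversion.
    """
    sums: dict[int, Fraction] = defaultdict(Fraction)
    ns: dict[int, int] = defaultdict(int)
    for r in records:
        if r.max_forks is None or r.segments_to_first_fork is None:
            continue
        sums[r.max_forks] += r.segments_to_first_fork
        ns[r.max_forks] += 1
    return {k: float(sums[k] / ns[k]) for k in sorted(sums)}


def multiarm_census(matrix: CharacterMatrix) -> pd.DataFrame:
    """Census of species with more than five arms.

    Returns species-rank records with ``n_arms_max > 5``, sorted by family
    then name, with the exceptional-case flag (dubious or single-specimen
    reports) carried through so they can be listed apart.
    """
    rows = [
        {
            "species": r.taxon_name,
            "family": r.family,
            "n_arms_min": r.n_arms_min,
            "n_arms_max": r.n_arms_max,
            "branched": r.branched,
            "pattern": r.pattern,
            "exceptional": r.exceptional,
        }
        for r in matrix
        if r.rank == "species" and (r.n_arms_max or 0) > 5
    ]
    df = pd.DataFrame(rows, columns=["species", "family", "n_arms_min",
                                     "n_arms_max", "branched", "pattern",
                                     "exceptional"])
    return df.sort_values(["family", "species"], kind="stable").reset_index(drop=True)


def check_bimodality(records: Iterable[ForkRecord],
                     basal_min_forks: int = 8,
                     distal_max_forks: int = 10) -> list[str]:
    """Validate the bimodal branching structure on a species table.

    Where fork data exist, basally-branching species are expected to carry
    many forks (>= 8) and distally-branching species few (<= 10); the
    returned list names the violations (empty = consistent).
    """
    problems = []
    for r in records:
        if r.max_forks is None:
            continue
        if r.pattern == "basal" and r.max_forks < basal_min_forks:
            problems.append(
                f"{r.species}: basal branching with only {r.max_forks} forks")
        if r.pattern == "distal" and r.max_forks > distal_max_forks:
            problems.append(
                f"{r.species}: distal branching with {r.max_forks} forks")
    return problems


def fork_records_from_matrix(matrix: CharacterMatrix) -> list[ForkRecord]:
    """Expand a richness matrix into per-species fork records.

    Genus- and clade-level rows contribute ``species_count`` records each.
    Unbranched taxa yield zero-fork records; branched taxa with no recorded
    fork count yield records with missing fork data, so the histogram's
    missing tally stays honest.
    """
    records = []
    for r in matrix:
        for i in range(r.species_count):
            name = r.taxon_name if r.species_count == 1 else f"{r.taxon_name}_{i + 1}"
            if r.branched is False:
                forks: Optional[int] = 0
            else:
                forks = r.max_forks
            records.append(ForkRecord(
                species=name,
                max_forks=forks,
                forks_is_lower_bound=r.forks_is_lower_bound,
                segments_to_first_fork=r.segments_to_first_fork,
                pattern=r.pattern or "none",
            ))
    return records
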
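"""Taxon records, character matrices and their TSV round trip.

A :class:`TaxonRecord` is one row of the character census: a tip of the
cladogram (genus- or clade-level, with described species aggregated into
``species_count``), an unplaced (*incertae sedis*) taxon excluded from
tree-based comparisons, or a species-level morphology row.  Binary traits
are tri-state: ``True`` / ``False`` / ``None`` (unknown).

The matrix validates record-level invariants on load and cross-references
against a tree on demand; loading goes through :func:`pandas.read_csv`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields
from typing import Iterable, Iterator, Optional, Union

import pandas as pd

from .errors import CharacterTableError, MissingTaxonError
from .tree import Tree

__all__ = [
    "TaxonRecord", "CharacterMatrix", "ValidationReport",
    "read_character_table", "write_character_table",
    "states_from_matrix", "pattern_map", "validate",
]

RANKS = ("species", "genus", "clade")
PATTERNS = ("none", "basal", "distal")

#: column order of the canonical TSV representation
COLUMNS = [
    "taxon_name", "rank", "family", "species_count", "branched", "pattern",
    "pedicellariae", "placed", "n_arms_min", "n_arms_max", "max_forks",
    "forks_is_lower_bound", "segments_to_first_fork", "genera_count",
    "exceptional",
]


@dataclass(frozen=True)
class TaxonRecord:
    """One census row: a taxon with its richness and trait states.

    ``branched``/``pedicellariae`` use ``None`` for unknown; ``pattern`` is
    one of ``none``/``basal``/``distal`` or ``None`` for unknown.  ``placed``
    is False for *incertae sedis* taxa, which never appear as tree tips.
    ``genera_count`` is the number of described genera a clade-level row
    aggregates (used only for family tallies); species-level rows leave it
    unset and are tallied by the genus part of their name.
    """

    taxon_name: str
    rank: str
    family: str
    species_count: int
    branched: Optional[bool] = None
    pattern: Optional[str] = None
    pedicellariae: Optional[bool] = None
    placed: bool = True
    n_arms_min: Optional[int] = None
    n_arms_max: Optional[int] = None
    max_forks: Optional[int] = None
    forks_is_lower_bound: bool = False
    segments_to_first_fork: Optional[int] = None
    genera_count: Optional[int] = None
    exceptional: bool = False

    def check(self) -> list[str]:
        """Return human-readable invariant violations (empty = valid)."""
        problems = []
        if not self.taxon_name:
            problems.append("empty taxon_name")
        if self.rank not in RANKS:
            problems.append(f"unknown rank {self.rank!r}")
        if self.pattern is not None and self.pattern not in PATTERNS:
            problems.append(f"unknown pattern token {self.pattern!r}")
        if self.species_count < 1:
            problems.append(f"species_count {self.species_count} < 1")
        if self.branched is False:
            if self.pattern not in (None, "none"):
                problems.append(
                    f"branched=false but pattern={self.pattern!r}")
            if self.max_forks not in (None, 0):
                problems.append(
                    f"branched=false but max_forks={self.max_forks}")
        if self.pattern in ("basal", "distal") and self.branched is not True:
            problems.append(
                f"pattern={self.pattern!r} requires branched=true")
        if self.segments_to_first_fork is not None:
            if self.segments_to_first_fork < 1:
                problems.append("segments_to_first_fork < 1")
        for name in ("n_arms_min", "n_arms_max"):
            value = getattr(self, name)
            if value is not None and value < 1:
                problems.append(f"{name} {value} < 1")
        if self.max_forks is not None and self.max_forks < 0:
            problems.append(f"max_forks {self.max_forks} < 0")
        return problems

    @property
    def genus(self) -> str:
        """Genus part of a species-level name (``Genus_species``)."""
        return self.taxon_name.split("_", 1)[0]


class CharacterMatrix:
    """Ordered collection of :class:`TaxonRecord`, indexed by name."""

    def __init__(self, records: Iterable[TaxonRecord]):
        self.records: list[TaxonRecord] = list(records)
        self._index: dict[str, TaxonRecord] = {}
        problems: list[str] = []
        for i, record in enumerate(self.records, start=1):
            if record.taxon_name in self._index:
                problems.append(f"row {i}: duplicate taxon {record.taxon_name!r}")
            self._index[record.taxon_name] = record
            problems.extend(f"row {i}: {p}" for p in record.check())
        if problems:
            rows = sorted({int(p.split()[1].rstrip(":")) for p in problems})
            raise CharacterTableError(
                "invalid character table:\n  " + "\n  ".join(problems), rows)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TaxonRecord]:
        return iter(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> TaxonRecord:
        try:
            return self._index[name]
        except KeyError:
            raise MissingTaxonError(name) from None

    @property
    def placed_names(self) -> list[str]:
        return [r.taxon_name for r in self.records if r.placed]

    def family(self, name: str, placed: Optional[bool] = None) -> list[TaxonRecord]:
        """Records of one family, optionally filtered by placement."""
        return [r for r in self.records
                if r.family == name and (placed is None or r.placed == placed)]

    def richness(self, names: Iterable[str]) -> int:
        return sum(self[n].species_count for n in names)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({f.name: getattr(r, f.name) for f in fields(TaxonRecord)})
        return pd.DataFrame(rows, columns=COLUMNS)


# -- TSV round trip --------------------------------------------------------

_BOOL_TOKENS = {"true": True, "false": False, "unknown": None, "na": None}


def _parse_tristate(token: str, column: str, row: int, problems: list[str]):
    t = str(token).strip().lower()
    if t in _BOOL_TOKENS:
        return _BOOL_TOKENS[t]
    problems.append(f"row {row}: unknown {column} token {token!r}")
    return None


def _parse_optional_int(token, column: str, row: int, problems: list[str]):
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return None
    t = str(token).strip()
    if t.upper() in ("", "NA"):
        return None
    try:
        return int(float(t))
    except ValueError:
        problems.append(f"row {row}: non-numeric {column} {token!r}")
        return None


def read_character_table(source: Union[str, io.IOBase]) -> CharacterMatrix:
    """Read a character table from a TSV path, file object or literal text.

    The header must carry the :data:`COLUMNS` names (``genera_count`` and
    ``exceptional`` are optional); ``NA`` marks absent optional fields and
    ``unknown`` an unscored binary trait.  Invariant violations are
    collected and raised together as :class:`CharacterTableError` listing
    the offending row numbers.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS[:13] if c not in df.columns]
    if missing:
        raise CharacterTableError(f"missing columns: {missing}")
    problems: list[str] = []
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        pattern = str(d["pattern"]).strip().lower()
        if pattern in ("na", "unknown", ""):
            pattern = None
        records.append(TaxonRecord(
            taxon_name=str(d["taxon_name"]).strip(),
            rank=str(d["rank"]).strip().lower(),
            family=str(d["family"]).strip(),
            species_count=_parse_optional_int(
                d["species_count"], "species_count", i, problems) or 0,
            branched=_parse_tristate(d["branched"], "branched", i, problems),
            pattern=pattern,
            pedicellariae=_parse_tristate(
                d["pedicellariae"], "pedicellariae", i, problems),
            placed=bool(_parse_tristate(d["placed"], "placed", i, problems)),
            n_arms_min=_parse_optional_int(d["n_arms_min"], "n_arms_min", i, problems),
            n_arms_max=_parse_optional_int(d["n_arms_max"], "n_arms_max", i, problems),
            max_forks=_parse_optional_int(d["max_forks"], "max_forks", i, problems),
            forks_is_lower_bound=_parse_tristate(
                d["forks_is_lower_bound"], "forks_is_lower_bound", i, problems) or False,
            segments_to_first_fork=_parse_optional_int(
                d["segments_to_first_fork"], "segments_to_first_fork", i, problems),
            genera_count=_parse_optional_int(
                d.get("genera_count"), "genera_count", i, problems),
            exceptional=_parse_tristate(
                d.get("exceptional", "false"), "exceptional", i, problems) or False,
        ))
    seen: set[str] = set()
    for i, record in enumerate(records, start=1):
        problems.extend(f"row {i}: {p}" for p in record.check())
        if record.taxon_name in seen:
            problems.append(f"row {i}: duplicate taxon {record.taxon_name!r}")
        seen.add(record.taxon_name)
    if problems:
        rows = sorted({int(p.split()[1].rstrip(":")) for p in problems})
        raise CharacterTableError(
            "invalid character table:\n  " + "\n  ".join(problems), rows)
    return CharacterMatrix(records)


def _format(value) -> str:
    if value is None:
        return "NA"
    if value is True:
        return "true"
    if value is False:
        return "false"
    return str(value)


def write_character_table(matrix: CharacterMatrix, path=None) -> Optional[str]:
    """Write the matrix as TSV; return the text when ``path`` is None."""
    lines = ["\t".join(COLUMNS)]
    for r in matrix:
        lines.append("\t".join(_format(getattr(r, c)) for c in COLUMNS))
    text = "\n".join(lines) + "\n"
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)
    return None


# -- cross-referencing -----------------------------------------------------


@dataclass
class ValidationReport:
    """Outcome of cross-validating a tree against a matrix."""

    messages: list[str] = field(default_factory=list)
    trait_coverage: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.messages

    def __str__(self) -> str:
        if self.ok:
            return "tree and character matrix are consistent"
        return "\n".join(self.messages)


def validate(tree: Tree, matrix: CharacterMatrix) -> ValidationReport:
    """Cross-check tree tips against placed records.

    The report lists tips without a record and placed records that are not
    tips, plus the fraction of placed taxa scored (non-unknown) for each
    binary trait.  An empty message list means the inputs are consistent.
    """
    report = ValidationReport()
    tips = set(tree.tip_labels())
    placed = set(matrix.placed_names)
    for tip in sorted(tips - placed):
        report.messages.append(f"tip {tip!r} unmatched by any placed record")
    for name in sorted(placed - tips):
        report.messages.append(f"{name!r} placed but not a tip")
    n_placed = len(placed) or 1
    for trait in ("branched", "pedicellariae"):
        scored = sum(1 for r in matrix if r.placed and getattr(r, trait) is not None)
        report.trait_coverage[trait] = scored / n_placed
    scored = sum(1 for r in matrix if r.placed and r.pattern is not None)
    report.trait_coverage["pattern"] = scored / n_placed
    return report


def states_from_matrix(matrix: CharacterMatrix, trait: str) -> dict[str, frozenset[int]]:
    """Tip-state map for a binary trait over placed records.

    State 1 encodes the derived condition (branched arms, or pedicellariae
    present); unknowns map to the full state set ``{0, 1}``.
    """
    if trait not in ("branched", "pedicellariae"):
        raise ValueError(f"unknown binary trait {trait!r}")
    out = {}
    for r in matrix:
        if not r.placed:
            continue
        value = getattr(r, trait)
        if value is None:
            out[r.taxon_name] = frozenset({0, 1})
        else:
            out[r.taxon_name] = frozenset({int(value)})
    return out


def pattern_map(matrix: CharacterMatrix) -> dict[str, Optional[str]]:
    """Branching pattern (none/basal/distal or None) per placed taxon."""
    return {r.taxon_name: r.pattern for r in matrix if r.placed}
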
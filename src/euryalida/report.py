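"""Consolidated analysis report: tallies, origin counts, comparisons, tests.

:func:`analyze` wires the whole pipeline together on one tree + census:
cross-validation, parsimony origin counting for both traits, sister-pair
extraction at whole-order and per-family scope, the distal-branching
sub-comparisons, and the sign tests.  The JSON report is canonical and
deterministic for fixed inputs; TSV mirrors of the comparison and census
tables are emitted alongside for eyeball diffing against published tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .characters import (CharacterMatrix, pattern_map, read_character_table,
                         states_from_matrix, validate)
from .morphology import multiarm_census
from .parsimony import MPRSummary, mpr_gain_range
from .sign_test import sign_test
from .sister import (DistalComparisons, SisterPair, build_sister_pairs,
                     distal_subcomparisons, pairs_to_tsv)
from .tree import Tree, parse_newick

__all__ = ["AnalysisConfig", "AnalysisReport", "tally_traits", "analyze",
           "write_report"]

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the standard analysis.

    ``class_total`` is the approximate number of living species in the
    whole class against which "percent of ophiuroids" figures are quoted;
    the derived percentages are labelled approximate in the report.
    """

    alpha: float = 0.05
    distal_threshold: int = 10
    class_total: int = 2100
    include_unplaced_family_richness: bool = True
    outgroup_family: str = "Ophiurida"

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "distal_threshold": self.distal_threshold,
            "class_total": self.class_total,
            "include_unplaced_family_richness":
                self.include_unplaced_family_richness,
            "outgroup_family": self.outgroup_family,
        }


def tally_traits(matrix: CharacterMatrix,
                 outgroup_family: str = "Ophiurida",
                 class_total: int = 2100) -> dict:
    """Per-family and overall species/genus/trait tallies.

    Unplaced records count fully here (unlike in tree-based comparisons):
    the tallies describe the fauna, not the cladogram.  The overall row
    aggregates every family except the outgroup's.
    """
    families: dict[str, dict] = {}
    for r in matrix.records:
        fam = families.setdefault(r.family, {
            "species": 0, "genera": 0, "branched": 0, "pedicellariae": 0,
            "snakestars": 0})
        fam["species"] += r.species_count
        if r.rank == "species":
            pass  # genera of species-rank rows counted once below
        elif r.genera_count is not None:
            fam["genera"] += r.genera_count
        else:
            fam["genera"] += 1
        if r.branched:
            fam["branched"] += r.species_count
        elif r.branched is False:
            fam["snakestars"] += r.species_count
        if r.pedicellariae:
            fam["pedicellariae"] += r.species_count
    for name, fam in families.items():
        genera = {r.genus for r in matrix.records
                  if r.family == name and r.rank == "species"}
        fam["genera"] += len(genera)
    overall = {"species": 0, "genera": 0, "branched": 0, "pedicellariae": 0,
               "snakestars": 0}
    for name, fam in families.items():
        if name == outgroup_family:
            continue
        for key in overall:
            overall[key] += fam[key]
    percent = {
        "branched": round(100.0 * overall["branched"] / class_total, 1),
        "pedicellariae": round(100.0 * overall["pedicellariae"] / class_total, 1),
        "class_total": class_total,
        "approximate": True,
    }
    return {"families": dict(sorted(families.items())),
            "overall": overall, "percent_of_class": percent}


def _summary_dict(s: MPRSummary) -> dict:
    return {"min_changes": s.min_changes, "gains_min": s.gains_min,
            "gains_max": s.gains_max, "losses_min": s.losses_min,
            "losses_max": s.losses_max}


def _pair_dict(p: SisterPair) -> dict:
    return {
        "focal": p.focal_label, "focal_tips": list(p.focal_tips),
        "focal_richness": p.focal_richness,
        "sister": p.sister_label, "sister_tips": list(p.sister_tips),
        "sister_richness": p.sister_richness,
        "outcome": p.outcome, "sister_is_mixed": p.sister_is_mixed,
        "family_scope": p.family_scope,
    }


@dataclass
class AnalysisReport:
    """Everything the standard analysis computes, JSON-serialisable."""

    tallies: dict
    origin_summaries: dict
    sister_pairs: dict
    distal: DistalComparisons
    sign_tests: dict
    validation_messages: list[str]
    provenance: dict
    multiarm: Optional[object] = None   # pandas DataFrame when supplied

    def to_dict(self) -> dict:
        out = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "provenance": self.provenance,
            "validation": self.validation_messages,
            "tallies": self.tallies,
            "origin_summaries": self.origin_summaries,
            "sister_pairs": {k: [_pair_dict(p) for p in v]
                             for k, v in self.sister_pairs.items()},
            "distal_subcomparisons": {
                "pairs": [_pair_dict(p) for p in self.distal.pairs],
                "unknown_sister": [
                    {"taxon": u.taxon_name, "species": u.species_count}
                    for u in self.distal.unplaced],
            },
            "sign_tests": {k: v.to_dict() for k, v in self.sign_tests.items()},
        }
        if self.multiarm is not None:
            out["multiarm_census"] = self.multiarm.to_dict(orient="records")
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          default=str)


def analyze(tree: Union[Tree, str, Path],
            chars: Union[CharacterMatrix, str, Path],
            config: Optional[AnalysisConfig] = None,
            multiarm: Union[CharacterMatrix, str, Path, None] = None
            ) -> AnalysisReport:
    """Run the full pipeline on a tree and character table.

    Accepts parsed objects or file paths.  Raises on an inconsistent
    tree/matrix pair (the validation messages become the error text).
    """
    config = config or AnalysisConfig()
    if not isinstance(tree, Tree):
        tree = parse_newick(Path(tree).read_text())
    if not isinstance(chars, CharacterMatrix):
        chars = read_character_table(str(chars))
    if multiarm is not None and not isinstance(multiarm, CharacterMatrix):
        multiarm = read_character_table(str(multiarm))

    report = validate(tree, chars)
    if not report.ok:
        raise ValueError("tree and character table disagree:\n" + str(report))

    branched = states_from_matrix(chars, "branched")
    pedicel = states_from_matrix(chars, "pedicellariae")
    patterns = pattern_map(chars)

    ingroup_families = sorted(
        {r.family for r in chars if r.family != config.outgroup_family})
    family_scopes = {}
    for family in ingroup_families:
        placed = [r.taxon_name for r in chars.family(family, placed=True)]
        if len(placed) >= 2:
            family_scopes[family] = tree.mrca(placed)

    origin_summaries = {
        "branched": _summary_dict(mpr_gain_range(tree, branched, root_state=0)),
        "pedicellariae": _summary_dict(
            mpr_gain_range(tree, pedicel, root_state=0)),
    }
    for family, node in family_scopes.items():
        origin_summaries[f"branched_{family}"] = _summary_dict(
            mpr_gain_range(tree, branched, root_state=0, scope=node))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sister_pairs = {
            "branched_all": build_sister_pairs(tree, branched, chars),
            "pedicellariae_all": build_sister_pairs(
                tree, pedicel, chars,
                include_unplaced_families=config.include_unplaced_family_richness),
        }
        for family, node in family_scopes.items():
            sister_pairs[f"branched_{family}"] = build_sister_pairs(
                tree, branched, chars, scope=node)
        distal = distal_subcomparisons(tree, patterns, chars)

    sign_tests = {}
    for key, pairs in sister_pairs.items():
        if pairs:
            sign_tests[key] = sign_test(pairs, alpha=config.alpha)

    tallies = tally_traits(chars, outgroup_family=config.outgroup_family,
                           class_total=config.class_total)

    provenance = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_tips": tree.n_tips,
        "n_records": len(chars),
    }

    return AnalysisReport(
        tallies=tallies,
        origin_summaries=origin_summaries,
        sister_pairs=sister_pairs,
        distal=distal,
        sign_tests=sign_tests,
        validation_messages=report.messages,
        provenance=provenance,
        multiarm=multiarm_census(multiarm) if multiarm is not None else None,
    )


def write_report(report: AnalysisReport, outdir: Union[str, Path]) -> dict:
    """Write report.json plus TSV table mirrors; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"report": outdir / "report.json"}
    paths["report"].write_text(report.to_json())
    paths["sister_pairs"] = outdir / "sister_pairs.tsv"
    paths["sister_pairs"].write_text(
        pairs_to_tsv(report.sister_pairs["branched_all"]))
    paths["distal_pairs"] = outdir / "distal_pairs.tsv"
    paths["distal_pairs"].write_text(
        pairs_to_tsv(report.distal.pairs, report.distal.unplaced))
    if report.multiarm is not None:
        paths["multiarm"] = outdir / "multiarm_census.tsv"
        report.multiarm.to_csv(paths["multiarm"], sep="\t", index=False)
    return paths
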
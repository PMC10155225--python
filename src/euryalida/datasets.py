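"""Packaged fixture data: the euryalidan cladogram and character census.

The cladogram is a genus-level composite of the published molecular trees
for the order, rooted on Ophiurida; the census aggregates described species
per tip and records the binary traits (branched arms, branching pattern,
pedicellariae), with *incertae sedis* gorgonocephalids carried as unplaced
rows.  A separate species-level table holds the multi-armed census.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .characters import CharacterMatrix, read_character_table
from .tree import Tree, parse_newick

__all__ = ["fixture_path", "load_tree", "load_characters", "load_multiarm"]

OUTGROUP = "Ophiurida"


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("euryalida.data") / name)


def load_tree() -> Tree:
    """The genus-level euryalidan cladogram, rooted on Ophiurida."""
    text = fixture_path("euryalida.nwk").read_text()
    return parse_newick(text, outgroup=OUTGROUP)


def load_characters() -> CharacterMatrix:
    """Per-tip species richness and trait states, plus unplaced taxa."""
    return read_character_table(str(fixture_path("euryalida_chars.tsv")))


def load_multiarm() -> CharacterMatrix:
    """Species-level census of multi-armed (> 5 arms) euryalidans."""
    return read_character_table(str(fixture_path("multiarm.tsv")))
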
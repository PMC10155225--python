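"""Exception types shared across the package."""


class EuryalidaError(Exception):
    """Base class for package-specific errors."""


class NewickParseError(EuryalidaError, ValueError):
    """Malformed Newick input (unbalanced parentheses, bad labels, ...)."""


class TreeStructureError(EuryalidaError, ValueError):
    """A node structure violates the rooted-tree invariants."""


class CharacterTableError(EuryalidaError, ValueError):
    """A character-table row violates the record invariants.

    Carries the offending row numbers (1-based, excluding the header) in
    ``rows`` when they are known.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class MissingTaxonError(EuryalidaError, KeyError):
    """A taxon required by an operation is absent from its input."""


class AllDerivedWarning(UserWarning):
    """The scope root itself is entirely in the derived state: no sister
    group exists and no comparison can be formed."""


class PolytomyWarning(UserWarning):
    """A sister group was taken as the union of co-siblings at a polytomy."""
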
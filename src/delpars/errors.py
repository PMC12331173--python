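"""Exception hierarchy for delpars.

Every user-facing failure mode maps to one of these classes so the CLI can
translate them into distinct exit codes.
"""


class DelparsError(Exception):
    """Base class for all delpars errors."""


class NewickError(DelparsError):
    """Malformed Newick input."""


class TreeStructureError(DelparsError):
    """Tree violates structural requirements (e.g. non-binary internal node)."""


class AlignmentFormatError(DelparsError):
    """Malformed alignment input (unequal rows, empty file, bad gap form...)."""


class AllZeroColumnError(AlignmentFormatError):
    """An interior alignment column contains only gaps.

    Such a column cannot be explained without inserting a character that no
    extant sequence retains, so the deletion-only model rejects it by default.
    """


class LeafMismatchError(DelparsError):
    """Tree leaf set and alignment row set differ."""


class EnumerationOverflowError(DelparsError):
    """Number of solutions/paths exceeds the configured cap."""


class InternalConsistencyError(DelparsError):
    """An algorithm invariant was violated; indicates a bug or bad state."""
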
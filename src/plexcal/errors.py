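"""Exception hierarchy.

All domain errors derive from :class:`PlexcalError` so callers (and the CLI)
can distinguish bad input from genuine bugs.
"""


class PlexcalError(Exception):
    """Base class for all plexcal domain errors."""


class InputError(PlexcalError):
    """A value violates an operation's precondition."""


class CompositionError(InputError):
    """A sequence contains a character outside the plain {A,C,G,T} alphabet."""

    def __init__(self, position: int, character: str, message: str | None = None):
        self.position = position
        self.character = character
        super().__init__(
            message
            or f"invalid base {character!r} at position {position} "
            "(plain A/C/G/T expected; degenerate codes are not allowed here)"
        )


class AlphabetError(InputError):
    """A sequence contains a character outside the IUPAC DNA alphabet."""


class LinkageError(InputError):
    """Records that must refer to the same entity do not."""


class PlanningError(PlexcalError):
    """A dilution target cannot be reached under the stated constraints."""


class ExtrapolationError(PlexcalError):
    """A pipetted volume falls outside the error model's calibrated range."""


class SchemaError(InputError):
    """A tabular input violates its schema (columns, duplicates, emptiness)."""


class DegeneracyError(InputError):
    """A degenerate primer expands to more variants than the configured cap."""


class ComparabilityError(InputError):
    """Two dilution plans with different total factors cannot be ranked."""


class CoverageError(InputError):
    """A requested summary slice is missing readings for some target."""
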
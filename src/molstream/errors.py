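"""Exception hierarchy for molstream.

Everything raised on purpose derives from :class:`MolstreamError`, so callers
(the CLI in particular) can distinguish data problems from programming bugs.
"""

from __future__ import annotations


class MolstreamError(Exception):
    """Base class for all molstream errors."""


class ParseError(MolstreamError):
    """A Molfile entry could not be parsed.

    Parameters
    ----------
    message:
        Human-readable description.
    stage:
        Short tag naming the failing parse stage, e.g. ``"counts"``,
        ``"version"``, ``"truncated block"``, ``"atom"``, ``"bond"``.
    entry_index:
        1-based index of the entry within its source, when known.
    row:
        1-based row within the failing block, when applicable.
    """

    def __init__(self, message: str, *, stage: str = "parse",
                 entry_index: int | None = None, row: int | None = None):
        super().__init__(message)
        self.stage = stage
        self.entry_index = entry_index
        self.row = row


class StructuralIntegrityError(MolstreamError):
    """An operation received a molecule record violating its invariants."""


class ContainerError(MolstreamError):
    """Base class for record-container failures."""


class ContainerFormatError(ContainerError):
    """The file is not a molstream container (bad magic/version)."""


class ContainerCorruptionError(ContainerError):
    """A container record is truncated or undecodable.

    ``ordinal`` is the 1-based position of the unreadable record.
    """

    def __init__(self, message: str, *, ordinal: int | None = None):
        super().__init__(message)
        self.ordinal = ordinal


class ContainerStateError(ContainerError):
    """Operation on a handle in the wrong state (closed, wrong mode)."""


class FilterSpecError(MolstreamError):
    """A filter specification is malformed (e.g. bad regex, empty clauses)."""


class FixtureSpecError(MolstreamError):
    """A synthetic-data generation spec is invalid."""
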
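"""Exception hierarchy for the pisrank toolkit.

Every error raised deliberately by the library derives from
:class:`PisrankError`, so callers (and the CLI) can distinguish data
problems from programming errors.
"""


class PisrankError(Exception):
    """Base class for all pisrank errors."""


class StructureFormatError(PisrankError):
    """A structure file could not be parsed under the named standard."""


class EmptyStructureError(PisrankError):
    """A structure contains no polymer chains."""


class ConfidenceFormatError(PisrankError):
    """A confidence JSON document violates the dialect (shape, sign, range)."""


class JobSpecError(PisrankError):
    """A job-specification document failed validation."""


class TokenMappingError(PisrankError):
    """An interface residue could not be resolved to a PAE token."""


class ScoringError(PisrankError):
    """A model cannot be scored (e.g. empty interface and no pTM fallback)."""


class AlignmentError(PisrankError):
    """Paired inputs (scores, decisions, coordinate sets) do not align."""


class EvaluationError(PisrankError):
    """Model/reference comparison is impossible (unmappable chains, no contacts)."""
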
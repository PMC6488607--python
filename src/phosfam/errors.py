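"""Exception types shared across the package."""


class PhosfamError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhosfamError, ValueError):
    """An input file violates its format contract (raggedness, duplicate
    identifiers, malformed records)."""


class ValidationError(PhosfamError, ValueError):
    """Structurally well-formed data violates a semantic invariant
    (out-of-range coordinate, residue mismatch, infeasible placement)."""
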
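"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems exit 2,
numerical failures exit 3.
"""


class PSMAError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PSMAError, ValueError):
    """Malformed input file (wrong shape, bad header, unparseable body)."""


class ValidationError(PSMAError, ValueError):
    """Well-formed input that violates a domain invariant."""


class NumericalError(PSMAError, ArithmeticError):
    """Numerical failure (non-convergence, degenerate spectrum, ...)."""
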
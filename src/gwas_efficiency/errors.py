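"""Exception hierarchy shared across the package.

All package errors derive from :class:`GwasEfficiencyError` so callers can
catch one base class. The CLI maps these onto exit codes: input/validation
problems exit 2, degenerate computations exit 3.
"""


class GwasEfficiencyError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GwasEfficiencyError):
    """A summary-statistics file does not follow the expected schema."""


class ValidationError(GwasEfficiencyError):
    """Input values violate a domain invariant (e.g. p outside (0, 1])."""


class NoOverlapError(GwasEfficiencyError):
    """Two study panels share no loci, so pairing is impossible."""


class DegenerateError(GwasEfficiencyError):
    """A computation is undefined for the given input (e.g. xi = 0 in a ratio)."""
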
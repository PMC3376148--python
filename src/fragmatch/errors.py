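"""Exception hierarchy shared across fragmatch modules.

Every error carries a short machine-parsable ``code`` so the CLI can exit
nonzero with a stable identifier.
"""


class FragmatchError(Exception):
    """Base class for all fragmatch errors."""

    code = "error"


class DomainError(FragmatchError, ValueError):
    """An argument is outside the physically meaningful domain."""

    code = "domain"


class InsufficientDataError(FragmatchError):
    """Too few observations to perform the requested fit or statistic."""

    code = "insufficient-data"


class FitFailureError(FragmatchError):
    """Nonlinear regression failed to converge across all restarts."""

    code = "fit-failure"

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class BandDetectionError(FragmatchError):
    """Fewer resolvable ladder bands than requested."""

    code = "band-detection"

    def __init__(self, message, found_positions=None):
        super().__init__(message)
        self.found_positions = list(found_positions or [])


class NoSmearError(FragmatchError):
    """No smear apex above the prominence floor in a lane profile."""

    code = "no-smear"


class DegenerateNoiseError(FragmatchError):
    """Noise scale estimate is zero; interval scores are undefined."""

    code = "degenerate-noise"


class ParseError(FragmatchError):
    """Malformed input file; message names the offending line."""

    code = "parse"


class ValidationError(FragmatchError):
    """A record violates a type invariant."""

    code = "validation"
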
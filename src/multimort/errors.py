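"""Exception hierarchy for multimort.

All package errors derive from :class:`MultimortError` so callers can catch
one type at the CLI boundary.
"""


class MultimortError(Exception):
    """Base class for all multimort errors."""


class FormatError(MultimortError):
    """An input file does not conform to the expected dialect."""


class ValidationError(MultimortError):
    """Data violates an invariant (gaps, negative counts, missing bands...)."""


class ComputationError(MultimortError):
    """A quantity is undefined for the given inputs (e.g. expected deaths 0)."""


class ConfigError(MultimortError):
    """A run configuration is invalid; carries the list of violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))
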
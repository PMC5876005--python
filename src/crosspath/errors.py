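"""Exception hierarchy.

Input/validation problems (bad user data, bad config, malformed dumps) derive
from :class:`InputError` and map to CLI exit code 1; anything else escaping to
the CLI is an internal error (exit code 2).
"""


class CrosspathError(Exception):
    """Base class for all package errors."""


class InputError(CrosspathError):
    """User-supplied data or arguments are invalid."""


class ConfigError(InputError):
    """A configuration value is out of range or inconsistent."""


class DumpLoadError(InputError):
    """A source dump is missing a mandatory table or has a malformed header."""


class DumpValidationError(InputError):
    """A source dump has dangling references; carries per-row detail."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(self.violations[:10])
        if len(self.violations) > 10:
            msg += f" (+{len(self.violations) - 10} more)"
        super().__init__(f"{len(self.violations)} referential violation(s): {msg}")


class SerialOverflowError(CrosspathError):
    """The 9-digit serial space of an ID kind is exhausted."""
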
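"""Exception hierarchy for the mkftm pipeline.

Every stage raises a subclass of :class:`MKFTMError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class MKFTMError(Exception):
    """Base class for all mkftm errors."""


class InputError(MKFTMError):
    """A source file or argument is missing, unreadable, or malformed."""


class EmptyCorpusError(InputError):
    """The corpus contains no documents."""


class ConfigError(MKFTMError):
    """An invalid configuration value or unknown option name."""


class StateError(MKFTMError):
    """An operation was called on an object in the wrong state
    (e.g. counting terms of an unprocessed corpus)."""


class DegenerateInputError(MKFTMError):
    """Numerically degenerate input such as an all-zero document vector."""


class NumericError(MKFTMError):
    """Non-finite values or a singular matrix where one must be invertible."""


class UndefinedIndexError(MKFTMError):
    """A cluster validity index is undefined for the given partition."""
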
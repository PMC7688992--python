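"""Exception hierarchy.

Configuration problems (bad parameter values) and input problems (malformed
or inconsistent data) are kept distinct so callers can report them
differently; inference errors signal an analysis stage that cannot proceed.
"""


class VigornetError(Exception):
    """Base class for all package errors."""


class ConfigError(VigornetError):
    """A configuration value is invalid; the message names the field."""


class InputError(VigornetError):
    """Input data violate a precondition of an operation."""


class InferenceError(VigornetError):
    """A network-inference stage cannot run (e.g. no factors survive)."""
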
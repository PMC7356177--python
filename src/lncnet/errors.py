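"""Exception hierarchy used across the pipeline.

``FormatError`` and ``ConfigError`` are raised while reading inputs and
configuration, ``AnalysisError`` for violations of a stage's statistical
preconditions, and ``ParameterError`` for out-of-range arguments.
"""


class LncnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LncnetError):
    """A table or file does not follow its documented dialect."""


class ConfigError(LncnetError):
    """A configuration value or combination of values is invalid."""


class AnalysisError(LncnetError):
    """An analysis stage's preconditions are not met by its inputs."""


class ParameterError(LncnetError):
    """A function argument is outside its documented range."""
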
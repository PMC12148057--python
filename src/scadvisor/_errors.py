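"""Exception hierarchy.

User-facing errors (bad input, bad config, unparseable text) derive from
:class:`UserError` so the CLI can map them to exit code 2; everything else
is treated as an internal error (exit code 1).
"""


class ScAdvisorError(Exception):
    """Base class for all package errors."""


class UserError(ScAdvisorError):
    """An error attributable to user input or configuration."""


class DataError(UserError):
    """Malformed or inconsistent input data."""


class ConfigError(UserError):
    """Invalid backend or run configuration."""


class TemplateError(UserError):
    """Unknown template or unfilled placeholder."""


class ParseError(UserError):
    """LLM response text did not match the expected structure."""


class MetricError(UserError):
    """A metric precondition was not met."""


class BackendError(ScAdvisorError):
    """Backend dispatch failure (network, auth, empty completion)."""
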
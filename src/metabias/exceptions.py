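"""Exception hierarchy.

All package errors derive from :class:`MetaBiasError` so callers can catch
one base class; the CLI maps validation errors and runtime errors to
distinct exit codes.
"""


class MetaBiasError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(MetaBiasError):
    """Malformed user input (bad CSV rows, unknown method names, bad config)."""


class InvalidTableError(ValidationError):
    """A 2x2 table whose margins make the effect measure undefined."""


class DegenerateMetaError(MetaBiasError):
    """A meta-analysis whose pooled margins leave no information (e.g. no
    exposed subjects anywhere even after continuity correction)."""


class TooFewStudiesError(MetaBiasError):
    """Fewer than the minimum number of studies (3) required by a test."""


class CollinearDesignError(MetaBiasError):
    """The regression covariate is constant across studies, so the slope is
    not identifiable (e.g. all studies share the same arm sizes)."""


class RunawaySelectionError(MetaBiasError):
    """The publication-bias selection mechanism accepts almost nothing;
    guards against misconfigured selection rules."""


class ConfigError(ValidationError):
    """Invalid simulation or experiment configuration."""
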
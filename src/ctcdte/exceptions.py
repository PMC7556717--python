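"""Exception hierarchy for the ctcdte pipeline."""


class CtcDteError(Exception):
    """Base class for all ctcdte errors."""


class ValidationError(CtcDteError, ValueError):
    """A domain object violates one of its invariants."""


class FormatError(CtcDteError, ValueError):
    """An on-disk file does not conform to the expected layout or metadata."""


class ChannelLookupError(CtcDteError, KeyError):
    """A requested channel name is not present in a stack."""


class ConfigurationError(CtcDteError, ValueError):
    """Pipeline input is missing a required channel or setting."""


class DegenerateImageError(CtcDteError, ValueError):
    """An all-zero image for which the MT-DTE score is undefined.

    Degenerate cells are reported as missing scores, never as 0, so that
    they cannot contaminate per-timepoint means.
    """


class PlacementError(CtcDteError, RuntimeError):
    """A synthetic field is too small to place the requested cells."""


class DesignError(CtcDteError, ValueError):
    """A synthetic cohort design is internally inconsistent."""
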
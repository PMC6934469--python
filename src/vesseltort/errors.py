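"""Exception hierarchy for vesseltort.

All package errors derive from :class:`VesseltortError` so callers (and the
CLI) can catch domain failures without masking programming errors.
"""


class VesseltortError(Exception):
    """Base class for all vesseltort domain errors."""


class InvalidCenterlineError(VesseltortError):
    """A vessel centerline violates its invariants (too short, repeated points)."""


class AnnotationError(VesseltortError):
    """Per-vessel annotations (calibers, labels) are missing or malformed."""


class ContractViolationError(VesseltortError):
    """An operation received inputs outside its documented contract."""


class UndefinedScoreError(VesseltortError):
    """A retina-level score is undefined (no vessels, zero total weight)."""


class UndefinedStatisticError(VesseltortError):
    """A statistic is undefined for the given labels (e.g. a class absent)."""


class ConfigError(VesseltortError):
    """A configuration value is invalid or inconsistent."""


class VesselGraphError(VesseltortError):
    """The vessel-graph JSON file is malformed or violates its schema."""


class RatingsFormatError(VesseltortError):
    """The ratings CSV is malformed (missing raters, non-binary cells)."""
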
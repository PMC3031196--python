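"""Exception hierarchy for orassess."""


class OrassessError(Exception):
    """Base class for all orassess errors."""


class SchemaError(OrassessError):
    """A case-log file is missing required columns or is otherwise unreadable."""


class ValidationError(OrassessError):
    """A case log violates a structural invariant (e.g. overlapping cases in one OR)."""


class GenerationError(OrassessError):
    """The synthetic-data generator was asked for an impossible schedule."""


class ParameterError(OrassessError):
    """A facility parameter could not be derived from the available cases."""


class ManifestError(OrassessError):
    """The packaged scenario manifest fails its integrity checks."""


class BindingError(OrassessError):
    """A scenario placeholder cannot be bound from the facility profile."""


class RenderError(OrassessError):
    """A scenario body contains a placeholder with no binding."""
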
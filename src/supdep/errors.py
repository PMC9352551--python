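"""Exception hierarchy for the supernatant-depletion analysis pipeline."""


class SupdepError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SupdepError, ValueError):
    """A parameter violates its physical or numerical precondition."""


class InvalidAffinityError(InvalidInputError):
    """A dissociation constant that is not a positive finite molar value."""


class MissingControlError(SupdepError, ValueError):
    """No usable no-ligand control intensity (I at [L]=0 must be > 0)."""


class BelowDetectionError(SupdepError):
    """Fraction bound at or below zero: the interaction is not detectable."""


class SaturationError(SupdepError):
    """Fraction bound at or above one: the receptor is fully depleted and
    the closed-form Kd is undefined."""


class DepletionInconsistencyError(SupdepError, ValueError):
    """The implied complex concentration exceeds the total ligand: the
    measurement is physically inconsistent with the stated concentrations."""


class InsufficientDataError(SupdepError, ValueError):
    """Fewer replicates than the requested statistic needs."""


class AllBelowDetectionError(BelowDetectionError):
    """Every replicate in an experiment is below the detection limit."""


class SchemaError(SupdepError, ValueError):
    """A delimited intensity table or config does not match the schema."""
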
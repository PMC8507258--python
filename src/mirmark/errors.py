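"""Exception types shared across the package."""


class MirmarkError(ValueError):
    """Base class for all domain errors raised by mirmark."""


class ValidationError(MirmarkError):
    """An input table or configuration violates a structural invariant."""


class CollisionError(MirmarkError):
    """Two distinct input identifiers canonicalize to the same name."""
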
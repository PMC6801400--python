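"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input object or parameter violates a documented contract."""


class EmptyAcceptanceError(RuntimeError):
    """A sampler finished without a single accepted network/signature.

    Raised instead of returning an empty posterior so callers are forced
    to either lower the acceptance threshold or draw more candidates.
    """
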
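"""Exception types shared across the package."""


class SpecificationError(ValueError):
    """A model or cohort specification is malformed or not identified."""


class ConvergenceWarning(UserWarning):
    """An optimizer finished without meeting the convergence tolerance."""
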
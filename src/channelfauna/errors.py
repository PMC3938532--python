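"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A run or generator configuration is invalid."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate (e.g. all-zero probability)."""
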
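"""Exception types shared across melanokit modules."""


class ParameterError(ValueError):
    """A specification or configuration value violates its constraints."""


class FitError(RuntimeError):
    """A model fit could not be completed; the message carries diagnostics."""
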
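class ValidationError(ValueError):
    """Raised when an input violates a physical or protocol invariant.

    Raised before any computation touches the offending row, so a failed
    run never leaves partially reduced output for that table.
    """
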
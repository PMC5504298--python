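class ValidationError(ValueError):
    """A session, epoch or parameter object violates one of its invariants."""
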
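"""Exception types shared across the toolkit."""


class SpecificationError(ValueError):
    """A synthetic-data specification violates its invariants."""


class SaturationError(ValueError):
    """A requested or observed divergence lies at or beyond Jukes-Cantor
    saturation (proportion of differences >= 3/4), where the correction
    is undefined."""


class InputError(ValueError):
    """Malformed or inconsistent user input (sequences, tables, files)."""
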
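"""Exception types raised across the analysis layer."""


class ConfigurationError(ValueError):
    """Invalid cohort or pipeline configuration."""


class AlignmentError(ValueError):
    """Inputs that must share a sample or feature axis do not."""


class DegenerateTableError(ValueError):
    """A contingency table with an empty margin."""


class FormatError(ValueError):
    """A malformed input file."""
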
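"""Exception hierarchy for medrelex."""


class MedRelError(Exception):
    """Base class for all medrelex errors."""


class ConfigurationError(MedRelError):
    """A backend, resource, or config key is missing or invalid."""


class DataFormatError(MedRelError):
    """An input file (corpus, lexicon, config) is malformed."""


class IntegrityError(MedRelError):
    """An internal invariant was violated (e.g. matched word indices out of range)."""
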
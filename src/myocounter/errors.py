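"""Exception hierarchy shared across the pipeline."""


class MyocounterError(Exception):
    """Base class for all pipeline errors."""


class RCCFormatError(MyocounterError):
    """An RCC file violates the expected section/record layout."""


class RCCParseError(MyocounterError):
    """A field inside an RCC file could not be parsed."""


class ValidationError(MyocounterError):
    """Inputs are structurally valid but inconsistent with each other."""
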
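"""Exception types shared across nucint."""


class NucintError(Exception):
    """Base class for all nucint errors."""


class ConfigurationError(NucintError, ValueError):
    """A simulation or analysis configuration violates an invariant.

    The message always names the offending field.
    """


class TableFormatError(NucintError, ValueError):
    """A delimited input table violates the column or value contract.

    Where possible the message names the 1-based data row.
    """


class GenerationError(NucintError, RuntimeError):
    """Synthetic data could not be generated under the requested geometry."""


class BaitNotDetectedError(NucintError, ValueError):
    """The bait protein is absent from an IP sample, so IP efficiency is undefined."""
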
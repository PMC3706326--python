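"""Exception types shared across the package."""


class BimodulesError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BimodulesError, ValueError):
    """An input file does not conform to the expected format."""


class ValidationError(BimodulesError, ValueError):
    """Inputs are well-formed but violate a contract (bounds, emptiness, ...)."""


class UnknownNodeError(BimodulesError, KeyError):
    """A node id was not found in the network."""


class InfeasibleCompositionError(BimodulesError, RuntimeError):
    """No connected node set with the requested composition could be sampled."""
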
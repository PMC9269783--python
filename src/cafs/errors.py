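"""Exception hierarchy. Everything raised on purpose derives from CafsError."""


class CafsError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(CafsError, ValueError):
    """Invalid or inconsistent configuration / specification."""


class ShapeError(CafsError, ValueError):
    """Array shape mismatch between cooperating tensors."""


class DataError(CafsError, ValueError):
    """Malformed dataset contents (missing files, non-binary masks, leakage)."""


class InfeasibleSplitError(CafsError, ValueError):
    """Fewer patients than non-empty splits requested."""


class ProtocolError(CafsError, RuntimeError):
    """Training-loop operations invoked out of order."""
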
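"""Exception types shared across the package."""


class LungDoseError(Exception):
    """Base class for all package errors."""


class ValidationError(LungDoseError, ValueError):
    """A physical or numerical precondition was violated."""


class StructuralError(LungDoseError, ValueError):
    """Airway-tree pieces do not fit together (generation gap/overlap, empty tree)."""


class ConfigurationError(LungDoseError, ValueError):
    """A run configuration is incomplete or inconsistent."""


class NumericalError(LungDoseError, RuntimeError):
    """The solver produced an out-of-tolerance state (negative mass, CFL blow-up)."""


class ParseError(LungDoseError, ValueError):
    """A data file does not match the declared dialect."""
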
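"""Exception hierarchy for fpcea."""


class FpceaError(Exception):
    """Base class for all fpcea errors."""


class SchemaError(FpceaError):
    """A parameter file or configuration violates the documented schema."""


class CalibrationError(FpceaError):
    """A distribution or model component could not be calibrated."""


class ModelError(FpceaError):
    """Invalid input to a model computation."""
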
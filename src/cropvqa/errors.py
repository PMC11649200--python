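"""Exception hierarchy shared across the package."""


class CropVQAError(Exception):
    """Base class for package errors."""


class ShapeError(CropVQAError, ValueError):
    """Tensor dimensions do not satisfy an operation's contract."""


class ConfigError(CropVQAError, ValueError):
    """Invalid configuration value."""


class InputError(CropVQAError, ValueError):
    """Invalid input data (non-finite values, out-of-range targets, ...)."""


class DegenerateInputError(CropVQAError, ValueError):
    """Structurally valid input on which the operation is undefined
    (e.g. attention over a fully masked key set)."""


class ContractError(CropVQAError, RuntimeError):
    """A runtime contract such as the gradient partition was violated."""
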
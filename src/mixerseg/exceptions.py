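"""Exception types shared across the package."""


class MixersegError(Exception):
    """Base class for package errors."""


class ShapeError(MixersegError, ValueError):
    """Tensor shapes are inconsistent with a block's contract."""


class ConfigurationError(MixersegError, ValueError):
    """A configuration value is invalid or inconsistent."""
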
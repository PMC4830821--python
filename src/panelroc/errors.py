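"""Exception hierarchy shared across the pipeline."""


class PanelROCError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(PanelROCError, ValueError):
    """An argument is outside its documented range."""


class DegenerateInputError(PanelROCError, ValueError):
    """Input lacks the structure the computation needs (e.g. one class only)."""


class ConfigurationError(PanelROCError, ValueError):
    """Panel configuration is inconsistent with the data supplied."""
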
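"""Exception and warning types shared across the package."""


class EphysyncError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(EphysyncError):
    """A dataset configuration could not be parsed or validated."""


class ConfigParseError(ConfigError):
    """The YAML document itself is malformed.

    ``line`` is the 1-based line number of the problem when the parser
    reports one, else ``None``.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigValidationError(ConfigError):
    """A well-formed block violates the schema.

    Always names the offending dataset and field so the user can find it
    in a multi-dataset file.
    """

    def __init__(self, dataset: str, field: str, message: str):
        self.dataset = dataset
        self.field = field
        super().__init__(f"dataset {dataset!r}, field {field!r}: {message}")


class ConfigWarning(UserWarning):
    """Non-fatal issue in a configuration file (e.g. an unknown key)."""


class LoadError(EphysyncError):
    """A signal or annotation file could not be loaded."""


class SyncError(EphysyncError):
    """Invalid synchronization parameters or query."""


class DetectError(EphysyncError):
    """Invalid detection parameters or input."""


class PipelineError(EphysyncError):
    """A pipeline stage failed; names the stage and dataset."""

    def __init__(self, stage: str, dataset: str, message: str):
        self.stage = stage
        self.dataset = dataset
        super().__init__(f"[{stage}] dataset {dataset!r}: {message}")
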
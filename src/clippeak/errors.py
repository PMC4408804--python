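"""Exception hierarchy; the CLI maps these onto exit codes."""


class ClippeakError(Exception):
    """Base class for all package errors."""


class ConfigError(ClippeakError):
    """Invalid or inconsistent configuration (CLI exit code 2)."""


class DataError(ClippeakError):
    """Malformed or missing input data (CLI exit code 3)."""


class StageError(ClippeakError):
    """A pipeline stage failed mid-run (CLI exit code 4)."""
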
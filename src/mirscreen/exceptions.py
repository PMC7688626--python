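"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class MirscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(MirscreenError):
    """Invalid configuration: bad thresholds, infeasible simulation, unknown format."""


class DataError(MirscreenError):
    """Invalid data: malformed files, violated invariants, missing annotations."""
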
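"""Exception hierarchy shared across the pipeline.

Two failure families matter to callers (and to the CLI's exit codes):
malformed input files, and data that are structurally valid but too
degenerate for the statistics to be defined (a theme with a single
accuracy class, constant ratings, a zero-norm construct vector, ...).
"""


class WitsemError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(WitsemError, ValueError):
    """An input file violates its declared on-disk dialect."""


class DegenerateDataError(WitsemError, ValueError):
    """Structurally valid data on which the requested statistic is undefined."""
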
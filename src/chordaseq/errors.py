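"""Exception taxonomy shared across the pipeline.

The CLI maps these onto exit codes (config error -> 2, input-format
error -> 3, stage failure -> 4); library users catch them directly.
"""


class ChordaseqError(Exception):
    """Base class for all package errors."""


class ConfigError(ChordaseqError):
    """Invalid or infeasible configuration (bad thresholds, genes that do not fit, ...)."""


class InputFormatError(ChordaseqError):
    """Malformed input data (missing NM tag, unknown contig, bad table columns, ...)."""


class StageError(ChordaseqError):
    """A pipeline stage failed; the message names the stage."""
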
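"""Exception hierarchy.

All library errors derive from :class:`SeqEntropyError` so callers (and the
CLI) can distinguish data/contract failures (exit 1) from usage errors
(exit 2) raised by the argument parser.
"""


class SeqEntropyError(Exception):
    """Base class for all seqentropy errors."""


class FormatError(SeqEntropyError):
    """Malformed input file: ragged rows, missing columns, duplicate IDs."""


class LabelError(FormatError):
    """A label value outside {0, 1}."""


class InputError(SeqEntropyError):
    """Invalid in-memory input (length mismatch, duplicate epochs, ...)."""


class StratificationError(SeqEntropyError):
    """A class is absent or too small for the requested split/folding."""


class SampleSizeError(SeqEntropyError):
    """Too few samples for the requested neighbor order."""


class ConfigError(SeqEntropyError):
    """Invalid configuration (unknown classifier family, bad profile)."""


class UndefinedMetricError(SeqEntropyError):
    """A threshold-free metric is undefined (single-class input)."""
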
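"""Exception hierarchy for trimsight.

All parsing/vision failures derive from :class:`TrimsightError` so callers
(and the CLI) can catch one base class.
"""


class TrimsightError(Exception):
    """Base class for all trimsight errors."""


class ReportModuleNotFoundError(TrimsightError):
    """The FastQC report lacks the per-base sequence quality module."""


class CorruptImageError(TrimsightError):
    """An embedded or referenced plot image could not be decoded."""


class MetadataMissingError(TrimsightError):
    """Required report metadata (e.g. Sequence length) absent or unparseable."""


class DataTableParseError(TrimsightError):
    """A fastqc_data.txt table is absent or malformed."""


class AxisCalibrationError(TrimsightError):
    """Too few axis tick labels were recognized to calibrate the plot."""


class FastqFormatError(TrimsightError):
    """A FASTQ record violates the format (e.g. seq/qual length mismatch)."""
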
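"""End-to-end truncation prediction and FASTQ trimming.

Two routes produce a :class:`TrimRecommendation`:

* :func:`predict_trim` — the vision route: color-map the plot raster,
  calibrate both axes from the tick labels, scan right-to-left for the
  yellow transition, and map the stop column back to a base position.
* :func:`oracle_trim` — the numeric route: scan the per-base quality
  table directly.  It is deliberately independent of the image pipeline
  so the two can cross-check each other.

Both express the result as the number of bases kept (equivalently the
1-based position of the last kept base; 0 means nothing survives).
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from Bio import SeqIO

from .errors import AxisCalibrationError, FastqFormatError
from .fastqc_io import QCReport, QualityProfile
from .plot_vision import (
    VisionParams,
    build_color_map,
    calibrate_x_axis,
    locate_threshold_row,
    pixel_to_position,
    scan_transition,
)

__all__ = [
    "TrimRecommendation",
    "predict_trim",
    "oracle_trim",
    "trim_fastq",
    "phred_error_rate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrimRecommendation:
    """Predicted truncation for one read file.

    ``truncation_position`` counts bases kept; ``status`` records whether
    quality actually crossed the threshold (``found``), never dropped
    below it (``never_below``, keep everything) or never cleared it
    (``always_below``, nothing usable).
    """

    read_label: str
    truncation_position: int
    quality_threshold: float
    status: Literal["found", "never_below", "always_below"]
    source: Literal["image", "table"]
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "read_label": self.read_label,
            "truncation_position": self.truncation_position,
            "threshold": self.quality_threshold,
            "status": self.status,
            "source": self.source,
            "diagnostics": self.diagnostics,
        }


def predict_trim(
    report: QCReport,
    params: VisionParams = VisionParams(),
    read_label: str = "read1",
) -> TrimRecommendation:
    """Predict the truncation position from a report's plot raster.

    Composes the vision pipeline (color map, y/x axis calibration,
    right-to-left transition scan, pixel-to-base mapping) and clamps the
    result to [0, read_length].
    """
    img = report.plot_image
    try:
        color_map = build_color_map(img, params)
        geometry = locate_threshold_row(img, params)
        geometry = calibrate_x_axis(img, params, geometry)
    except (AxisCalibrationError, ValueError) as exc:
        raise AxisCalibrationError(f"{report.sample_name}: {exc}") from exc

    result = scan_transition(img, geometry, color_map, params)
    if result.status == "never_below":
        position = report.read_length
    elif result.status == "always_below":
        position = 0
    else:
        assert result.transition_column is not None
        position = pixel_to_position(result.transition_column, geometry)
        position = min(max(position, 0), report.read_length)

    return TrimRecommendation(
        read_label=read_label,
        truncation_position=position,
        quality_threshold=params.quality_threshold,
        status=result.status,
        source="image",
        diagnostics={
            "sample": report.sample_name,
            "transition_column": result.transition_column,
            "patches_scanned": result.scanned_patches,
            "stop_label": result.stop_label,
        },
    )


def oracle_trim(
    profile: QualityProfile,
    threshold: float = 20.0,
    read_label: str = "read1",
) -> TrimRecommendation:
    """Truncation from the numeric table: independent of the image route.

    Scans bins from last to first for the rightmost bin whose lower
    quartile clears the threshold — the same statistic the yellow-box
    geometry encodes — and truncates at that bin's end.
    """
    status: str = "always_below"
    position = 0
    bins_scanned = 0
    for b in reversed(profile.bins):
        bins_scanned += 1
        if b.q25 >= threshold:
            position = b.end
            status = "never_below" if b is profile.bins[-1] else "found"
            break
    return TrimRecommendation(
        read_label=read_label,
        truncation_position=position,
        quality_threshold=threshold,
        status=status,  # type: ignore[arg-type]
        source="table",
        diagnostics={"bins_scanned": bins_scanned},
    )


def phred_error_rate(q: float) -> float:
    """Base-call error probability for a Phred score: 10^(-q/10).

    Q20 corresponds to a 1% error rate, the conventional boundary
    between acceptable and poor base calls.
    """
    if q < 0:
        raise ValueError("Phred score must be >= 0")
    return 10.0 ** (-q / 10.0)


# --------------------------------------------------------------------------
# FASTQ trimming
# --------------------------------------------------------------------------


class _GzipTextWriter(io.TextIOWrapper):
    """Deterministic gzip text writer that also closes the raw file."""

    def __init__(self, path: Path):
        self._raw = open(path, "wb")
        # zeroed mtime and empty filename keep output byte-reproducible
        gz = gzip.GzipFile(filename="", fileobj=self._raw, mode="wb", mtime=0)
        super().__init__(gz, encoding="ascii", newline="")

    def close(self) -> None:
        try:
            super().close()
        finally:
            self._raw.close()


def _open_text(path: Path, mode: str):
    if path.suffix == ".gz":
        if "w" in mode:
            return _GzipTextWriter(path)
        return gzip.open(path, "rt", encoding="ascii")
    return open(path, mode, encoding="ascii", newline="" if "w" in mode else None)


def trim_fastq(
    fastq_in: str | Path,
    truncation_position: int,
    discard_short: bool = False,
    fastq_out: str | Path = "trimmed.fastq",
) -> tuple[int, int, int]:
    """Cut every read to its first ``truncation_position`` bases.

    Sequence and quality strings are cut identically.  Reads shorter than
    the truncation length are kept unchanged when ``discard_short`` is
    false (the default) and dropped when true — the latter mirrors how
    DADA2's ``truncLen`` handles short reads.  Returns
    ``(read, written, discarded)`` record counts.  Gzip in/out is
    selected by a ``.gz`` suffix.
    """
    if truncation_position < 0:
        raise ValueError("truncation_position must be >= 0")
    fastq_in, fastq_out = Path(fastq_in), Path(fastq_out)
    n_read = n_written = n_discarded = 0
    with _open_text(fastq_in, "r") as fin, _open_text(fastq_out, "w") as fout:
        try:
            for rec in SeqIO.parse(fin, "fastq"):
                n_read += 1
                if len(rec) < truncation_position:
                    if discard_short:
                        n_discarded += 1
                        continue
                    out = rec
                else:
                    out = rec[:truncation_position]
                SeqIO.write(out, fout, "fastq")
                n_written += 1
        except ValueError as exc:
            raise FastqFormatError(
                f"{fastq_in}: record {n_read + 1}: {exc}"
            ) from exc
    logger.info(
        "trimmed %s -> %s: read=%d written=%d discarded=%d (truncation=%d)",
        fastq_in, fastq_out, n_read, n_written, n_discarded, truncation_position,
    )
    return n_read, n_written, n_discarded
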
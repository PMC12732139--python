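"""Readers for FastQC artifacts.

Two independent input routes feed the truncation predictor:

* the HTML report, from which the per-base sequence quality plot is
  extracted as an RGB raster together with the read length (the image
  route — the one the vision pipeline consumes);
* the plain-text ``fastqc_data.txt`` companion file, whose numeric
  per-base quality table serves as the independent oracle route.

Only the Basic Statistics and Per base sequence quality modules are
interpreted; everything else in a report is ignored.
"""

from __future__ import annotations

import base64
import binascii
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import html as lxml_html
from PIL import Image, UnidentifiedImageError

from .errors import (
    CorruptImageError,
    DataTableParseError,
    MetadataMissingError,
    ReportModuleNotFoundError,
)

__all__ = [
    "PositionBin",
    "QualityProfile",
    "QCReport",
    "parse_fastqc_html",
    "parse_fastqc_data",
    "load_plot_image",
]

#: Phred scores FastQC plots can display; used for invariant checks.
QUALITY_RANGE = (0.0, 45.0)


@dataclass(frozen=True)
class PositionBin:
    """Quality summary for one base position or one FastQC bin.

    ``start``/``end`` are 1-based inclusive base positions; single-base
    bins have ``start == end``.  The percentile fields mirror the
    box-and-whisker elements of the plot: the yellow box spans
    ``q25``–``q75``, the whiskers reach ``q10``/``q90``, the red line is
    the ``median`` and the blue line the ``mean``.
    """

    start: int
    end: int
    mean: float
    median: float
    q25: float
    q75: float
    q10: float
    q90: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"bin start {self.start} > end {self.end}")
        if not (self.q10 <= self.q25 <= self.median <= self.q75 <= self.q90):
            raise ValueError(
                f"percentile ordering violated in bin {self.start}-{self.end}: "
                f"q10={self.q10} q25={self.q25} median={self.median} "
                f"q75={self.q75} q90={self.q90}"
            )
        lo, hi = QUALITY_RANGE
        for v in (self.mean, self.median, self.q25, self.q75, self.q10, self.q90):
            if not (lo <= v <= hi):
                raise ValueError(f"quality value {v} outside [{lo}, {hi}]")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        """FastQC-style row label: ``"7"`` or ``"100-104"``."""
        return str(self.start) if self.start == self.end else f"{self.start}-{self.end}"


@dataclass(frozen=True)
class QualityProfile:
    """Per-position Phred quality distribution, binned as FastQC bins it."""

    bins: tuple[PositionBin, ...]
    read_length: int

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("profile has no bins")
        object.__setattr__(self, "bins", tuple(self.bins))
        prev_end = 0
        for b in self.bins:
            if b.start != prev_end + 1:
                raise ValueError(
                    f"bins not contiguous: expected start {prev_end + 1}, got {b.start}"
                )
            prev_end = b.end
        if prev_end != self.read_length:
            raise ValueError(
                f"last bin ends at {prev_end} but read_length is {self.read_length}"
            )

    @property
    def max_bin_width(self) -> int:
        return max(b.width for b in self.bins)


@dataclass
class QCReport:
    """A parsed FastQC report: the quality-plot raster plus metadata."""

    sample_name: str
    read_length: int
    plot_image: np.ndarray  # HxWx3 uint8
    source_path: str = ""
    has_data_table: bool = False

    def __post_init__(self) -> None:
        if not self.sample_name:
            raise ValueError("sample_name must be non-empty")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.plot_image.ndim != 3 or self.plot_image.shape[2] != 3:
            raise ValueError("plot_image must be an HxWx3 RGB array")
        if self.plot_image.shape[0] < 1 or self.plot_image.shape[1] < 1:
            raise ValueError("plot_image must have positive dimensions")


# --------------------------------------------------------------------------
# HTML report
# --------------------------------------------------------------------------

_PBQ_HEADING = re.compile(r"per\s*base\s*sequence\s*quality", re.IGNORECASE)
_SEQLEN_RE = re.compile(r"^\s*(?:(\d+)\s*-\s*)?(\d+)\s*$")
_DATA_URI_RE = re.compile(r"^data:image/[^;]+;base64,(.*)$", re.DOTALL)


def _decode_image_src(src: str, html_dir: Path) -> np.ndarray:
    """Decode an <img> src that is either a base64 data URI or a sibling file."""
    m = _DATA_URI_RE.match(src.strip())
    try:
        if m:
            payload = base64.b64decode(m.group(1), validate=False)
            img = Image.open(io.BytesIO(payload))
        else:
            img = Image.open(html_dir / src)
        img.load()
    except (binascii.Error, UnidentifiedImageError, OSError, ValueError) as exc:
        raise CorruptImageError(f"corrupt image payload: {exc}") from exc
    return _to_rgb_array(img)


def _to_rgb_array(img: Image.Image) -> np.ndarray:
    """RGB array; alpha (if any) composited on white."""
    if img.mode in ("RGBA", "LA", "PA"):
        bg = Image.new("RGBA", img.size, (255, 255, 255, 255))
        bg.alpha_composite(img.convert("RGBA"))
        img = bg.convert("RGB")
    elif img.mode != "RGB":
        img = img.convert("RGB")
    return np.asarray(img, dtype=np.uint8)


def _find_pbq_image(doc) -> str | None:
    """Locate the per-base quality <img> src in a FastQC-style document.

    Primary key: the module heading whose text mentions per-base quality;
    fallback: the first image whose alt text mentions it.  FastQC dialects
    drift across versions, hence the two-step search.
    """
    for h in doc.iter("h1", "h2", "h3"):
        if h.text_content() and _PBQ_HEADING.search(h.text_content()):
            node = h
            while node is not None:
                nxt = node.getnext()
                while nxt is not None:
                    imgs = nxt.findall(".//img") + ([nxt] if nxt.tag == "img" else [])
                    if imgs:
                        return imgs[0].get("src")
                    if nxt.tag in ("h1", "h2", "h3"):
                        break
                    nxt = nxt.getnext()
                node = node.getparent()
            break
    for img in doc.iter("img"):
        alt = img.get("alt") or ""
        if _PBQ_HEADING.search(alt):
            return img.get("src")
    return None


def _find_basic_statistics(doc) -> dict[str, str]:
    """Collect key/value rows from the Basic Statistics table, if present."""
    stats: dict[str, str] = {}
    for tr in doc.iter("tr"):
        cells = [c.text_content().strip() for c in tr.findall("td")]
        if len(cells) >= 2:
            stats.setdefault(cells[0], cells[1])
    return stats


def parse_fastqc_html(html_path: str | Path) -> QCReport:
    """Parse a FastQC HTML report into a :class:`QCReport`.

    Extracts the per-base sequence quality plot (base64-embedded or a
    sibling-file reference) and the read length from the Basic Statistics
    "Sequence length" entry.  A range entry ``"A-B"`` yields ``B`` — the
    maximum cycle count, matching the plot's x-axis extent.
    """
    html_path = Path(html_path)
    doc = lxml_html.fromstring(html_path.read_text(encoding="utf-8"))

    src = _find_pbq_image(doc)
    if src is None:
        raise ReportModuleNotFoundError(
            f"{html_path}: per-base sequence quality module not found"
        )
    image = _decode_image_src(src, html_path.parent)

    stats = _find_basic_statistics(doc)
    seqlen_raw = next(
        (v for k, v in stats.items() if k.lower().startswith("sequence length")), None
    )
    if seqlen_raw is None:
        raise MetadataMissingError(f"{html_path}: Sequence length entry not found")
    m = _SEQLEN_RE.match(seqlen_raw)
    if not m:
        raise MetadataMissingError(
            f"{html_path}: unparseable Sequence length {seqlen_raw!r}"
        )
    read_length = int(m.group(2))

    sample = next(
        (v for k, v in stats.items() if k.lower().startswith("filename")), None
    )
    if not sample:
        title = doc.find(".//title")
        sample = title.text.strip() if title is not None and title.text else html_path.stem

    return QCReport(
        sample_name=sample,
        read_length=read_length,
        plot_image=image,
        source_path=str(html_path),
    )


# --------------------------------------------------------------------------
# fastqc_data.txt table
# --------------------------------------------------------------------------

_PBQ_BLOCK = ">>Per base sequence quality"


def parse_fastqc_data(data_path: str | Path) -> QualityProfile:
    """Parse the per-base quality table of a ``fastqc_data.txt`` file.

    Expects the ``>>Per base sequence quality`` block with columns
    Base / Mean / Median / Lower Quartile / Upper Quartile /
    10th Percentile / 90th Percentile.  ``"A-B"`` labels become bins
    spanning A..B; bare numbers become single-base bins.
    """
    data_path = Path(data_path)
    lines = data_path.read_text(encoding="utf-8").splitlines()
    try:
        start = next(
            i for i, ln in enumerate(lines) if ln.startswith(_PBQ_BLOCK)
        )
    except StopIteration:
        raise DataTableParseError(
            f"{data_path}: '{_PBQ_BLOCK}' block not found"
        ) from None

    bins: list[PositionBin] = []
    for lineno, ln in enumerate(lines[start + 1 :], start=start + 2):
        if ln.startswith(">>END_MODULE"):
            break
        if ln.startswith("#") or not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 7:
            raise DataTableParseError(
                f"{data_path}:{lineno}: expected 7 columns, got {len(fields)}"
            )
        label = fields[0].strip()
        if "-" in label:
            a, b = label.split("-", 1)
            try:
                start_pos, end_pos = int(a), int(b)
            except ValueError:
                raise DataTableParseError(
                    f"{data_path}:{lineno}: bad base label {label!r}"
                ) from None
        else:
            try:
                start_pos = end_pos = int(label)
            except ValueError:
                raise DataTableParseError(
                    f"{data_path}:{lineno}: bad base label {label!r}"
                ) from None
        try:
            mean, median, q25, q75, q10, q90 = (float(x) for x in fields[1:])
        except ValueError as exc:
            raise DataTableParseError(f"{data_path}:{lineno}: {exc}") from None
        try:
            bins.append(
                PositionBin(
                    start=start_pos, end=end_pos, mean=mean, median=median,
                    q25=q25, q75=q75, q10=q10, q90=q90,
                )
            )
        except ValueError as exc:
            raise DataTableParseError(f"{data_path}:{lineno}: {exc}") from None

    if not bins:
        raise DataTableParseError(f"{data_path}: quality table has no rows")
    return QualityProfile(bins=tuple(bins), read_length=bins[-1].end)


def load_plot_image(image_path: str | Path) -> np.ndarray:
    """Load a standalone plot raster (PNG/JPEG) as an RGB array.

    Alpha, if present, is composited on white.
    """
    try:
        with Image.open(image_path) as img:
            img.load()
            return _to_rgb_array(img)
    except (UnidentifiedImageError, OSError, ValueError) as exc:
        raise CorruptImageError(f"cannot read image {image_path}: {exc}") from exc
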
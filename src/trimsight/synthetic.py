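"""Synthetic test universe: quality profiles with known ground truth and
their FastQC-style renderings.

Real Illumina amplicon runs show a high, flat quality plateau that decays
toward the 3' end; the generator parameterizes exactly that shape
(plateau, decay onset, linear decay rate, Gaussian position noise) so
every downstream stage — plot rendering, HTML wrapping, vision-based
prediction, FASTQ trimming — can be verified against a closed-form or
sidecar ground truth.  The fixtures model only the quality-profile
geometry the vision algorithm consumes, not sequencing chemistry.

Every generator is bit-reproducible under a fixed seed (gzip streams are
written with a zeroed mtime for this reason).
"""

from __future__ import annotations

import base64
import gzip
import io
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from ._font import label_font
from .fastqc_io import PositionBin, QualityProfile

__all__ = [
    "ProfileSpec",
    "RenderStyle",
    "RenderSidecar",
    "simulate_profile",
    "render_plot",
    "wrap_html",
    "write_data_table",
    "simulate_fastq",
    "verification_grid",
]

#: Phred clamp range for simulated statistics.
_Q_MIN, _Q_MAX = 2.0, 41.0


@dataclass(frozen=True)
class ProfileSpec:
    """Parameters of a simulated per-position quality profile.

    The median is ``plateau_q`` before ``decay_start`` and decays linearly
    at ``decay_rate`` Phred units per base after it, with seeded Gaussian
    noise of ``noise_sd`` added per position; quartiles sit ``iqr_half_width``
    Phred units either side of the median and the whiskers twice that.
    Positions 1-9 stay unbinned (as FastQC draws them) and later positions
    aggregate into ``bin_width``-base bins.
    """

    read_length: int = 250
    plateau_q: float = 38.0
    decay_start: int = 180
    decay_rate: float = 0.5
    noise_sd: float = 1.0
    iqr_half_width: float = 4.0
    bin_width: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not (1 <= self.decay_start):
            raise ValueError("decay_start must be >= 1")
        if not (_Q_MIN <= self.plateau_q <= _Q_MAX):
            raise ValueError(f"plateau_q must be in [{_Q_MIN}, {_Q_MAX}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.iqr_half_width < 0:
            raise ValueError("iqr_half_width must be >= 0")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")


def verification_grid(n: int = 50, seed: int = 0) -> list[ProfileSpec]:
    """Standard grid of profile specs spanning realistic MiSeq regimes.

    Read lengths cycle through {150, 250, 300}; decay onsets span 40-95%
    of the read length, decay rates 0.2-1.0 Phred/base, and per-position
    noise SD draws from {0, 1, 2}.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    lengths = (150, 250, 300)
    specs = []
    for i in range(n):
        L = lengths[i % len(lengths)]
        onset = max(1, int(round(rng.uniform(0.40, 0.95) * L)))
        specs.append(
            ProfileSpec(
                read_length=L,
                decay_start=onset,
                decay_rate=float(rng.uniform(0.2, 1.0)),
                noise_sd=float(rng.choice([0.0, 1.0, 2.0])),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def _bin_edges(read_length: int, bin_width: int) -> list[tuple[int, int]]:
    """FastQC-like layout: per-base bins for 1-9, fixed-width bins after."""
    edges = [(p, p) for p in range(1, min(read_length, 9) + 1)]
    p = 10
    while p <= read_length:
        edges.append((p, min(p + bin_width - 1, read_length)))
        p += bin_width
    return edges


def simulate_profile(spec: ProfileSpec) -> QualityProfile:
    """Simulate a binned quality profile from a :class:`ProfileSpec`.

    Per-position medians follow plateau-then-linear-decay plus Gaussian
    noise and are clamped (with all derived percentiles) to [2, 41]; bin
    statistics are the mean over member positions.  Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pos = np.arange(1, spec.read_length + 1, dtype=float)
    median = spec.plateau_q - spec.decay_rate * np.maximum(0.0, pos - spec.decay_start)
    median = median + rng.normal(0.0, spec.noise_sd, size=pos.size)
    median = np.clip(median, _Q_MIN, _Q_MAX)

    def clamp(x: np.ndarray) -> np.ndarray:
        return np.clip(x, _Q_MIN, _Q_MAX)

    hw = spec.iqr_half_width
    stats = {
        "median": median,
        "mean": median,
        "q25": clamp(median - hw),
        "q75": clamp(median + hw),
        "q10": clamp(median - 2 * hw),
        "q90": clamp(median + 2 * hw),
    }
    bins = []
    for start, end in _bin_edges(spec.read_length, spec.bin_width):
        sl = slice(start - 1, end)
        bins.append(
            PositionBin(
                start=start,
                end=end,
                **{k: float(np.mean(v[sl])) for k, v in stats.items()},
            )
        )
    return QualityProfile(bins=tuple(bins), read_length=spec.read_length)


# --------------------------------------------------------------------------
# FastQC-style renderer
# --------------------------------------------------------------------------

#: Colors used for each plot element; saturated enough that the broad-color
#: classifier names them unambiguously, but still FastQC-like.
PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (255, 255, 255),
    "band_green": (60, 205, 60),
    "band_orange": (245, 160, 70),
    "band_red": (210, 60, 60),
    "box_yellow": (250, 230, 30),
    "median_red": (200, 0, 0),
    "mean_blue": (0, 0, 200),
    "frame_black": (0, 0, 0),
}


@dataclass(frozen=True)
class RenderStyle:
    """Geometry of the rendered plot raster."""

    width: int = 800
    height: int = 600
    margin_left: int = 80
    margin_top: int = 40
    margin_right: int = 20
    margin_bottom: int = 60
    y_max: float = 42.0
    y_tick_step: int = 2
    range_x_labels: bool = False  # label binned ticks "A-B" instead of "B"

    @property
    def plot_box(self) -> tuple[int, int, int, int]:
        return (
            self.margin_left,
            self.margin_top,
            self.width - self.margin_right,
            self.height - self.margin_bottom,
        )


@dataclass
class RenderSidecar:
    """Pixel-exact ground truth for a rendered plot."""

    plot_box: tuple[int, int, int, int]
    y_tick_rows: dict[float, float]
    x_tick_cols: dict[int, float]
    threshold_row_q20: float
    ground_truth_crossing: int | None
    ground_truth_truncation: int
    palette: dict[str, tuple[int, int, int]]

    def to_json(self) -> str:
        d = asdict(self)
        d["y_tick_rows"] = {str(k): v for k, v in self.y_tick_rows.items()}
        d["x_tick_cols"] = {str(k): v for k, v in self.x_tick_cols.items()}
        return json.dumps(d, indent=1, sort_keys=True)


def _x_tick_positions(read_length: int) -> list[int]:
    for step in (1, 2, 5, 10, 20, 25, 50, 100, 200):
        if read_length / step <= 10:
            break
    ticks = [1] + [p for p in range(step, read_length + 1, step) if p > 1]
    return ticks


def _q25_truncation(profile: QualityProfile, threshold: float = 20.0) -> int | None:
    """End of the rightmost bin whose lower quartile clears ``threshold``."""
    for b in reversed(profile.bins):
        if b.q25 >= threshold:
            return b.end
    return None


def render_plot(
    profile: QualityProfile, style: RenderStyle = RenderStyle()
) -> tuple[np.ndarray, RenderSidecar]:
    """Render a profile as a FastQC-style plot and return pixel ground truth.

    Layout: green/orange/red background bands split at Phred 28 and 20,
    a yellow interquartile box with 10/90-percentile whiskers per bin,
    a red median segment, a blue mean poly-line, y tick labels every
    ``y_tick_step`` Phred units and x tick labels at round positions.
    """
    left, top, right, bottom = style.plot_box
    n = profile.read_length
    ppb = (right - left) / n

    def row(score: float) -> float:
        return (bottom - 1) - score / style.y_max * (bottom - 1 - top)

    def col(pos: float) -> float:
        return left + (pos - 0.5) * ppb

    img = Image.new("RGB", (style.width, style.height), PALETTE["background"])
    draw = ImageDraw.Draw(img)

    # background quality bands: red [0,20), orange [20,28), green [28,max]
    r20, r28 = int(row(20.0)), int(row(28.0))
    draw.rectangle([left, top, right - 1, r28], fill=PALETTE["band_green"])
    draw.rectangle([left, r28 + 1, right - 1, r20], fill=PALETTE["band_orange"])
    draw.rectangle([left, r20 + 1, right - 1, bottom - 1], fill=PALETTE["band_red"])

    # per-bin box-and-whisker bars
    for b in profile.bins:
        x0 = int(round(left + (b.start - 1) * ppb))
        x1 = int(round(left + b.end * ppb)) - 1
        cx = (x0 + x1) // 2
        draw.line([cx, int(row(b.q90)), cx, int(row(b.q75))], fill=PALETTE["frame_black"])
        draw.line([cx, int(row(b.q25)), cx, int(row(b.q10))], fill=PALETTE["frame_black"])
        draw.rectangle(
            [x0, int(row(b.q75)), x1, int(row(b.q25))], fill=PALETTE["box_yellow"]
        )
        draw.line([x0, int(row(b.median)), x1, int(row(b.median))], fill=PALETTE["median_red"])

    # mean poly-line across bin centers
    pts = [
        (col((b.start + b.end) / 2.0), row(b.mean)) for b in profile.bins
    ]
    if len(pts) > 1:
        draw.line(pts, fill=PALETTE["mean_blue"], width=1)

    # frame
    draw.rectangle([left - 1, top - 1, right, bottom], outline=PALETTE["frame_black"])

    font = label_font()
    # y tick labels, right-aligned left of the frame
    y_tick_rows: dict[float, float] = {}
    score = 0
    while score <= min(style.y_max, 41):
        r = row(score)
        text = str(score)
        tb = draw.textbbox((0, 0), text, font=font)
        tw, th = tb[2] - tb[0], tb[3] - tb[1]
        draw.text(
            (left - 8 - tw - tb[0], int(round(r - th / 2)) - tb[1]),
            text, fill=PALETTE["frame_black"], font=font,
        )
        y_tick_rows[float(score)] = r
        score += style.y_tick_step

    # x tick labels centered under their base position; in range-label
    # mode each tick snaps to its containing bin's end and is labeled
    # "A-B", so the recognized value (the upper bound) stays exact
    x_tick_cols: dict[int, float] = {}
    bin_by_pos = {p: b for b in profile.bins for p in range(b.start, b.end + 1)}
    ticks: list[tuple[int, str]] = []
    for p in _x_tick_positions(n):
        if style.range_x_labels:
            b = bin_by_pos[p]
            if (b.end, b.label) not in ticks:
                ticks.append((b.end, b.label))
        else:
            ticks.append((p, str(p)))
    for p, text in ticks:
        c = col(p)
        tb = draw.textbbox((0, 0), text, font=font)
        tw = tb[2] - tb[0]
        draw.text(
            (int(round(c - tw / 2)) - tb[0], bottom + 4 - tb[1]),
            text, fill=PALETTE["frame_black"], font=font,
        )
        x_tick_cols[p] = c

    truncation = _q25_truncation(profile)
    sidecar = RenderSidecar(
        plot_box=(left, top, right, bottom),
        y_tick_rows=y_tick_rows,
        x_tick_cols=x_tick_cols,
        threshold_row_q20=row(20.0),
        ground_truth_crossing=(truncation + 1) if truncation is not None and truncation < n else None,
        ground_truth_truncation=0 if truncation is None else truncation,
        palette=dict(PALETTE),
    )
    return np.asarray(img, dtype=np.uint8), sidecar


# --------------------------------------------------------------------------
# Report shells and companion files
# --------------------------------------------------------------------------

_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head><title>{name} FastQC Report</title></head>
<body>
<h1>FastQC Report</h1>
<div>
<h2>Basic Statistics</h2>
<table>
<tr><td>Filename</td><td>{name}</td></tr>
<tr><td>Sequence length</td><td>{seqlen}</td></tr>
</table>
</div>
<div>
<h2>Per base sequence quality</h2>
<p><img src="data:image/png;base64,{b64}" alt="Per base quality graph"/></p>
</div>
</body>
</html>
"""


def wrap_html(
    image: np.ndarray,
    read_length: int | str,
    sample_name: str = "sample.fastq",
) -> str:
    """Wrap a plot raster in a minimal FastQC-report HTML shell.

    ``read_length`` may be an integer or a range string like ``"35-251"``
    (which parses back to its upper bound).
    """
    buf = io.BytesIO()
    Image.fromarray(image).save(buf, format="PNG")
    b64 = base64.b64encode(buf.getvalue()).decode("ascii")
    return _HTML_TEMPLATE.format(name=sample_name, seqlen=read_length, b64=b64)


def write_data_table(profile: QualityProfile, path: str | Path) -> Path:
    """Write the per-base quality table in FastQC ``fastqc_data.txt`` layout."""
    path = Path(path)
    lines = [
        "##FastQC\t0.12.1",
        ">>Basic Statistics\tpass",
        "#Measure\tValue",
        f"Sequence length\t{profile.read_length}",
        ">>END_MODULE",
        ">>Per base sequence quality\tpass",
        "#Base\tMean\tMedian\tLower Quartile\tUpper Quartile\t"
        "10th Percentile\t90th Percentile",
    ]
    for b in profile.bins:
        lines.append(
            f"{b.label}\t{b.mean:.1f}\t{b.median:.1f}\t{b.q25:.1f}\t"
            f"{b.q75:.1f}\t{b.q10:.1f}\t{b.q90:.1f}"
        )
    lines.append(">>END_MODULE")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def simulate_fastq(
    profile: QualityProfile, n_reads: int, seed: int, path: str | Path
) -> Path:
    """Write ``n_reads`` synthetic FASTQ records consistent with a profile.

    Per-position qualities are Gaussian with the bin's median and an SD
    matching its interquartile range (IQR = 1.349 sigma for a normal),
    clamped to [2, 41] and Phred+33 encoded; bases are uniform over ACGT.
    A ``.gz`` suffix selects gzip output (mtime zeroed for determinism).
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    path = Path(path)
    rng = np.random.default_rng(seed)
    L = profile.read_length

    mu = np.empty(L)
    sd = np.empty(L)
    for b in profile.bins:
        mu[b.start - 1 : b.end] = b.median
        sd[b.start - 1 : b.end] = max(b.q75 - b.q25, 0.0) / 1.349

    chunks: list[str] = []
    bases = np.array(list("ACGT"))
    for i in range(n_reads):
        seq = "".join(bases[rng.integers(0, 4, size=L)])
        q = np.clip(np.rint(rng.normal(mu, sd)), _Q_MIN, _Q_MAX).astype(int)
        qual = "".join(chr(33 + v) for v in q)
        chunks.append(f"@sim_{i}\n{seq}\n+\n{qual}\n")
    payload = "".join(chunks).encode("ascii")

    if path.suffix == ".gz":
        with open(path, "wb") as raw, gzip.GzipFile(
            filename="", fileobj=raw, mode="wb", mtime=0
        ) as gz:
            gz.write(payload)
    else:
        path.write_bytes(payload)
    return path
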
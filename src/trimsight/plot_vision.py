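"""Computer-vision core: turn a per-base quality plot raster into a trim column.

The pipeline has four stages, mirroring how a person reads the plot:

1. :func:`build_color_map` — tile the image into small patches, summarize
   each tile by its dominant RGB value, and cluster those into a mapping
   from fine-grained colors (light yellow, dark yellow, ...) to broad
   human-readable labels (yellow, green, red, ...).
2. :func:`locate_threshold_row` — read the numeric y-axis tick labels to
   find the pixel row corresponding to the Phred quality threshold
   (Q20 by default, roughly a 1% base-call error rate).
3. :func:`calibrate_x_axis` — read the x-axis tick labels to fit the
   affine map between pixel columns and base positions.
4. :func:`scan_transition` — walk patches right-to-left along the
   threshold row; while a patch classifies as broad yellow the
   interquartile box still straddles the threshold, and the first
   non-yellow patch marks where quality clears (or never reached) it.

Digit recognition defaults to template matching against a glyph atlas
rendered with the same font as the fixture renderer; an external OCR
engine can be plugged in via ``VisionParams.engine``.

Pixel coordinates are 0-based, row-major, origin top-left; base positions
are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import ndimage

from ._font import INK_THRESHOLD, crop_mask, render_text_mask
from .errors import AxisCalibrationError

__all__ = [
    "VisionParams",
    "ColorMap",
    "PlotGeometry",
    "TransitionResult",
    "REFERENCE_PALETTE",
    "build_color_map",
    "classify_patch",
    "recognize_number",
    "detect_plot_box",
    "locate_threshold_row",
    "calibrate_x_axis",
    "scan_transition",
    "pixel_to_position",
]

BroadLabel = Literal[
    "yellow", "green", "orange", "red", "blue", "black", "white", "gray", "other"
]

#: Pure anchors used to name color-cluster centroids.
REFERENCE_PALETTE: tuple[tuple[tuple[int, int, int], str], ...] = (
    ((255, 255, 0), "yellow"),
    ((0, 255, 0), "green"),
    ((255, 165, 0), "orange"),
    ((255, 0, 0), "red"),
    ((0, 0, 255), "blue"),
    ((0, 0, 0), "black"),
    ((255, 255, 255), "white"),
    ((128, 128, 128), "gray"),
)


@dataclass(frozen=True)
class VisionParams:
    """Constants of the vision algorithm.

    patch_size: side of the square color-analysis patches, in pixels.
    quality_threshold: Phred score separating acceptable from poor calls.
    ocr_patch_width / ocr_patch_height: size of the sliding windows used
        to read x-axis tick labels from the bottom label strip.
    engine: optional external number-recognition engine with the same
        signature as :func:`recognize_number`; None selects the built-in
        template matcher.
    """

    patch_size: int = 10
    quality_threshold: float = 20.0
    ocr_patch_width: int = 80
    ocr_patch_height: int = 20
    engine: Callable[[np.ndarray, tuple[int, int, int, int]], int | None] | None = None

    def __post_init__(self) -> None:
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")
        if not (1 <= self.quality_threshold <= 41):
            raise ValueError("quality_threshold must be in [1, 41]")
        if self.ocr_patch_width < 1 or self.ocr_patch_height < 1:
            raise ValueError("OCR patch dimensions must be positive")


@dataclass(frozen=True)
class ColorMap:
    """Nearest-centroid map from RGB values to broad color labels."""

    centroids: tuple[tuple[tuple[int, int, int], str], ...]

    def __post_init__(self) -> None:
        if not self.centroids:
            raise ValueError("ColorMap needs at least one centroid")

    @property
    def labels(self) -> set[str]:
        return {lab for _, lab in self.centroids}

    def classify_rgb(self, rgb: Sequence[float]) -> str:
        """Label of the nearest centroid (Euclidean RGB; first wins ties)."""
        arr = np.array([c for c, _ in self.centroids], dtype=float)
        d = np.sum((arr - np.asarray(rgb, dtype=float)) ** 2, axis=1)
        return self.centroids[int(np.argmin(d))][1]

    def label_image(self, image: np.ndarray, label: str) -> np.ndarray:
        """Boolean mask of pixels whose nearest centroid carries ``label``."""
        arr = np.array([c for c, _ in self.centroids], dtype=np.int32)
        px = image.astype(np.int32)
        d = np.sum(
            (px[:, :, None, :] - arr[None, None, :, :]) ** 2, axis=3
        )
        idx = np.argmin(d, axis=2)
        wanted = np.array([lab == label for _, lab in self.centroids])
        return wanted[idx]


@dataclass(frozen=True)
class PlotGeometry:
    """Pixel calibration of a quality plot.

    plot_box is (left, top, right, bottom), right/bottom exclusive.
    y_ticks are (Phred score, pixel row); x_ticks are (position, column).
    """

    plot_box: tuple[int, int, int, int]
    y_ticks: tuple[tuple[float, float], ...] = ()
    x_ticks: tuple[tuple[int, float], ...] = ()
    threshold_row: float | None = None
    px_per_base: float | None = None
    x_affine: tuple[float, float] | None = None  # position = a*column + b

    def to_dict(self) -> dict:
        return {
            "plot_box": list(self.plot_box),
            "y_ticks": [list(t) for t in self.y_ticks],
            "x_ticks": [list(t) for t in self.x_ticks],
            "threshold_row": self.threshold_row,
            "px_per_base": self.px_per_base,
        }


@dataclass(frozen=True)
class TransitionResult:
    """Outcome of the right-to-left yellow scan."""

    transition_column: int | None
    scanned_patches: int
    stop_label: str
    status: Literal["found", "never_below", "always_below"]

    def to_dict(self) -> dict:
        return {
            "transition_column": self.transition_column,
            "scanned_patches": self.scanned_patches,
            "stop_label": self.stop_label,
            "status": self.status,
        }


# --------------------------------------------------------------------------
# Color mapping
# --------------------------------------------------------------------------

#: Merge radius for clustering patch-dominant colors into centroids.
_CLUSTER_RADIUS = 30.0


def _dominant_rgb(patch: np.ndarray) -> np.ndarray:
    """Per-channel median of a tile — robust to thin overdrawn lines."""
    return np.median(patch.reshape(-1, 3), axis=0)


def build_color_map(image: np.ndarray, params: VisionParams) -> ColorMap:
    """Cluster patch-dominant colors and name each cluster by nearest anchor.

    The image is partitioned into non-overlapping ``patch_size`` squares
    (ragged edge tiles allowed); each tile's dominant RGB is greedily
    clustered (first-seen color seeds a centroid; later colors within
    a fixed radius join it), then every centroid is labeled by its
    nearest reference-palette anchor.
    """
    h, w = image.shape[:2]
    ps = params.patch_size
    if h < ps or w < ps:
        raise ValueError(f"image too small: {w}x{h} for patch size {ps}")

    dominants: list[np.ndarray] = []
    for r0 in range(0, h, ps):
        for c0 in range(0, w, ps):
            tile = image[r0 : min(r0 + ps, h), c0 : min(c0 + ps, w)]
            dominants.append(_dominant_rgb(tile))

    centroids: list[np.ndarray] = []
    for d in dominants:
        if not any(np.linalg.norm(d - c) <= _CLUSTER_RADIUS for c in centroids):
            centroids.append(d)

    anchors = np.array([c for c, _ in REFERENCE_PALETTE], dtype=float)
    names = [lab for _, lab in REFERENCE_PALETTE]
    labeled = []
    for c in centroids:
        i = int(np.argmin(np.sum((anchors - c) ** 2, axis=1)))
        labeled.append((tuple(int(round(v)) for v in c), names[i]))
    return ColorMap(centroids=tuple(labeled))


def classify_patch(patch: np.ndarray, color_map: ColorMap) -> str:
    """Broad label of a tile: nearest centroid to its dominant RGB value."""
    if patch.size == 0:
        raise ValueError("empty patch")
    return color_map.classify_rgb(_dominant_rgb(patch))


# --------------------------------------------------------------------------
# Digit recognition (template matching against the shared font atlas)
# --------------------------------------------------------------------------

_ATLAS: dict[str, np.ndarray] | None = None


def _digit_atlas() -> dict[str, np.ndarray]:
    global _ATLAS
    if _ATLAS is None:
        _ATLAS = {}
        for ch in "0123456789-":
            m = crop_mask(render_text_mask(ch))
            assert m is not None
            _ATLAS[ch] = m
    return _ATLAS


def _match_glyph(glyph: np.ndarray) -> tuple[str, float]:
    """Best atlas character for a cropped glyph mask, with mismatch score."""
    best, best_score = "?", np.inf
    for ch, tmpl in _digit_atlas().items():
        h = max(glyph.shape[0], tmpl.shape[0])
        w = max(glyph.shape[1], tmpl.shape[1])
        a = np.zeros((h, w), bool)
        b = np.zeros((h, w), bool)
        a[: glyph.shape[0], : glyph.shape[1]] = glyph
        b[: tmpl.shape[0], : tmpl.shape[1]] = tmpl
        score = float(np.mean(a ^ b))
        if score < best_score:
            best, best_score = ch, score
    return best, best_score


#: Glyphs whose best match is still this dissimilar are rejected.
_MAX_GLYPH_MISMATCH = 0.25


def _read_text_mask(mask: np.ndarray) -> str:
    """Segment a binary ink mask into glyphs by column gaps and match each."""
    cols = np.any(mask, axis=0)
    if not cols.any():
        return ""
    lbl, n = ndimage.label(cols)
    out = []
    for i in range(1, n + 1):
        cs = np.flatnonzero(lbl == i)
        glyph = crop_mask(mask[:, cs[0] : cs[-1] + 1])
        if glyph is None:
            continue
        ch, score = _match_glyph(glyph)
        if score <= _MAX_GLYPH_MISMATCH:
            out.append(ch)
    return "".join(out)


def recognize_number(
    image: np.ndarray, region: tuple[int, int, int, int]
) -> int | None:
    """Read an integer from ``region`` = (left, top, right, bottom) of ``image``.

    Returns None when no digits are found.  A range label ``"A-B"``
    resolves to its upper bound B, the convention used for binned
    x-axis ticks.
    """
    left, top, right, bottom = region
    h, w = image.shape[:2]
    left, top = max(0, left), max(0, top)
    right, bottom = min(w, right), min(h, bottom)
    if right <= left or bottom <= top:
        return None
    crop = image[top:bottom, left:right]
    gray = np.mean(crop.astype(float), axis=2)
    text = _read_text_mask(gray < INK_THRESHOLD)
    parts = [p for p in text.split("-") if p.isdigit()]
    if not parts:
        return None
    return int(parts[-1])


def _recognize(
    image: np.ndarray, region: tuple[int, int, int, int], params: VisionParams
) -> int | None:
    engine = params.engine or recognize_number
    return engine(image, region)


# --------------------------------------------------------------------------
# Geometry: frame detection and axis calibration
# --------------------------------------------------------------------------


def detect_plot_box(image: np.ndarray) -> tuple[int, int, int, int]:
    """Find the rectangular data-area frame by its long dark border lines."""
    gray = np.mean(image.astype(float), axis=2)
    dark = gray < 100
    h, w = dark.shape
    row_runs = np.flatnonzero(dark.sum(axis=1) > 0.5 * w)
    col_runs = np.flatnonzero(dark.sum(axis=0) > 0.3 * h)
    if row_runs.size < 2 or col_runs.size < 2:
        raise AxisCalibrationError("plot frame not found")
    top, bottom = int(row_runs[0]), int(row_runs[-1])
    left, right = int(col_runs[0]), int(col_runs[-1])
    if right - left < 10 or bottom - top < 10:
        raise AxisCalibrationError("plot frame degenerate")
    # interior of the frame
    return (left + 1, top + 1, right, bottom)


def _row_label_groups(mask: np.ndarray, max_gap: int = 2) -> list[tuple[int, int]]:
    """Group ink rows of the y-label strip into per-label (top, bottom) bands."""
    rows = np.flatnonzero(np.any(mask, axis=1))
    if rows.size == 0:
        return []
    groups = []
    start = prev = rows[0]
    for r in rows[1:]:
        if r - prev > max_gap:
            groups.append((int(start), int(prev)))
            start = r
        prev = r
    groups.append((int(start), int(prev)))
    return groups


def locate_threshold_row(image: np.ndarray, params: VisionParams) -> PlotGeometry:
    """Calibrate the y axis and place the quality-threshold row.

    Reads each numeric tick label left of the plot area; the threshold
    row is the row of the tick equal to ``quality_threshold``, or the
    linear interpolation between the two flanking ticks otherwise.
    """
    try:
        plot_box = detect_plot_box(image)
    except AxisCalibrationError as exc:
        raise AxisCalibrationError(f"axis calibration failed: {exc}") from exc
    left, top, right, bottom = plot_box

    strip = image[:, : max(0, left - 2)]
    if strip.size == 0:
        raise AxisCalibrationError("axis calibration failed: no y-label strip")
    gray = np.mean(strip.astype(float), axis=2)
    mask = gray < INK_THRESHOLD

    ticks: list[tuple[float, float]] = []
    for r0, r1 in _row_label_groups(mask):
        region = (0, r0 - 1, strip.shape[1], r1 + 2)
        val = _recognize(image, region, params)
        if val is not None:
            ticks.append((float(val), (r0 + r1) / 2.0))
    if len(ticks) < 2:
        raise AxisCalibrationError(
            f"axis calibration failed: {len(ticks)} y tick(s) recognized"
        )
    ticks.sort(key=lambda t: t[0])

    q = params.quality_threshold
    scores = np.array([t[0] for t in ticks])
    rows = np.array([t[1] for t in ticks])
    exact = np.flatnonzero(scores == q)
    if exact.size:
        threshold_row = float(rows[exact[0]])
    elif scores[0] <= q <= scores[-1]:
        threshold_row = float(np.interp(q, scores, rows))
    else:
        # extrapolate from the overall linear fit
        a, b = np.polyfit(scores, rows, 1)
        threshold_row = float(a * q + b)
    return PlotGeometry(
        plot_box=plot_box,
        y_ticks=tuple((s, r) for s, r in ticks),
        threshold_row=threshold_row,
    )


def _column_label_groups(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Group ink columns into per-label (left, right) spans."""
    cols = np.flatnonzero(np.any(mask, axis=0))
    if cols.size == 0:
        return []
    groups = []
    start = prev = cols[0]
    for c in cols[1:]:
        if c - prev > max_gap:
            groups.append((int(start), int(prev)))
            start = c
        prev = c
    groups.append((int(start), int(prev)))
    return groups


def calibrate_x_axis(
    image: np.ndarray, params: VisionParams, geometry: PlotGeometry
) -> PlotGeometry:
    """Read x tick labels from the bottom strip and fit the pixel↔base map.

    Slides ``ocr_patch_width`` × ``ocr_patch_height`` windows along the
    label strip below the plot (half-window overlap so no label straddles
    every window edge); the rightmost window is narrowed to the image
    boundary.  Labels are read with the recognition engine; a range label
    ``"A-B"`` contributes B.  The affine column→position map is the least
    squares fit through all recovered (column, position) ticks.
    """
    left, top, right, bottom = geometry.plot_box
    h, w = image.shape[:2]
    strip_top = min(bottom + 2, h)
    strip_bottom = min(strip_top + params.ocr_patch_height, h)
    if strip_bottom <= strip_top:
        raise AxisCalibrationError("axis calibration failed: no x-label strip")

    gray = np.mean(image[strip_top:strip_bottom].astype(float), axis=2)
    mask = gray < INK_THRESHOLD
    # x labels sit under the plot area; ink further left belongs to the
    # y-axis label column and must not contribute ticks
    mask[:, : max(0, left - params.patch_size // 2)] = False

    found: dict[float, int] = {}  # center column -> position
    # a label nearer than this to a window edge may be cut mid-glyph-gap;
    # it is skipped there and read from a window that contains it cleanly
    # (the small step guarantees such a window exists for any label
    # narrower than the window minus two margins)
    margin = 9
    step = max(1, min(params.ocr_patch_width // 2, 12))
    for w0 in range(0, w, step):
        w1 = min(w0 + params.ocr_patch_width, w)  # clip to rightmost boundary
        sub = mask[:, w0:w1]
        # intra-label digit gaps are a few px; inter-label gaps are tens
        for c0, c1 in _column_label_groups(sub, max_gap=8):
            if c0 < margin and w0 > 0:
                continue  # may continue past the left window edge
            if c1 > (w1 - w0 - 1) - margin and w1 < w:
                continue  # may continue past the right edge
            region = (w0 + c0 - 1, strip_top, w0 + c1 + 2, strip_bottom)
            val = _recognize(image, region, params)
            if val is None:
                continue
            center = w0 + (c0 + c1) / 2.0
            if not any(abs(center - c) <= 3 for c in found):
                found[center] = val
        if w1 == w:
            break

    if len(found) < 2:
        raise AxisCalibrationError(
            f"axis calibration failed: {len(found)} x tick(s) recognized"
        )
    cols = np.array(sorted(found), dtype=float)
    poss = np.array([found[c] for c in cols], dtype=float)
    a, b = np.polyfit(cols, poss, 1)
    if a <= 0:
        raise AxisCalibrationError("axis calibration failed: non-increasing x axis")
    return replace(
        geometry,
        x_ticks=tuple((int(p), float(c)) for c, p in zip(cols, poss)),
        px_per_base=float(1.0 / a),
        x_affine=(float(a), float(b)),
    )


def pixel_to_position(column: float, geometry: PlotGeometry) -> int:
    """Map a pixel column to the nearest 1-based base position."""
    if geometry.x_affine is None:
        raise ValueError("geometry is not x-calibrated")
    left, top, right, bottom = geometry.plot_box
    if not (left <= column <= right):
        raise ValueError(f"column {column} outside plot box [{left}, {right}]")
    a, b = geometry.x_affine
    pos = int(round(a * column + b))
    max_pos = int(round(a * right + b))
    return min(max(pos, 1), max(max_pos, 1))


# --------------------------------------------------------------------------
# Transition scan
# --------------------------------------------------------------------------


def scan_transition(
    image: np.ndarray,
    geometry: PlotGeometry,
    color_map: ColorMap,
    params: VisionParams,
) -> TransitionResult:
    """Right-to-left patch scan along the threshold row.

    A patch centered vertically on the threshold row classifies yellow
    exactly while the interquartile box straddles the threshold.  The
    scan starts at the right edge of the plot area, continues leftward in
    ``patch_size`` steps while patches are yellow, and reports the right
    edge of the first non-yellow patch (the box has cleared the
    threshold) as the transition column.

    When the rightmost patch is already non-yellow the patch loop cannot
    start (the boxes at the read end are entirely above or entirely below
    the threshold), so the scan falls back to per-column yellow spans:
    each column's yellow extent is classified as above / straddling /
    below the threshold row, and the rightmost fully-above column — the
    same boundary the patch scan stops at — gives the transition;
    all-above means quality never dropped, no-above means it never
    cleared the bar.
    """
    if geometry.threshold_row is None or geometry.x_affine is None:
        raise ValueError("geometry must be fully calibrated")
    left, top, right, bottom = geometry.plot_box
    ps = params.patch_size
    tr = int(round(geometry.threshold_row))
    r0 = max(top, tr - ps // 2)
    r1 = min(bottom, r0 + ps)

    scanned = 0
    col = right
    last_label = ""
    while col - ps >= left:
        patch = image[r0:r1, col - ps : col]
        label = classify_patch(patch, color_map)
        scanned += 1
        if label != "yellow":
            if scanned == 1:
                return _column_span_fallback(
                    image, geometry, color_map, scanned, label
                )
            # the patch localizes the transition to patch_size pixels;
            # refine to the rightmost column whose box sits entirely
            # above the threshold (sub-patch features, e.g. a single
            # narrow bar recovering past the threshold, resolve here)
            refined = _rightmost_above_column(
                image, geometry, color_map, lo_col=col - ps
            )
            return TransitionResult(
                transition_column=refined if refined is not None else col,
                scanned_patches=scanned,
                stop_label=label,
                status="found",
            )
        last_label = label
        col -= ps
    # ran off the left edge while still yellow: boxes straddle everywhere
    return TransitionResult(
        transition_column=None,
        scanned_patches=scanned,
        stop_label=last_label or "yellow",
        status="always_below",
    )


def _yellow_spans(image, geometry, color_map, lo_col):
    """Per-column yellow extent over plot columns >= lo_col.

    Returns (any_yellow, top_rows, bottom_rows) in plot-local rows.
    """
    left, top, right, bottom = geometry.plot_box
    lo = max(left, lo_col)
    yellow = color_map.label_image(image[top:bottom, lo:right], "yellow")
    any_yellow = np.any(yellow, axis=0)
    h = yellow.shape[0]
    top_rows = np.where(any_yellow, np.argmax(yellow, axis=0), -1)
    bottom_rows = np.where(any_yellow, h - 1 - np.argmax(yellow[::-1], axis=0), -1)
    return lo, any_yellow, top_rows, bottom_rows


def _rightmost_above_column(image, geometry, color_map, lo_col):
    """Rightmost column whose yellow span lies entirely above the threshold."""
    tr_local = geometry.threshold_row - geometry.plot_box[1]
    lo, any_yellow, _, bottom_rows = _yellow_spans(
        image, geometry, color_map, lo_col
    )
    above = any_yellow & (bottom_rows < tr_local)
    if not above.any():
        return None
    return lo + int(np.flatnonzero(above)[-1]) + 1


def _column_span_fallback(
    image: np.ndarray,
    geometry: PlotGeometry,
    color_map: ColorMap,
    scanned: int,
    stop_label: str,
) -> TransitionResult:
    left, top, right, bottom = geometry.plot_box
    assert geometry.threshold_row is not None
    tr_local = geometry.threshold_row - top
    lo, any_yellow, top_rows, bottom_rows = _yellow_spans(
        image, geometry, color_map, left
    )
    if not any_yellow.any():
        # no boxes visible at all; treat as quality never clearing the bar
        return TransitionResult(None, scanned, stop_label, "always_below")

    above = any_yellow & (bottom_rows < tr_local)
    below = any_yellow & (top_rows > tr_local)
    straddle = any_yellow & ~above & ~below

    if not (straddle.any() or below.any()):
        return TransitionResult(None, scanned, stop_label, "never_below")
    if not above.any():
        return TransitionResult(None, scanned, stop_label, "always_below")
    transition = lo + int(np.flatnonzero(above)[-1]) + 1
    return TransitionResult(transition, scanned, stop_label, "found")
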
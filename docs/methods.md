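# Methods

## Problem

Illumina amplicon reads degrade in quality toward the 3′ end, and
ASV-calling pipelines want a per-run truncation length that cuts the
degraded tail while keeping enough sequence for read-pair overlap.
`trimsight` estimates that length from the FastQC per-base sequence
quality plot — the raster image itself, not the underlying numbers —
so it works from the one artifact every run already has.

## The plot model

A FastQC per-base quality plot encodes, per position (or per bin of
positions on long reads), a box-and-whisker summary: a yellow box from
the 25th to the 75th percentile, whiskers at the 10th/90th, a red median
segment and a blue mean poly-line, drawn over background bands (green
≥ Q28, orange Q20–28, red < Q20). The key geometric fact the algorithm
exploits: at the pixel row corresponding to quality threshold *t*, a
column is covered by yellow exactly when that position's IQR straddles
*t*, i.e. q25 ≤ *t* ≤ q75. As quality decays rightward, the boxes slide
down through the threshold row; the boundary where boxes stop being
entirely above the row is precisely where q25 crosses *t*.

## Algorithm

**Color mapping.** The image is tiled into non-overlapping
`patch_size` × `patch_size` squares (default 10 px, matching the block
scale of plot elements). Each tile is summarized by its per-channel
median — robust to thin overdrawn lines (whiskers, median/mean strokes)
crossing a tile. Tile colors are greedily clustered (a color within
Euclidean RGB distance 30 of an existing centroid joins it, otherwise it
seeds a new centroid; first-seen order, hence deterministic), and each
centroid is named by its nearest anchor in a fixed palette of pure
yellow/green/orange/red/blue/black/white/gray. Classification of any
patch is then nearest-centroid on its dominant RGB, ties broken by list
order. Only the yellow/non-yellow distinction is load-bearing; the other
labels exist for diagnostics and reporting.

**Digit recognition.** Axis tick labels are read by template matching:
every glyph of `0123456789-` is rasterized once with the same embedded
font the fixture renderer uses, and a label region is binarized
(gray < 160), split into glyphs at column gaps, and each glyph matched
to the atlas by minimal XOR pixel mismatch (reject above 25%
mismatch). A range label "A-B" (FastQC's binned ticks) resolves to its
upper bound B, the convention under which truncation positions refer to
the longest cycle. The engine is pluggable (`VisionParams.engine`), so
an external OCR system can be substituted without touching the
pipeline; the built-in matcher needs no external binaries and is exact
on renderer output.

**Axis calibration.** The data area is located by its long dark frame
lines. The y axis: each label group left of the frame is read and
paired with its row centroid; the threshold row is the tick equal to
the threshold or the linear interpolation between the flanking ticks
(extrapolation from a least-squares fit if outside the tick range,
which does not occur for thresholds 15–30 on standard plots). The x
axis: `ocr_patch_width` × `ocr_patch_height` (80 × 20) windows slide
along the label strip under the plot; the final window is narrowed to
the image boundary. A label group closer than 9 px to an interior
window edge may have been cut mid-label and is skipped there — the
12 px slide step guarantees every label also appears cleanly inside
some window. The column→position map is the least-squares affine fit
through all recovered ticks, and `pixel_to_position` rounds through it
to the nearest integer base.

**Transition scan.** Starting at the plot's right edge, the
`patch_size` square centered vertically on the threshold row is
classified; the scan steps leftward one patch at a time while patches
are yellow (IQR straddling the threshold) and stops at the first
non-yellow patch (boxes entirely above the row). Patch stepping
quantizes the stop to ~10 px, so the stop is then refined at column
resolution: within the stopping window and everything to its right, the
transition is the rightmost column whose yellow extent lies entirely
above the threshold row. This refinement also resolves sub-patch
features — e.g. a single-base bin at the read end whose q25 pops back
above the threshold under noise, which a 10 px patch cannot see.

Two degenerate starts are possible when the *rightmost* patch is
already non-yellow: either quality never drops (boxes entirely above
the row everywhere) or the read end is already hopeless (boxes entirely
below). The scan then falls back to per-column yellow spans over the
whole plot, classifying each column as above / straddling / below the
threshold row: no straddle-or-below columns ⇒ `never_below` (keep the
full read), no above columns ⇒ `always_below` (nothing survives), and
otherwise the rightmost fully-above column is the transition — the same
boundary rule as the refined scan.

**Statistic choice.** The plot does not label which quality statistic
"falls below the threshold"; the yellow-box geometry makes the scan's
stop condition equivalent to *q25 ≥ t*, so the lower quartile is the
statistic, and the independent table route (`oracle_trim`) uses exactly
that: the truncation is the end of the rightmost bin with q25 ≥ t.
Binned bars resolve to the bin end (conservative-right; any choice
within the bin is inside the one-bin agreement band). Users who prefer
a stricter or looser statistic can shift `quality_threshold` instead.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `quality_threshold` | 20 | Phred | quality bar; Q20 ≈ 1% error (10^(−Q/10)) |
| `patch_size` | 10 | px | color-analysis tile and scan step |
| `ocr_patch_width` / `ocr_patch_height` | 80 / 20 | px | x-label reading window |

Lowering the threshold keeps more bases (monotonically, by
construction); Q15–Q30 are the practically useful range. The pixel
parameters match the rendering scale of standard FastQC output and
should not need adjustment.

## Synthetic fixtures

`ProfileSpec` models the canonical MiSeq shape: a flat plateau
(default Q38) decaying linearly (default 0.5 Phred/base) from a given
cycle (default 180 of 250), with per-position Gaussian noise (default
sd 1), a fixed IQR half-width (default 4 Phred, whiskers at twice
that), clamped to [2, 41], and binned like FastQC (single bases through
position 9, 5-base bins after). The renderer draws the FastQC plot
anatomy described above at 800 × 600 and emits a sidecar with the exact
pixel rows/columns of every tick, the Q20 row, and the profile's true
q25 crossing, so vision output can be scored without circularity. FASTQ
simulation draws per-position qualities from a Gaussian matching each
bin's median and IQR (σ = IQR/1.349) with uniform random bases.

What the fixtures do **not** model: position-correlated and
heavy-tailed noise, per-read quality structure, tile/flow-cell
artifacts, the exact FastQC fonts and dimensions of any particular
FastQC version, or sequence composition. Passing tests therefore
demonstrate the correctness of the geometry→position logic, not
robustness to every real-world FastQC rendering; the HTML locator and
frame detector are written defensively (heading text with alt-text
fallback, embedded-base64 or sibling-file images) but real-report
robustness across FastQC versions is best-effort.

## Verification grid and problem sizes

The standard verification grid (`verification_grid`) holds 50 specs:
read lengths cycling through 150/250/300, decay onset uniform in
40–95% of the read length, decay rate uniform in 0.2–1.0 Phred/base,
noise sd drawn from {0, 1, 2}. The full simulate → render → wrap →
predict loop over the grid runs in ~20 s; FASTQ conservation is checked
on 2,000 simulated 250-cycle reads. On this grid the vision route
recovers the true crossing within one bin on 100% of fixtures
(and within 1–4 bases of the numeric oracle at worst), and all axis
tick labels are recognized exactly.

## Numerical and degenerate-input choices

- Pixel coordinates are 0-based, origin top-left; base positions are
  1-based inclusive; `truncation_position` counts bases kept (0 =
  nothing survives; `never_below` implies the full read length).
- Sequence-length ranges "A-B" in Basic Statistics parse to B, the
  longest cycle, matching the plot's x extent.
- Color clustering radius 30 RGB units separates all palette elements
  while merging anti-aliased shades; glyph match rejection at 25% XOR
  mismatch; ink binarization at gray < 160.
- `predict_trim` clamps to [0, read_length] against rounding at the
  plot edge; `pixel_to_position` refuses columns outside the data area.
- Gzip streams are written with zeroed mtime and empty name so
  fixed-seed outputs are byte-identical.
- Empty FASTQ input yields (0, 0, 0) and a valid empty output; a
  sequence/quality length mismatch aborts with the offending record
  named.

## Known limitations

- The vision route's precision is bounded by the plot's pixel density
  (~2–5 px per base at standard sizes); agreement with the numeric
  oracle is ±1 bin by design, not base-exact.
- Reports whose per-base-quality image is absent, or whose axis labels
  are unreadable by the digit matcher (exotic fonts at very small
  sizes), fail with a calibration error rather than guessing.
- Each read file is treated independently; no joint read1/read2
  overlap constraint is applied.
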
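"""Shared label font for the plot renderer and the digit-recognition atlas.

Both sides must rasterize glyphs through the same path so that template
matching is exact; Pillow's embedded default face is used because it ships
with the library and renders identically everywhere.
"""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageDraw, ImageFont

#: Point size used for every axis tick label.
LABEL_FONT_SIZE = 13

#: Grayscale level below which a pixel counts as glyph ink.
INK_THRESHOLD = 160


def label_font() -> ImageFont.FreeTypeFont:
    return ImageFont.load_default(size=LABEL_FONT_SIZE)


def render_text_mask(text: str) -> np.ndarray:
    """Rasterize ``text`` in the label font and return a boolean ink mask."""
    font = label_font()
    # generous canvas; caller crops to content
    w = 16 * max(1, len(text)) + 8
    img = Image.new("L", (w, LABEL_FONT_SIZE + 12), 255)
    ImageDraw.Draw(img).text((4, 2), text, fill=0, font=font)
    return np.asarray(img) < INK_THRESHOLD


def crop_mask(mask: np.ndarray) -> np.ndarray | None:
    """Tight bounding-box crop of a boolean mask; None if empty."""
    rows = np.any(mask, axis=1)
    if not rows.any():
        return None
    cols = np.any(mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return mask[r0 : r1 + 1, c0 : c1 + 1]
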
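"""Color handling.

A :class:`ColorSpec` is an RGBA quadruple with channels in [0, 1].  The
textual grammar accepted is the one annotation files use: a named color
(CSS names, via matplotlib), ``#rrggbb`` or ``#rrggbbaa``.  Serialization is
canonical lowercase hex so that emitted files are byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib.colors as _mcolors

from .errors import AnnotationError

__all__ = ["ColorSpec", "resolve_color"]


@dataclass(frozen=True)
class ColorSpec:
    r: float
    g: float
    b: float
    a: float = 1.0

    def __post_init__(self):
        for c in (self.r, self.g, self.b, self.a):
            if not (0.0 <= c <= 1.0):
                raise AnnotationError(f"color channel {c!r} outside [0, 1]")

    @classmethod
    def from_text(cls, text: str) -> "ColorSpec":
        return resolve_color(text)

    def to_hex(self) -> str:
        """Canonical ``#rrggbb`` (or ``#rrggbbaa`` when alpha < 1)."""
        keep_alpha = self.a < 1.0
        return _mcolors.to_hex((self.r, self.g, self.b, self.a), keep_alpha=keep_alpha)

    def with_alpha(self, a: float) -> "ColorSpec":
        return ColorSpec(self.r, self.g, self.b, a)


def resolve_color(text: str) -> ColorSpec:
    """Parse a named color, ``#rrggbb`` or ``#rrggbbaa`` into RGBA channels.

    Raises :class:`AnnotationError` on an unknown name or malformed hex.
    """
    if not isinstance(text, str) or not text.strip():
        raise AnnotationError(f"empty color value {text!r}")
    try:
        r, g, b, a = _mcolors.to_rgba(text.strip())
    except ValueError as exc:
        raise AnnotationError(f"unrecognized color {text!r}") from exc
    return ColorSpec(r, g, b, a)


BLACK = ColorSpec(0.0, 0.0, 0.0, 1.0)


def lerp(c0: ColorSpec, c1: ColorSpec, t: float) -> ColorSpec:
    """Per-channel linear interpolation; t=0 -> c0, t=1 -> c1."""
    return ColorSpec(
        c0.r + (c1.r - c0.r) * t,
        c0.g + (c1.g - c0.g) * t,
        c0.b + (c1.b - c0.b) * t,
        c0.a + (c1.a - c0.a) * t,
    )
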
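"""Deterministic color-style module labels.

Mimics the familiar convention of naming co-expression modules after
colors, assigned by decreasing module size; ``grey`` is reserved for
unassigned genes and never used as a module label.
"""

from __future__ import annotations

GREY_LABEL = "grey"

_COLOR_NAMES = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
    "lightsteelblue1", "lightcyan1", "ivory", "floralwhite", "darkorange2",
    "brown4", "bisque4", "darkslateblue", "plum2", "thistle2", "thistle1",
    "salmon4", "palevioletred3", "navajowhite2", "maroon", "lightpink4",
    "lavenderblush3", "honeydew1", "darkseagreen4", "coral1", "coral2",
    "antiquewhite4", "coral3", "mediumorchid", "skyblue2", "yellow4",
]


def module_color_names(n: int) -> list[str]:
    """First n module labels; falls back to numbered labels past the palette."""
    if n <= len(_COLOR_NAMES):
        return _COLOR_NAMES[:n]
    extra = [f"module{i + 1}" for i in range(len(_COLOR_NAMES), n)]
    return _COLOR_NAMES + extra
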
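"""Recovery-phase class scheme.

Regenerating skeletal muscle is staged into four phases: intact/stable
fibers, the early phase (ghost fibers: remnant basal membrane, no nuclei),
the mid phase (proliferating myoblasts), and the late phase (myotubes with
central nuclei).  Each phase carries a display color used for annotations
and inference maps; white is the "no detection / unannotated" sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field


WHITE: tuple[int, int, int] = (255, 255, 255)

#: integer sentinel for "no class / no detection" in class rasters
NO_DETECTION: int = -1


@dataclass(frozen=True)
class ClassScheme:
    """Ordered set of recovery-phase classes with display colors.

    Parameters
    ----------
    names : tuple of str
        Class labels, ordered; index in this tuple is the class code used
        everywhere in the package.
    colors : tuple of (int, int, int)
        One RGB triple per class, all distinct and distinct from white,
        which is reserved as the no-detection sentinel.
    """

    names: tuple[str, ...] = ("stable", "early", "mid", "late")
    colors: tuple[tuple[int, int, int], ...] = (
        (255, 0, 0),      # stable: red
        (0, 0, 255),      # early: blue
        (255, 255, 0),    # mid: yellow
        (255, 165, 0),    # late: orange
    )
    sentinel_color: tuple[int, int, int] = WHITE

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("a class scheme needs at least two classes")
        if len(self.colors) != len(self.names):
            raise ValueError("names and colors must have equal length")
        palette = set(self.colors)
        if len(palette) != len(self.colors) or self.sentinel_color in palette:
            raise ValueError("class colors must be distinct and non-white")

    @property
    def K(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


DEFAULT_SCHEME = ClassScheme()
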
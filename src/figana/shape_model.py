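"""Canonical geometry of the basic figure and its primitive transformations.

The basic figure is an irregular convex hexagon (the *main shape*) whose six
vertices are the *corners*.  Five internal line segments (*lines*, drawn as
diagonals of the hexagon) connect the corners in a simple path
``c1 - c2 - c3 - c4 - c5 - c6``; corner indices throughout this package refer
to positions along that path, not to the outline order.  A dot sits on one of
the corners and can travel along the internal path.  A trapezium is attached
outside one outline edge and rotates about its own pivot, and a broken-circle
arc glyph sits near the outline edge joining path corners 5 and 6.  Neither
the trapezium nor the broken circle belongs to the dot-traversal graph.

Orientation of the main shape is discretised to eight 45°-spaced rotational
positions (``main_state`` 1..8, state *k* meaning a counterclockwise rotation
by 45·(k-1)° from the template) plus a reflection flag, i.e. an element of the
dihedral group of order 16.  The trapezium has its own eight rotational
positions.  All transformations are exact on this discrete state space; the
concrete coordinates below only matter for rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, Literal, Tuple

import numpy as np

__all__ = [
    "Angle",
    "FigureState",
    "ShapeTemplate",
    "build_template",
    "rotate_main",
    "reflect_main",
    "rotate_trapezium",
    "subtract_line",
    "move_dot",
    "N_CORNERS",
    "N_LINES",
    "VALID_ANGLES",
]

N_CORNERS = 6
N_LINES = 5

#: Rotation arguments allowed for any rule: multiples of 45 in [-135, 180].
VALID_ANGLES = tuple(range(-135, 181, 45))

# Outline vertices of the main hexagon, in hull order, spanning the unit box.
# Deliberately irregular so that all 16 (rotation, flip) orientations render
# distinctly.
_HULL = np.array(
    [
        [0.06, 0.34],
        [0.30, 0.92],
        [0.74, 0.97],
        [0.96, 0.58],
        [0.84, 0.10],
        [0.34, 0.03],
    ]
)

# Internal-line arrangements: each form lists the hull-vertex order visited by
# the 5-segment internal path.  Every consecutive pair is a hexagon diagonal
# (never an outline edge), so the lines read as interior chords.  Path
# position k (1-based) is "corner k" for dot placement.
_INT_FORMS = {
    "A": (1, 4, 2, 6, 3, 5),
    "B": (2, 6, 4, 1, 3, 5),
    "C": (3, 1, 5, 2, 4, 6),
    "D": (5, 3, 1, 4, 2, 6),
}

# Trapezium arrangements: hull edge (by index of its first vertex, 1-based)
# the trapezium is attached to.  Form A sits on the edge nearest hull vertex 3.
_EXT_FORMS = {"A": 3, "B": 5, "C": 1, "D": 4}

# Hull edge carrying the broken-circle arc is fixed per internal form so the
# arc sits adjacent to path corners 5 and 6 (it shares no edge with the path).
ErrorKind = Literal["x", "y"]


class InvalidArgumentError(ValueError):
    """An argument is outside its documented domain."""


class InfeasibleStateError(RuntimeError):
    """A transformation cannot be applied to the current figure state."""


@dataclass(frozen=True)
class Angle:
    """A rotation argument: a multiple of 45 degrees within [-135, 180].

    Positive angles rotate counterclockwise, negative clockwise.
    """

    degrees: int

    def __post_init__(self) -> None:
        if self.degrees % 45 != 0 or not (-135 <= self.degrees <= 180):
            raise InvalidArgumentError(
                f"rotation angle must be a multiple of 45 in [-135, 180], "
                f"got {self.degrees}"
            )

    @property
    def steps(self) -> int:
        """Number of 45° counterclockwise steps (negative for clockwise)."""
        return self.degrees // 45


def _as_angle(angle: "Angle | int") -> Angle:
    return angle if isinstance(angle, Angle) else Angle(int(angle))


@dataclass(frozen=True)
class ShapeTemplate:
    """Reference geometry for one combination of internal/external form.

    Attributes
    ----------
    corner_positions
        Planar coordinates of path corners 1..6 (row ``i`` is corner ``i+1``).
    internal_lines
        The five path segments as corner-index pairs ``(k, k+1)``, 1-based.
    trapezium
        Vertices of the trapezium polygon, attached outside the hull.
    trapezium_pivot
        Point the trapezium rotates about (midpoint of its attachment edge).
    broken_circle
        ``(center, radius)`` of the broken-circle arc glyph.
    form_int, form_ext
        Preset ids in {A, B, C, D}.
    """

    corner_positions: Tuple[Tuple[float, float], ...]
    internal_lines: Tuple[Tuple[int, int], ...]
    trapezium: Tuple[Tuple[float, float], ...]
    trapezium_pivot: Tuple[float, float]
    broken_circle: Tuple[Tuple[float, float], float]
    form_int: str
    form_ext: str

    @property
    def centroid(self) -> Tuple[float, float]:
        c = np.asarray(self.corner_positions).mean(axis=0)
        return (float(c[0]), float(c[1]))

    #: Path corners the broken circle is attached next to.
    broken_circle_corners: Tuple[int, int] = (5, 6)


def build_template(form_int: str = "A", form_ext: str = "A") -> ShapeTemplate:
    """Build the reference geometry for the given form presets.

    Parameters
    ----------
    form_int
        Internal-line arrangement, one of ``"A".."D"``.
    form_ext
        Trapezium arrangement, one of ``"A".."D"``.
    """
    if form_int not in _INT_FORMS:
        raise InvalidArgumentError(f"unknown internal form {form_int!r}")
    if form_ext not in _EXT_FORMS:
        raise InvalidArgumentError(f"unknown external form {form_ext!r}")

    order = _INT_FORMS[form_int]
    corners = tuple((float(_HULL[v - 1, 0]), float(_HULL[v - 1, 1])) for v in order)
    lines = tuple((k, k + 1) for k in range(1, N_CORNERS))

    # Trapezium outside the configured hull edge, pivoting on the edge midpoint.
    e0 = _EXT_FORMS[form_ext] - 1
    p, q = _HULL[e0], _HULL[(e0 + 1) % 6]
    mid = (p + q) / 2.0
    edge = q - p
    out = np.array([edge[1], -edge[0]])  # outward normal (hull is CCW)
    out = out / np.linalg.norm(out)
    u = edge / np.linalg.norm(edge)
    trap = tuple(
        (float(v[0]), float(v[1]))
        for v in (
            mid - 0.10 * u + 0.02 * out,
            mid + 0.10 * u + 0.02 * out,
            mid + 0.055 * u + 0.11 * out,
            mid - 0.055 * u + 0.11 * out,
        )
    )

    # Broken circle adjacent to path corners 5 and 6, pushed outside the hull.
    c5 = np.asarray(corners[4])
    c6 = np.asarray(corners[5])
    centroid = _HULL.mean(axis=0)
    bc_mid = (c5 + c6) / 2.0
    away = bc_mid - centroid
    away = away / (np.linalg.norm(away) + 1e-12)
    bc_center = bc_mid + 0.16 * away
    return ShapeTemplate(
        corner_positions=corners,
        internal_lines=lines,
        trapezium=trap,
        trapezium_pivot=(float(mid[0]), float(mid[1])),
        broken_circle=((float(bc_center[0]), float(bc_center[1])), 0.06),
        form_int=form_int,
        form_ext=form_ext,
    )


@dataclass(frozen=True)
class FigureState:
    """Position of every movable part of one figure.

    ``main_state`` and ``trap_state`` are 1..8 (45° steps counterclockwise
    from the template), ``flipped`` records a reflection of the main shape,
    ``dot_corner`` is a path corner 1..6 and ``present_lines`` the subset of
    internal lines still drawn.
    """

    main_state: int = 1
    flipped: bool = False
    trap_state: int = 1
    dot_corner: int = 1
    present_lines: FrozenSet[int] = field(
        default_factory=lambda: frozenset(range(1, N_LINES + 1))
    )

    def __post_init__(self) -> None:
        if not 1 <= self.main_state <= 8:
            raise InvalidArgumentError(f"main_state must be 1..8, got {self.main_state}")
        if not 1 <= self.trap_state <= 8:
            raise InvalidArgumentError(f"trap_state must be 1..8, got {self.trap_state}")
        if not 1 <= self.dot_corner <= N_CORNERS:
            raise InvalidArgumentError(f"dot_corner must be 1..6, got {self.dot_corner}")
        object.__setattr__(self, "present_lines", frozenset(self.present_lines))
        if not self.present_lines <= set(range(1, N_LINES + 1)):
            raise InvalidArgumentError("present_lines must be a subset of 1..5")


def rotate_main(state: FigureState, angle: "Angle | int") -> FigureState:
    """Rotate the main shape counterclockwise by ``angle`` degrees."""
    a = _as_angle(angle)
    new = (state.main_state - 1 + a.steps) % 8 + 1
    return replace(state, main_state=new)


def reflect_main(state: FigureState, axis: str) -> FigureState:
    """Reflect the main shape about the ``x`` or ``y`` axis.

    With orientation written as the transform ``R(45·(s-1)) ∘ F^flip`` (``F``
    the x-axis reflection of the template), an x-axis reflection maps state
    ``s`` to ``-(s-1)`` and a y-axis reflection to ``4-(s-1)`` (mod 8), each
    toggling the flip flag; both are involutions by construction.
    """
    s = state.main_state - 1
    if axis == "x":
        s_new = (-s) % 8
    elif axis == "y":
        s_new = (4 - s) % 8
    else:
        raise InvalidArgumentError(f"axis must be 'x' or 'y', got {axis!r}")
    return replace(state, main_state=s_new + 1, flipped=not state.flipped)


def rotate_trapezium(state: FigureState, angle: "Angle | int") -> FigureState:
    """Rotate the trapezium about its own pivot, independently of all lines."""
    a = _as_angle(angle)
    new = (state.trap_state - 1 + a.steps) % 8 + 1
    return replace(state, trap_state=new)


def subtract_line(state: FigureState, line_id: int) -> FigureState:
    """Remove one internal line segment."""
    if not 1 <= line_id <= N_LINES:
        raise InvalidArgumentError(f"line id must be 1..5, got {line_id}")
    if line_id not in state.present_lines:
        raise InfeasibleStateError(f"line {line_id} is already absent")
    return replace(state, present_lines=state.present_lines - {line_id})


def move_dot(state: FigureState, n_edges: int, direction: int) -> FigureState:
    """Move the dot ``n_edges`` edges along the internal path.

    ``direction`` is +1 toward corner 6 and -1 toward corner 1.  The dot never
    leaves the internal path (and hence never crosses the broken circle or the
    trapezium, which share no edge with it).
    """
    if n_edges < 0:
        raise InvalidArgumentError("n_edges must be non-negative")
    if direction not in (-1, 1):
        raise InvalidArgumentError("direction must be +1 or -1")
    target = state.dot_corner + direction * n_edges
    if not 1 <= target <= N_CORNERS:
        raise InfeasibleStateError(
            f"dot cannot move {n_edges} edges from corner {state.dot_corner} "
            f"in direction {direction:+d}: runs off the 5-edge path"
        )
    return replace(state, dot_corner=target)


def dot_reach(corner: int) -> int:
    """Largest number of edges the dot can traverse in one direction from
    ``corner`` on the 5-edge internal path."""
    return max(N_CORNERS - corner, corner - 1)
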
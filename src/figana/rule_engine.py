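"""The five general rules, their validation, and both solution pathways.

A figural analogy A:B::C:D transforms A into B and A into C by the *same*
set of rules with different arguments per pathway; D must be reachable both
by applying the A→C changes to B and the A→B changes to C.  Rules are the
item's *radicals*:

* ``main_rot``   — rotation of the main shape, one angle per pathway;
* ``mirror``     — reflection of the main shape (x-axis for A→B, y-axis for
  A→C); mutually exclusive with ``main_rot`` because a reflection composed
  with a rotation is indistinguishable from another reflection;
* ``trap_rot``   — rotation of the trapezium, one angle per pathway;
* ``subtract``   — removal of one internal line per pathway (or a random
  marker resolved at build time);
* ``dot_mov``    — dot movement by a number of edges per pathway, the two
  counts summing to at most 5 (the path length).

At most four radicals can therefore be active at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .shape_model import (
    Angle,
    FigureState,
    InfeasibleStateError,
    InvalidArgumentError,
    N_LINES,
    dot_reach,
    move_dot,
    reflect_main,
    rotate_main,
    rotate_trapezium,
    subtract_line,
)

__all__ = [
    "RANDOM_SUBTRACT",
    "GENERAL_RULES",
    "SPECIFIC_RULES",
    "RuleSet",
    "AnalogyStem",
    "validate_ruleset",
    "apply_pathway",
    "solve_item",
    "stem_dot_direction",
    "PathwayError",
]

#: Marker for "choose the subtracted lines at random at build time".
RANDOM_SUBTRACT = "R"

#: The five general rules, in canonical order.
GENERAL_RULES = (
    "main_rotation",
    "reflection",
    "trapezium_rotation",
    "subtraction",
    "dot_movement",
)


class PathwayError(RuntimeError):
    """The two solution pathways disagree (internal consistency failure)."""


def _angle_pair(pair) -> Tuple[Angle, Angle]:
    a, b = pair
    return (
        a if isinstance(a, Angle) else Angle(int(a)),
        b if isinstance(b, Angle) else Angle(int(b)),
    )


@dataclass(frozen=True)
class RuleSet:
    """The radicals of an item: per-pathway arguments for each active rule.

    Pairs are ordered ``(A→B, A→C)``.  ``subtract`` may be the string ``"R"``
    to request a random (build-time) choice of lines.
    """

    main_rot: Optional[Tuple[Angle, Angle]] = None
    mirror: bool = False
    trap_rot: Optional[Tuple[Angle, Angle]] = None
    subtract: Optional[object] = None  # (line, line) | "R"
    dot_mov: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.main_rot is not None:
            object.__setattr__(self, "main_rot", _angle_pair(self.main_rot))
        if self.trap_rot is not None:
            object.__setattr__(self, "trap_rot", _angle_pair(self.trap_rot))
        if self.subtract is not None and self.subtract != RANDOM_SUBTRACT:
            a, b = self.subtract
            object.__setattr__(self, "subtract", (int(a), int(b)))
        if self.dot_mov is not None:
            a, b = self.dot_mov
            object.__setattr__(self, "dot_mov", (int(a), int(b)))

    @property
    def active_rules(self) -> Tuple[str, ...]:
        """Names of the general rules this set manipulates."""
        names: List[str] = []
        if self.main_rot is not None:
            names.append("main_rotation")
        if self.mirror:
            names.append("reflection")
        if self.trap_rot is not None:
            names.append("trapezium_rotation")
        if self.subtract is not None:
            names.append("subtraction")
        if self.dot_mov is not None:
            names.append("dot_movement")
        return tuple(names)

    @property
    def n_rules(self) -> int:
        return len(self.active_rules)

    @property
    def dot_total(self) -> int:
        return sum(self.dot_mov) if self.dot_mov is not None else 0


@dataclass(frozen=True)
class ValidationReport:
    violations: Tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy == valid
        return self.ok


def validate_ruleset(rules: RuleSet) -> ValidationReport:
    """Check a rule set against the combination constraints.

    Violations are returned as data rather than raised, so callers can
    surface all problems at once.
    """
    v: List[str] = []
    if rules.n_rules == 0:
        v.append("at least one radical must be manipulated")
    if rules.main_rot is not None and rules.mirror:
        v.append(
            "mutually exclusive radicals: main rotation and reflection cannot "
            "be manipulated together (rule confusion)"
        )
    if rules.main_rot is not None and all(a.degrees == 0 for a in rules.main_rot):
        v.append("main rotation arguments are both zero (no rule effect)")
    if rules.trap_rot is not None and all(a.degrees == 0 for a in rules.trap_rot):
        v.append("trapezium rotation arguments are both zero (no rule effect)")
    if rules.subtract is not None and rules.subtract != RANDOM_SUBTRACT:
        a, b = rules.subtract
        if not (1 <= a <= N_LINES and 1 <= b <= N_LINES):
            v.append("subtracted line ids must lie in 1..5")
        elif a == b:
            v.append("subtraction must name a different line per pathway")
    if rules.dot_mov is not None:
        a, b = rules.dot_mov
        if a < 0 or b < 0:
            v.append("dot movement counts must be non-negative")
        elif a + b > N_LINES:
            v.append("sum exceeds five: the dot has only five edges to move through")
        elif a + b == 0:
            v.append("dot movement arguments are both zero (no rule effect)")
    return ValidationReport(tuple(v))


def stem_dot_direction(a: FigureState, rules: RuleSet) -> int:
    """Deterministic traversal direction for the dot in a stem.

    Both pathways move the dot the same way along the internal path, so the
    full movement ``dot_mov[0] + dot_mov[1]`` must fit in one direction from
    A's corner.  Prefers +1 (toward corner 6), falls back to -1; raises
    :class:`~figana.shape_model.InfeasibleStateError` when neither fits
    (callers re-draw incidentals).
    """
    total = rules.dot_total
    if a.dot_corner + total <= 6:
        return 1
    if a.dot_corner - total >= 1:
        return -1
    raise InfeasibleStateError(
        f"dot at corner {a.dot_corner} cannot travel {total} edges in either "
        f"direction (reach {dot_reach(a.dot_corner)})"
    )


def _pathway_index(pathway: str) -> int:
    if pathway in ("AB", "A->B"):
        return 0
    if pathway in ("AC", "A->C"):
        return 1
    raise InvalidArgumentError(f"pathway must be 'AB' or 'AC', got {pathway!r}")


def apply_pathway(
    a: FigureState,
    rules: RuleSet,
    pathway: str,
    *,
    start: Optional[FigureState] = None,
    dot_direction: Optional[int] = None,
) -> FigureState:
    """Apply one pathway's component of every active rule.

    By default the changes are applied to A itself (producing B or C).  To
    chain pathways (producing D from B or C), pass the intermediate figure as
    ``start``; the rule arguments are still selected by ``pathway``.

    Radicals act on disjoint parts of the figure, applied in the fixed order
    reflection/main rotation → trapezium rotation → subtraction → dot
    movement.  ``mirror`` means an x-axis reflection on the A→B pathway and a
    y-axis reflection on A→C.  ``subtract`` must already be concrete (the
    random marker is resolved by the item builder).
    """
    i = _pathway_index(pathway)
    state = a if start is None else start
    if rules.mirror:
        state = reflect_main(state, "x" if i == 0 else "y")
    if rules.main_rot is not None:
        state = rotate_main(state, rules.main_rot[i])
    if rules.trap_rot is not None:
        state = rotate_trapezium(state, rules.trap_rot[i])
    if rules.subtract is not None:
        if rules.subtract == RANDOM_SUBTRACT:
            raise InvalidArgumentError(
                "random subtraction must be resolved to concrete lines before "
                "pathways are applied"
            )
        state = subtract_line(state, rules.subtract[i])
    if rules.dot_mov is not None:
        d = dot_direction if dot_direction is not None else stem_dot_direction(a, rules)
        state = move_dot(state, rules.dot_mov[i], d)
    return state


@dataclass(frozen=True)
class AnalogyStem:
    """The three given figures of an analogy plus the rules that relate them."""

    A: FigureState
    B: FigureState
    C: FigureState
    rules: RuleSet
    dot_direction: int = 1

    @classmethod
    def from_a(cls, a: FigureState, rules: RuleSet) -> "AnalogyStem":
        """Build a stem by applying both pathways to A.

        Raises :class:`~figana.shape_model.InfeasibleStateError` when A's
        incidentals cannot host the rules (the item builder then re-draws).
        """
        report = validate_ruleset(rules)
        if not report.ok:
            raise InvalidArgumentError("; ".join(report.violations))
        d = stem_dot_direction(a, rules) if rules.dot_mov is not None else 1
        b = apply_pathway(a, rules, "AB", dot_direction=d)
        c = apply_pathway(a, rules, "AC", dot_direction=d)
        return cls(A=a, B=b, C=c, rules=rules, dot_direction=d)


def solve_item(stem: AnalogyStem) -> FigureState:
    """Compute the unique correct D and verify both pathways agree.

    ``D`` is obtained by applying the A→C changes to B and, independently,
    the A→B changes to C; a mismatch indicates a rule-engine bug and raises
    :class:`PathwayError`.
    """
    d1 = apply_pathway(
        stem.A, stem.rules, "AC", start=stem.B, dot_direction=stem.dot_direction
    )
    d2 = apply_pathway(
        stem.A, stem.rules, "AB", start=stem.C, dot_direction=stem.dot_direction
    )
    if d1 != d2:
        raise PathwayError(f"solution pathways disagree: {d1} vs {d2}")
    return d1


#: The nine specific rules as rule sets (canonical arguments).  Rotation
#: rules: "short" = 90° A→B / 45° A→C, "long" = 180° A→B / 135° A→C;
#: clockwise arguments are negative, and the long clockwise B-rotation is
#: written +180 (the two half-turns coincide).
SPECIFIC_RULES = {
    1: RuleSet(main_rot=(-90, -45)),
    2: RuleSet(main_rot=(90, 45)),
    3: RuleSet(main_rot=(180, -135)),
    4: RuleSet(trap_rot=(-90, -45)),
    5: RuleSet(trap_rot=(90, 45)),
    6: RuleSet(trap_rot=(180, -135)),
    7: RuleSet(mirror=True),
    8: RuleSet(subtract=RANDOM_SUBTRACT),
    9: RuleSet(dot_mov=(1, 2)),
}

#: Mapping from each specific rule to its general rule.
SPECIFIC_TO_GENERAL = {
    1: "main_rotation",
    2: "main_rotation",
    3: "main_rotation",
    4: "trapezium_rotation",
    5: "trapezium_rotation",
    6: "trapezium_rotation",
    7: "reflection",
    8: "subtraction",
    9: "dot_movement",
}


def merge_rulesets(*sets: RuleSet) -> RuleSet:
    """Combine rule sets that manipulate disjoint general rules."""
    kw = {}
    for rs in sets:
        for name, val in (
            ("main_rot", rs.main_rot),
            ("mirror", rs.mirror or None),
            ("trap_rot", rs.trap_rot),
            ("subtract", rs.subtract),
            ("dot_mov", rs.dot_mov),
        ):
            if val is not None:
                if name in kw:
                    raise InvalidArgumentError(
                        f"cannot merge rule sets: {name} specified twice"
                    )
                kw[name] = val
    if "mirror" in kw:
        kw["mirror"] = True
    return RuleSet(**kw)
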
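"""Solutions Combination Design (SCD) construction of response options.

For every rule manipulated in an item, one *correct* solution and a number of
*alternative* (incorrect) solutions are generated; the Cartesian product of
per-rule solutions yields candidate options, of which exactly eight survive:

* one-rule items:   4 × 2 (four solutions for the rule, two for an extra rule
  that is absent from the stem and whose correct solution is "no change");
* two-rule items:   3 × 3, eliminating one of the nine combinations that is
  not the key;
* three-rule items: 2³, nothing eliminated;
* four-rule items:  2⁴, eliminating combinations holding exactly three
  correct or exactly three incorrect solutions (8 remain).

The option holding all correct solutions is the only right answer.  When the
key is the verbal "no answer is correct" option (position 9), that option is
replaced by a similar near-miss that duplicates no other option, or by a
combination that had been targeted for elimination.

A per-rule solution is represented by its *effect* on the stem figure A:

* main shape (rotation or reflection rules): a dihedral-group element
  ``(delta_steps, flip)`` applied to A's orientation;
* trapezium: a rotation step count;
* subtraction: the set of removed lines;
* dot movement: the final corner.

Effects act on disjoint parts of the figure, so options built from distinct
per-rule effects are distinct figures by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .shape_model import FigureState, InvalidArgumentError, N_LINES
from .rule_engine import AnalogyStem, RuleSet, solve_item

__all__ = [
    "SCDLayout",
    "SolutionSet",
    "OptionList",
    "AssemblyError",
    "InvalidAlternativeError",
    "scd_design",
    "generate_alternatives",
    "assemble_options",
    "build_option_list",
]


class AssemblyError(RuntimeError):
    """Eight pairwise-distinct options could not be constructed."""


class InvalidAlternativeError(ValueError):
    """A user-supplied alternative reproduces the correct solution's effect."""


# ---------------------------------------------------------------------------
# effects

MainEffect = Tuple[int, bool]  # (counterclockwise 45° steps, x-flip first)


def _compose_main(state: FigureState, effect: MainEffect) -> FigureState:
    d, f = effect
    s = state.main_state - 1
    flipped = state.flipped
    if f:
        s, flipped = (-s) % 8, not flipped
    s = (s + d) % 8
    return replace(state, main_state=s + 1, flipped=flipped)


def apply_effect(state: FigureState, rule: str, value) -> FigureState:
    """Apply one per-rule solution effect to a figure."""
    if rule in ("main_rotation", "reflection"):
        return _compose_main(state, value)
    if rule == "trapezium_rotation":
        return replace(state, trap_state=(state.trap_state - 1 + value) % 8 + 1)
    if rule == "subtraction":
        missing = frozenset(value)
        if not missing <= state.present_lines:
            raise AssemblyError(f"cannot subtract absent lines {sorted(missing)}")
        return replace(state, present_lines=state.present_lines - missing)
    if rule == "dot_movement":
        return replace(state, dot_corner=int(value))
    raise InvalidArgumentError(f"unknown rule {rule!r}")


def correct_effects(stem: AnalogyStem) -> Dict[str, object]:
    """Per-rule effects that together turn A into the correct D."""
    rules = stem.rules
    eff: Dict[str, object] = {}
    if rules.main_rot is not None:
        d = (rules.main_rot[0].steps + rules.main_rot[1].steps) % 8
        eff["main_rotation"] = (d, False)
    if rules.mirror:
        # x-axis then y-axis reflection composes to a half-turn.
        eff["reflection"] = (4, False)
    if rules.trap_rot is not None:
        eff["trapezium_rotation"] = (rules.trap_rot[0].steps + rules.trap_rot[1].steps) % 8
    if rules.subtract is not None:
        eff["subtraction"] = frozenset(rules.subtract)
    if rules.dot_mov is not None:
        target = stem.A.dot_corner + stem.dot_direction * rules.dot_total
        eff["dot_movement"] = int(target)
    return eff


def identity_effect(rule: str, a: FigureState):
    """The no-change effect used as the extra rule's correct solution."""
    if rule in ("main_rotation", "reflection"):
        return (0, False)
    if rule == "trapezium_rotation":
        return 0
    if rule == "subtraction":
        return frozenset()
    if rule == "dot_movement":
        return int(a.dot_corner)
    raise InvalidArgumentError(f"unknown rule {rule!r}")


# ---------------------------------------------------------------------------
# design


@dataclass(frozen=True)
class SCDLayout:
    """Shape of the solutions-combination design for a given rule count."""

    n_rules: int
    per_rule_counts: Tuple[int, ...]
    eliminated: frozenset
    elimination_rule: str

    @property
    def raw_combinations(self) -> int:
        return int(np.prod(self.per_rule_counts))

    @property
    def n_eliminated(self) -> int:
        if self.elimination_rule == "one_both_incorrect":
            return 1
        return len(self.eliminated)

    @property
    def n_surviving(self) -> int:
        return self.raw_combinations - self.n_eliminated

    def combinations(self) -> List[Tuple[int, ...]]:
        """All index combinations; index 0 is the correct solution."""
        return list(itertools.product(*(range(c) for c in self.per_rule_counts)))


def scd_design(n_rules: int) -> SCDLayout:
    """Return the solutions-combination design for ``n_rules`` manipulated
    rules (1..4); every design leaves exactly eight surviving options."""
    if n_rules == 1:
        return SCDLayout(1, (4, 2), frozenset(), "none")
    if n_rules == 2:
        # One of the four both-incorrect combinations is dropped; which one is
        # decided at assembly time (most similar to the key, seeded tie-break).
        return SCDLayout(2, (3, 3), frozenset(), "one_both_incorrect")
    if n_rules == 3:
        return SCDLayout(3, (2, 2, 2), frozenset(), "none")
    if n_rules == 4:
        bad = frozenset(
            c for c in itertools.product(range(2), repeat=4) if sum(c) in (1, 3)
        )
        return SCDLayout(4, (2, 2, 2, 2), bad, "unbalanced_one_or_three")
    raise InvalidArgumentError(f"SCD is defined for 1..4 rules, got {n_rules}")


# ---------------------------------------------------------------------------
# alternatives


@dataclass(frozen=True)
class SolutionSet:
    """Correct solution and its alternatives for one rule."""

    rule: str
    correct: object
    alternatives: Tuple[object, ...]

    @property
    def values(self) -> Tuple[object, ...]:
        return (self.correct,) + self.alternatives


def _rotation_alternatives(correct_d: int, n: int, rng) -> List[int]:
    # near-miss offsets (±45°, ±90°) first; the far offsets only matter for
    # degenerate designs that need more than four solutions of one rotation
    near = list(rng.permutation([-2, -1, 1, 2]))
    far = list(rng.permutation([3, -3, 4]))
    return [int((correct_d + o) % 8) for o in (near + far)[:n]]


def _mirror_alternatives(correct: MainEffect, n: int, rng) -> List[MainEffect]:
    d0, f0 = correct
    cands: List[MainEffect] = [((d0 + o) % 8, f0) for o in (-2, -1, 1, 2)]
    cands += [(d, not f0) for d in (0, 2, 4, 6)]
    idx = rng.permutation(len(cands))[:n]
    return [cands[i] for i in idx]


def _subtraction_alternatives(correct: frozenset, n: int, rng) -> List[frozenset]:
    all_lines = set(range(1, N_LINES + 1))
    pool: List[frozenset] = []
    # near misses first: share one line with the correct pair
    for s in itertools.combinations(sorted(all_lines), 2):
        fs = frozenset(s)
        if fs != correct and fs - correct and fs & correct:
            pool.append(fs)
    for s in itertools.combinations(sorted(all_lines), 2):
        fs = frozenset(s)
        if fs != correct and not (fs & correct):
            pool.append(fs)
    for l in sorted(all_lines - correct):
        pool.append(frozenset([l]))
    if correct == frozenset():  # extra-rule case: any single line differs
        pool = [frozenset([l]) for l in sorted(all_lines)]
    order = rng.permutation(len(pool))
    out: List[frozenset] = []
    for i in order:
        if pool[i] not in out:
            out.append(pool[i])
        if len(out) == n:
            break
    return out


def _dot_alternatives(correct: int, n: int, rng) -> List[int]:
    adjacent = [c for c in (correct - 1, correct + 1) if 1 <= c <= 6]
    rest = [c for c in range(1, 7) if c != correct and c not in adjacent]
    pool = list(rng.permutation(adjacent)) + list(rng.permutation(rest))
    return [int(c) for c in pool[:n]]


def _coerce_user_alt(rule: str, v, correct):
    """Translate a user-specified alternative to its effect representation.

    Rotation alternatives are given as angle offsets (degrees) from the right
    answer; reflection alternatives as ``(angle_offset, flip)`` pairs;
    subtraction alternatives as up to two line ids (0 = none, at least one id
    outside the correct pair); dot alternatives as absolute corner numbers.
    """
    from .shape_model import Angle  # validates offset angles

    if rule in ("main_rotation", "trapezium_rotation", "reflection"):
        if rule == "reflection":
            off, flip = v
            d0, f0 = correct
            return ((d0 + Angle(int(off)).steps) % 8, bool(int(flip)) ^ f0)
        if isinstance(v, tuple) and len(v) == 2 and isinstance(v[0], int):
            # already an effect for main rotation
            if rule == "main_rotation" and isinstance(v[1], bool):
                return v
        if rule == "main_rotation":
            return ((correct[0] + Angle(int(v)).steps) % 8, correct[1])
        return (correct + Angle(int(v)).steps) % 8
    if rule == "subtraction":
        fs = frozenset(int(x) for x in v if int(x) != 0)
        if not fs:
            raise InvalidAlternativeError("subtraction alternative removes no line")
        if fs != correct and not (fs - frozenset(correct)):
            raise InvalidAlternativeError(
                "subtraction alternative must name at least one line outside "
                f"the correct pair {sorted(correct)}"
            )
        return fs
    if rule == "dot_movement":
        c = int(v)
        if not 1 <= c <= 6:
            raise InvalidArgumentError("dot alternative must be a corner 1..6")
        return c
    raise InvalidArgumentError(f"unknown rule {rule!r}")


def _auto_alternatives(rule: str, correct, n: int, rng):
    if rule == "main_rotation" or rule == "trapezium_rotation":
        if rule == "main_rotation":
            return [(d, False) for d in _rotation_alternatives(correct[0], n, rng)]
        return _rotation_alternatives(correct, n, rng)
    if rule == "reflection":
        return _mirror_alternatives(correct, n, rng)
    if rule == "subtraction":
        return _subtraction_alternatives(correct, n, rng)
    if rule == "dot_movement":
        return _dot_alternatives(correct, n, rng)
    raise InvalidArgumentError(f"unknown rule {rule!r}")


def generate_alternatives(
    stem: AnalogyStem,
    layout: SCDLayout,
    *,
    extra_rule: Optional[str] = None,
    user_alts: Optional[Dict[str, Sequence[object]]] = None,
    seed: int = 0,
) -> Tuple[SolutionSet, ...]:
    """Build per-rule solution sets for an item.

    ``extra_rule`` names the additional general rule of the 4 × 2 one-rule
    design (its correct solution is "no change").  ``user_alts`` may supply
    alternative effects per rule; counts must match the layout, and an
    alternative reproducing the correct effect is rejected (except dot
    corners, which are relocated to an adjacent corner instead).
    """
    rng = np.random.default_rng(seed)
    eff = correct_effects(stem)
    rule_names = list(eff)
    if extra_rule is not None:
        rule_names.append(extra_rule)
        eff[extra_rule] = identity_effect(extra_rule, stem.A)
    if len(rule_names) != len(layout.per_rule_counts):
        raise InvalidArgumentError(
            f"layout expects {len(layout.per_rule_counts)} rules, "
            f"got {len(rule_names)}"
        )

    sets: List[SolutionSet] = []
    for rule, count in zip(rule_names, layout.per_rule_counts):
        n_alt = count - 1
        if user_alts is not None and rule in user_alts:
            alts = list(user_alts[rule])
            if len(alts) != n_alt:
                raise InvalidArgumentError(
                    f"{rule}: expected {n_alt} alternatives, got {len(alts)}"
                )
            cleaned = []
            for v in alts:
                v = _coerce_user_alt(rule, v, eff[rule])
                if v == eff[rule] or v in cleaned:
                    if rule == "dot_movement":
                        v = _dot_alternatives(eff[rule], 6, rng)[0]
                        while v in cleaned:
                            v = _dot_alternatives(eff[rule], 6, rng)[0]
                    else:
                        raise InvalidAlternativeError(
                            f"{rule}: alternative {v!r} reproduces the correct "
                            "solution's effect"
                        )
                cleaned.append(v)
            alts = cleaned
        else:
            alts = _auto_alternatives(rule, eff[rule], n_alt, rng)
        if len(alts) < n_alt:
            raise AssemblyError(f"{rule}: cannot find {n_alt} distinct alternatives")
        sets.append(SolutionSet(rule, eff[rule], tuple(alts)))
    return tuple(sets)


# ---------------------------------------------------------------------------
# assembly


@dataclass(frozen=True)
class OptionList:
    """The eight figural options in reading order plus the verbal slots."""

    figural: Tuple[FigureState, ...]
    combination_by_slot: Tuple[Tuple[int, ...], ...]
    verbal_9: str = "no answer is correct"
    verbal_idk: str = "I don't know"

    def __post_init__(self) -> None:
        if len(self.figural) != 8:
            raise AssemblyError(f"expected 8 figural options, got {len(self.figural)}")


def _combo_state(a: FigureState, sets: Sequence[SolutionSet], combo) -> FigureState:
    state = a
    for s, idx in zip(sets, combo):
        state = apply_effect(state, s.rule, s.values[idx])
    return state


def _effect_distance(rule: str, v, w) -> float:
    """Crude visual dissimilarity between two effects of the same rule."""
    if rule in ("main_rotation", "reflection"):
        dd = min((v[0] - w[0]) % 8, (w[0] - v[0]) % 8)
        return dd + (4.0 if v[1] != w[1] else 0.0)
    if rule == "trapezium_rotation":
        return min((v - w) % 8, (w - v) % 8)
    if rule == "subtraction":
        return len(frozenset(v) ^ frozenset(w))
    if rule == "dot_movement":
        return abs(int(v) - int(w))
    return 0.0


def _similarity_to_key(sets: Sequence[SolutionSet], combo) -> float:
    return sum(
        _effect_distance(s.rule, s.values[i], s.correct) for s, i in zip(sets, combo)
    )


def assemble_options(
    layout: SCDLayout,
    sets: Sequence[SolutionSet],
    correct_position: int,
    seed: int,
    a: FigureState,
) -> OptionList:
    """Map surviving combinations onto the eight option slots.

    The all-correct combination lands at ``correct_position`` (1..8); with
    ``correct_position = 9`` it is replaced by a near-miss so that no figural
    option equals the true D and the verbal "no answer is correct" slot keys
    the item.  Slot order for the remaining options is a seeded shuffle.
    """
    if not 1 <= correct_position <= 9:
        raise InvalidArgumentError("correct position must lie in 1..9")
    rng = np.random.default_rng(seed)
    sets = list(sets)
    combos = layout.combinations()
    eliminated = set(layout.eliminated)
    if layout.elimination_rule == "one_both_incorrect":
        both_bad = [c for c in combos if all(i > 0 for i in c)]
        dist = np.array([_similarity_to_key(sets, c) for c in both_bad])
        best = np.flatnonzero(dist == dist.min())
        eliminated = {both_bad[int(rng.choice(best))]}
    survivors = [c for c in combos if c not in eliminated]
    if len(survivors) != 8:
        raise AssemblyError(
            f"design left {len(survivors)} combinations, expected 8"
        )
    key_combo = tuple(0 for _ in layout.per_rule_counts)

    if correct_position == 9:
        survivors.remove(key_combo)
        repl = _near_miss(layout, sets, survivors, eliminated, rng)
        survivors.append(repl)
        key_slot = None
    else:
        key_slot = correct_position - 1

    order = list(rng.permutation(len(survivors)))
    placed = [survivors[i] for i in order]
    if key_slot is not None:
        at = placed.index(key_combo)
        placed[at], placed[key_slot] = placed[key_slot], placed[at]

    states = [_combo_state(a, sets, c) for c in placed]
    for i, j in itertools.combinations(range(8), 2):
        if states[i] == states[j]:
            raise AssemblyError(
                f"options {i + 1} and {j + 1} coincide (combinations "
                f"{placed[i]} and {placed[j]})"
            )
    return OptionList(figural=tuple(states), combination_by_slot=tuple(placed))


def _near_miss(layout, sets, survivors, eliminated, rng):
    """A 'similar option' replacing the key for position-9 items."""
    # nearest single-rule swap not already among the survivors
    swaps = []
    for r, s in enumerate(sets):
        for ai in range(1, len(s.values)):
            combo = tuple(ai if k == r else 0 for k in range(len(sets)))
            d = _effect_distance(s.rule, s.values[ai], s.correct)
            swaps.append((d, rng.random(), combo))
    for _, _, combo in sorted(swaps):
        if combo not in survivors and all(
            i < c for i, c in zip(combo, layout.per_rule_counts)
        ):
            return combo
    # fall back to a combination targeted for elimination
    for combo in sorted(eliminated):
        if combo not in survivors:
            return combo
    # designs without eliminations (one- and three-rule items): draw a fresh
    # alternative outside the design for one rule, nearest rule first
    for r in rng.permutation(len(sets)):
        s = sets[r]
        for cand in _auto_alternatives(s.rule, s.correct, 8, rng):
            if cand not in s.values:
                sets[r] = SolutionSet(s.rule, s.correct, s.alternatives + (cand,))
                return tuple(
                    len(sets[r].values) - 1 if k == r else 0 for k in range(len(sets))
                )
    raise AssemblyError("cannot construct a replacement for the correct option")


def build_option_list(
    stem: AnalogyStem,
    correct_position: int,
    *,
    extra_rule: Optional[str] = None,
    user_alts: Optional[Dict[str, Sequence[object]]] = None,
    seed: int = 0,
) -> OptionList:
    """High-level helper: design + alternatives + assembly for one stem."""
    layout = scd_design(max(stem.rules.n_rules, 1))
    sets = generate_alternatives(
        stem, layout, extra_rule=extra_rule, user_alts=user_alts, seed=seed
    )
    return assemble_options(layout, sets, correct_position, seed + 1, stem.A)
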
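"""Generation of isomorph families: incidental enumeration and item assembly.

An *item model* is a rule set (the radicals).  Its family of *isomorphs*
shares those radicals and differs only in *incidentals* — the initial
positions of the parts of figure A: main-shape state (8), flip (2),
trapezium state (8) and dot corner (6), giving 8·2·8·6 = 768 configurations.
Isomorphs are drawn as a seeded permutation of that product; once exhausted
the same sequence repeats, which is reported as a warning on the bank.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .shape_model import (
    FigureState,
    InfeasibleStateError,
    InvalidArgumentError,
    N_LINES,
    dot_reach,
)
from .rule_engine import (
    GENERAL_RULES,
    RANDOM_SUBTRACT,
    AnalogyStem,
    RuleSet,
    solve_item,
    validate_ruleset,
)
from .distractor_engine import OptionList, build_option_list

__all__ = [
    "IncidentalSpace",
    "Item",
    "ItemBank",
    "enumerate_incidentals",
    "build_items",
    "relocate_dot_if_needed",
]

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class IncidentalSpace:
    """The subsets of part positions figure A may be drawn from."""

    main_states: Tuple[int, ...] = tuple(range(1, 9))
    flips: Tuple[bool, ...] = (False, True)
    trap_states: Tuple[int, ...] = tuple(range(1, 9))
    dot_corners: Tuple[int, ...] = tuple(range(1, 7))
    constrict: Optional[str] = None  # None | "main" | "trap" | "dot"

    def __post_init__(self) -> None:
        for name, vals, dom in (
            ("main_states", self.main_states, range(1, 9)),
            ("trap_states", self.trap_states, range(1, 9)),
            ("dot_corners", self.dot_corners, range(1, 7)),
        ):
            vals = tuple(sorted(set(int(v) for v in vals)))
            object.__setattr__(self, name, vals)
            if not vals or not set(vals) <= set(dom):
                raise InvalidArgumentError(f"{name} must be a non-empty subset of {dom}")
        object.__setattr__(self, "flips", tuple(sorted(set(bool(f) for f in self.flips))))
        if not self.flips:
            raise InvalidArgumentError("flips must be non-empty")
        if self.constrict not in (None, "main", "trap", "dot"):
            raise InvalidArgumentError(
                f"constrict must be one of None/'main'/'trap'/'dot', got {self.constrict!r}"
            )

    @property
    def capacity(self) -> int:
        """Number of distinct A configurations available."""
        return (
            len(self.main_states)
            * len(self.flips)
            * len(self.trap_states)
            * len(self.dot_corners)
        )


def _product(space: IncidentalSpace) -> List[FigureState]:
    return [
        FigureState(main_state=m, flipped=f, trap_state=t, dot_corner=d)
        for m, f, t, d in itertools.product(
            space.main_states, space.flips, space.trap_states, space.dot_corners
        )
    ]


def enumerate_incidentals(
    space: IncidentalSpace, seed: int = 0
) -> Iterator[FigureState]:
    """Yield A configurations: a seeded permutation of the incidental product,
    repeated verbatim after exhaustion.

    With ``constrict`` set, every consecutive block of *n* states covers all
    *n* positions of the constricted part (a fresh shuffle per block), the
    other parts drawn at random per state.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if space.constrict is None:
        states = _product(space)
        order = rng.permutation(len(states))
        while True:
            for i in order:
                yield states[i]
    else:
        domain = {
            "main": space.main_states,
            "trap": space.trap_states,
            "dot": space.dot_corners,
        }[space.constrict]
        while True:
            block = rng.permutation(len(domain))
            for i in block:
                m = int(rng.choice(space.main_states))
                f = bool(space.flips[int(rng.integers(len(space.flips)))])
                t = int(rng.choice(space.trap_states))
                d = int(rng.choice(space.dot_corners))
                v = int(domain[i])
                if space.constrict == "main":
                    m = v
                elif space.constrict == "trap":
                    t = v
                else:
                    d = v
                yield FigureState(main_state=m, flipped=f, trap_state=t, dot_corner=d)


def relocate_dot_if_needed(a: FigureState, dot_mov: Tuple[int, int]) -> FigureState:
    """Relocate A's dot toward the broken-circle corners when necessary.

    When the two movement counts sum to more than 3 and A's corner cannot
    host the full traversal in either direction, the dot is moved to the
    nearest corner adjacent to the broken circle (path corners 5 and 6) that
    can; sums of at most 3 always fit somewhere, and sums of at most 5 always
    fit at corner 6, so the result is feasible by construction.
    """
    total = sum(dot_mov)
    if total > N_LINES:
        raise InvalidArgumentError("dot movement counts must sum to at most 5")
    if total <= 3 or dot_reach(a.dot_corner) >= total:
        return a
    feasible = [c for c in (5, 6) if dot_reach(c) >= total]
    target = min(feasible, key=lambda c: (abs(c - a.dot_corner), c))
    return replace(a, dot_corner=target)


@dataclass(frozen=True)
class Item:
    """One complete figural analogy item."""

    stem: AnalogyStem
    solution: FigureState
    options: OptionList
    correct_position: int
    isomorph_index: int
    rules_used: Tuple[str, ...]
    extra_rule: Optional[str] = None

    @property
    def item_id(self) -> str:
        return f"item{self.isomorph_index:03d}"


@dataclass(frozen=True)
class ItemBank:
    """An ordered family of isomorphs built from one rule set."""

    items: Tuple[Item, ...]
    rules: RuleSet
    seed: int
    warnings: Tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i: int) -> Item:
        return self.items[i]


def _resolve_subtract(rules: RuleSet, rng) -> RuleSet:
    if rules.subtract != RANDOM_SUBTRACT:
        return rules
    a, b = rng.choice(N_LINES, size=2, replace=False) + 1
    return RuleSet(
        main_rot=rules.main_rot,
        mirror=rules.mirror,
        trap_rot=rules.trap_rot,
        subtract=(int(a), int(b)),
        dot_mov=rules.dot_mov,
    )


def _pick_extra_rule(rules: RuleSet, add_rule, rng) -> Optional[str]:
    """Extra general rule for the 4 × 2 design of one-rule items."""
    if rules.n_rules != 1:
        return None
    if add_rule == "suppressed":
        return None
    active = set(rules.active_rules)
    candidates = [r for r in GENERAL_RULES if r not in active]
    # reflection and main rotation stay mutually exclusive in the options too
    if "main_rotation" in active:
        candidates = [r for r in candidates if r != "reflection"]
    if "reflection" in active:
        candidates = [r for r in candidates if r != "main_rotation"]
    if add_rule == "auto":
        return candidates[int(rng.integers(len(candidates)))]
    if add_rule not in GENERAL_RULES:
        raise InvalidArgumentError(f"unknown rule name {add_rule!r}")
    if add_rule not in candidates:
        raise InvalidArgumentError(
            f"extra rule {add_rule!r} clashes with the manipulated rule"
        )
    return add_rule


def build_items(
    rules: RuleSet,
    n_isomorphs: int = 1,
    *,
    space: Optional[IncidentalSpace] = None,
    correct: Optional[Sequence[int]] = None,
    add_rule: str = "auto",
    seed: int = 0,
) -> ItemBank:
    """Generate ``n_isomorphs`` items sharing one rule set.

    Parameters
    ----------
    rules
        The radicals; must pass :func:`~figana.rule_engine.validate_ruleset`.
    n_isomorphs
        Number of clones to generate.
    space
        Incidental space to draw A configurations from (full by default).
    correct
        Positions for the correct answer (1..9, cycled in order across
        isomorphs); drawn seeded-randomly from 1..8 by default.
    add_rule
        Extra-rule policy for one-rule items: ``"auto"`` (seeded draw), a
        general-rule name, or ``"suppressed"``.
    seed
        Master seed; named substreams keep incidentals, subtraction, options
        and placement independently reproducible.
    """
    if n_isomorphs < 1:
        raise InvalidArgumentError("n_isomorphs must be at least 1")
    report = validate_ruleset(rules)
    if not report.ok:
        raise InvalidArgumentError("; ".join(report.violations))
    if correct is not None:
        correct = [int(c) for c in correct]
        if any(not 1 <= c <= 9 for c in correct):
            raise InvalidArgumentError("correct positions must lie in 1..9")

    space = space or IncidentalSpace()
    ss = np.random.SeedSequence(seed)
    s_inc, s_sub, s_opt, s_place, s_extra = ss.spawn(5)
    rng_sub = np.random.default_rng(s_sub)
    rng_place = np.random.default_rng(s_place)
    rng_extra = np.random.default_rng(s_extra)
    opt_seeds = np.random.default_rng(s_opt).integers(2**31 - 1, size=n_isomorphs)

    warnings: List[str] = []
    if n_isomorphs > space.capacity:
        msg = (
            f"requested {n_isomorphs} isomorphs but only {space.capacity} distinct "
            f"main problems exist; items after number {space.capacity} may repeat "
            "an earlier main problem"
        )
        warnings.append(msg)
        logger.warning(msg)
    if rules.n_rules == 1 and add_rule == "suppressed":
        msg = (
            "extra rule suppressed on a one-rule item: the 4 x 2 design falls "
            "back to eight solutions of the single rule, which may be impossible "
            "for some rules"
        )
        warnings.append(msg)
        logger.warning(msg)
    if correct is not None and 9 in correct:
        msg = (
            "position 9 ('no answer is correct') keyed as the right answer; "
            "use with caution on difficult items"
        )
        warnings.append(msg)
        logger.warning(msg)

    incidentals = enumerate_incidentals(space, seed=int(s_inc.generate_state(1)[0] % 2**31))
    items: List[Item] = []
    for k in range(n_isomorphs):
        item_rules = _resolve_subtract(rules, rng_sub)
        stem = None
        for _attempt in range(_MAX_REDRAWS):
            a = next(incidentals)
            if rules.dot_mov is not None:
                a = relocate_dot_if_needed(a, rules.dot_mov)
            try:
                stem = AnalogyStem.from_a(a, item_rules)
                break
            except InfeasibleStateError:
                continue
        if stem is None:
            raise InfeasibleStateError(
                f"no feasible incidental configuration found in {_MAX_REDRAWS} draws"
            )
        d = solve_item(stem)
        pos = (
            correct[k % len(correct)]
            if correct is not None
            else int(rng_place.integers(1, 9))
        )
        extra = _pick_extra_rule(item_rules, add_rule, rng_extra)
        if item_rules.n_rules == 1 and extra is None:
            # degenerate fallback: eight solutions of the single rule
            from .distractor_engine import (
                SCDLayout,
                assemble_options,
                generate_alternatives,
            )

            layout = SCDLayout(1, (8,), frozenset(), "none")
            sets = generate_alternatives(stem, layout, seed=int(opt_seeds[k]))
            options = assemble_options(layout, sets, pos, int(opt_seeds[k]) + 1, stem.A)
        else:
            options = build_option_list(
                stem, pos, extra_rule=extra, seed=int(opt_seeds[k])
            )
        items.append(
            Item(
                stem=stem,
                solution=d,
                options=options,
                correct_position=pos,
                isomorph_index=k + 1,
                rules_used=item_rules.active_rules,
                extra_rule=extra,
            )
        )
    logger.info(
        "built %d isomorph(s) from rules %s (seed %d, capacity %d)",
        n_isomorphs,
        rules.active_rules,
        seed,
        space.capacity,
    )
    return ItemBank(items=tuple(items), rules=rules, seed=seed, warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# JSON serialization (for the CLI and answer-key round trips)


def _state_dict(s: FigureState) -> dict:
    return {
        "main_state": s.main_state,
        "flipped": s.flipped,
        "trap_state": s.trap_state,
        "dot_corner": s.dot_corner,
        "present_lines": sorted(s.present_lines),
    }


def _state_from(d: dict) -> FigureState:
    return FigureState(
        main_state=d["main_state"],
        flipped=d["flipped"],
        trap_state=d["trap_state"],
        dot_corner=d["dot_corner"],
        present_lines=frozenset(d["present_lines"]),
    )


def _rules_dict(r: RuleSet) -> dict:
    return {
        "main_rot": [a.degrees for a in r.main_rot] if r.main_rot else None,
        "mirror": r.mirror,
        "trap_rot": [a.degrees for a in r.trap_rot] if r.trap_rot else None,
        "subtract": (
            list(r.subtract) if r.subtract not in (None, RANDOM_SUBTRACT) else r.subtract
        ),
        "dot_mov": list(r.dot_mov) if r.dot_mov else None,
    }


def _rules_from(d: dict) -> RuleSet:
    sub = d["subtract"]
    return RuleSet(
        main_rot=tuple(d["main_rot"]) if d["main_rot"] else None,
        mirror=d["mirror"],
        trap_rot=tuple(d["trap_rot"]) if d["trap_rot"] else None,
        subtract=tuple(sub) if isinstance(sub, list) else sub,
        dot_mov=tuple(d["dot_mov"]) if d["dot_mov"] else None,
    )


def bank_to_json(bank: ItemBank) -> str:
    """Serialize a bank (losslessly for rendering/key purposes) to JSON."""
    payload = {
        "rules": _rules_dict(bank.rules),
        "seed": bank.seed,
        "warnings": list(bank.warnings),
        "items": [
            {
                "isomorph_index": it.isomorph_index,
                "correct_position": it.correct_position,
                "rules_used": list(it.rules_used),
                "extra_rule": it.extra_rule,
                "dot_direction": it.stem.dot_direction,
                "stem_rules": _rules_dict(it.stem.rules),
                "A": _state_dict(it.stem.A),
                "B": _state_dict(it.stem.B),
                "C": _state_dict(it.stem.C),
                "solution": _state_dict(it.solution),
                "options": [_state_dict(s) for s in it.options.figural],
                "combination_by_slot": [list(c) for c in it.options.combination_by_slot],
            }
            for it in bank.items
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def bank_from_json(text: str) -> ItemBank:
    d = json.loads(text)
    items = []
    for it in d["items"]:
        stem = AnalogyStem(
            A=_state_from(it["A"]),
            B=_state_from(it["B"]),
            C=_state_from(it["C"]),
            rules=_rules_from(it["stem_rules"]),
            dot_direction=it["dot_direction"],
        )
        options = OptionList(
            figural=tuple(_state_from(s) for s in it["options"]),
            combination_by_slot=tuple(tuple(c) for c in it["combination_by_slot"]),
        )
        items.append(
            Item(
                stem=stem,
                solution=_state_from(it["solution"]),
                options=options,
                correct_position=it["correct_position"],
                isomorph_index=it["isomorph_index"],
                rules_used=tuple(it["rules_used"]),
                extra_rule=it["extra_rule"],
            )
        )
    return ItemBank(
        items=tuple(items),
        rules=_rules_from(d["rules"]),
        seed=d["seed"],
        warnings=tuple(d["warnings"]),
    )
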
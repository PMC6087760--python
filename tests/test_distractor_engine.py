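import itertools

import numpy as np
import pytest

from figana.shape_model import FigureState, InvalidArgumentError
from figana.rule_engine import SPECIFIC_RULES, AnalogyStem, RuleSet, merge_rulesets, solve_item
from figana.distractor_engine import (
    InvalidAlternativeError,
    assemble_options,
    build_option_list,
    generate_alternatives,
    scd_design,
)

RULESETS_BY_COUNT = {
    1: RuleSet(trap_rot=(90, 45)),
    2: merge_rulesets(SPECIFIC_RULES[2], RuleSet(subtract=(1, 4))),
    3: merge_rulesets(SPECIFIC_RULES[7], SPECIFIC_RULES[4], SPECIFIC_RULES[9]),
    4: merge_rulesets(
        SPECIFIC_RULES[1], SPECIFIC_RULES[6], RuleSet(subtract=(2, 5)), SPECIFIC_RULES[9]
    ),
}


def make_stem(n_rules, a=None):
    a = a or FigureState()
    return AnalogyStem.from_a(a, RULESETS_BY_COUNT[n_rules])


# ---------------------------------------------------------------------------
# design shapes


def test_design_counts():
    d1 = scd_design(1)
    assert d1.per_rule_counts == (4, 2) and d1.raw_combinations == 8
    d2 = scd_design(2)
    assert d2.raw_combinations == 9 and d2.n_eliminated == 1 and d2.n_surviving == 8
    d3 = scd_design(3)
    assert d3.per_rule_counts == (2, 2, 2) and d3.raw_combinations == 8
    d4 = scd_design(4)
    assert d4.raw_combinations == 16 and d4.n_surviving == 8


def test_four_rule_elimination_matches_balance_rule():
    """Independent enumeration: drop combinations with exactly one or three
    incorrect solutions (equivalently three or one correct)."""
    layout = scd_design(4)
    expected = {
        c for c in itertools.product(range(2), repeat=4) if sum(c) in (1, 3)
    }
    assert set(layout.eliminated) == expected
    assert len(expected) == 8


def test_design_rejects_out_of_range():
    with pytest.raises(InvalidArgumentError):
        scd_design(0)
    with pytest.raises(InvalidArgumentError):
        scd_design(5)


# ---------------------------------------------------------------------------
# alternatives


def test_rotation_alternatives_offset_from_key_never_equal():
    stem = make_stem(1)
    layout = scd_design(1)
    sets = generate_alternatives(stem, layout, extra_rule="dot_movement", seed=3)
    trap_set = next(s for s in sets if s.rule == "trapezium_rotation")
    assert len(trap_set.alternatives) == 3
    assert all(alt != trap_set.correct for alt in trap_set.alternatives)
    assert len(set(trap_set.alternatives)) == 3


def test_user_alternative_reproducing_key_rejected():
    stem = make_stem(2)
    layout = scd_design(2)
    with pytest.raises(InvalidAlternativeError):
        generate_alternatives(
            stem, layout, user_alts={"main_rotation": [0, 45]}, seed=0
        )


def test_user_alternative_count_checked():
    stem = make_stem(2)
    with pytest.raises(InvalidArgumentError):
        generate_alternatives(
            stem, scd_design(2), user_alts={"main_rotation": [45]}, seed=0
        )


def test_user_dot_alternative_on_key_is_relocated():
    stem = make_stem(3)
    layout = scd_design(3)
    key_corner = solve_item(stem).dot_corner
    sets = generate_alternatives(
        stem, layout, user_alts={"dot_movement": [key_corner]}, seed=0
    )
    dot_set = next(s for s in sets if s.rule == "dot_movement")
    assert dot_set.alternatives[0] != key_corner


def test_subtraction_alternative_must_differ():
    stem = make_stem(2)
    rules = RULESETS_BY_COUNT[2]
    sub_stem = AnalogyStem.from_a(FigureState(), rules)
    with pytest.raises(InvalidAlternativeError):
        generate_alternatives(
            sub_stem,
            scd_design(2),
            user_alts={"subtraction": [(1, 0), (4, 0)]},  # both inside (1,4)
            seed=0,
        )


def test_alternatives_are_seed_deterministic():
    stem = make_stem(4)
    layout = scd_design(4)
    s1 = generate_alternatives(stem, layout, seed=5)
    s2 = generate_alternatives(stem, layout, seed=5)
    assert s1 == s2


# ---------------------------------------------------------------------------
# assembly


@pytest.mark.parametrize("n_rules", [1, 2, 3, 4])
def test_eight_distinct_options_with_unique_key(n_rules):
    extra = "subtraction" if n_rules == 1 else None
    for seed in range(40):
        a = FigureState(
            main_state=(seed % 8) + 1,
            trap_state=((seed * 3) % 8) + 1,
            dot_corner=(seed % 4) + 1,
        )
        stem = make_stem(n_rules, a)
        d = solve_item(stem)
        pos = (seed % 8) + 1
        options = build_option_list(stem, pos, extra_rule=extra, seed=seed)
        assert len(set(options.figural)) == 8
        matches = [k for k, o in enumerate(options.figural, start=1) if o == d]
        assert matches == [pos]


@pytest.mark.parametrize("n_rules", [1, 2, 3, 4])
def test_position_nine_removes_key_from_figural_options(n_rules):
    extra = "main_rotation" if n_rules == 1 else None
    stem = make_stem(n_rules)
    d = solve_item(stem)
    options = build_option_list(stem, 9, extra_rule=extra, seed=13)
    assert len(set(options.figural)) == 8
    assert all(o != d for o in options.figural)


def test_seed_permutes_placement_not_content():
    stem = make_stem(3)
    layout = scd_design(3)
    sets = generate_alternatives(stem, layout, seed=1)
    o1 = assemble_options(layout, sets, 2, seed=10, a=stem.A)
    o2 = assemble_options(layout, sets, 2, seed=20, a=stem.A)
    assert sorted(map(hash, o1.figural)) == sorted(map(hash, o2.figural))
    assert o1.figural[1] == o2.figural[1] == solve_item(stem)


def test_correct_position_validated():
    stem = make_stem(3)
    layout = scd_design(3)
    sets = generate_alternatives(stem, layout, seed=1)
    with pytest.raises(InvalidArgumentError):
        assemble_options(layout, sets, 0, seed=0, a=stem.A)
    with pytest.raises(InvalidArgumentError):
        assemble_options(layout, sets, 10, seed=0, a=stem.A)
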
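import itertools

import numpy as np
import pytest

from figana.shape_model import (
    Angle,
    FigureState,
    InfeasibleStateError,
    InvalidArgumentError,
    N_CORNERS,
    N_LINES,
    VALID_ANGLES,
    build_template,
    dot_reach,
    move_dot,
    reflect_main,
    rotate_main,
    rotate_trapezium,
    subtract_line,
)

ALL_FORMS = ["A", "B", "C", "D"]


def all_states():
    for m, f, t, d in itertools.product(range(1, 9), (False, True), range(1, 9), range(1, 7)):
        yield FigureState(main_state=m, flipped=f, trap_state=t, dot_corner=d)


# ---------------------------------------------------------------------------
# template geometry


@pytest.mark.parametrize("fi,fe", list(itertools.product(ALL_FORMS, ALL_FORMS)))
def test_template_topology(fi, fe):
    t = build_template(fi, fe)
    assert len(t.corner_positions) == N_CORNERS
    assert len(t.internal_lines) == N_LINES
    # internal lines form the simple path c1-c2-...-c6
    assert t.internal_lines == tuple((k, k + 1) for k in range(1, 6))


def test_templates_differ_across_forms():
    a = build_template("A", "A")
    b = build_template("B", "C")
    assert a.corner_positions != b.corner_positions
    assert a.trapezium != b.trapezium


@pytest.mark.parametrize("fi", ALL_FORMS)
def test_internal_lines_are_interior_chords(fi):
    """No internal line coincides with a hexagon outline edge."""
    t = build_template(fi, "A")
    pts = np.asarray(t.corner_positions)
    centroid = pts.mean(axis=0)
    hull_order = np.argsort(np.arctan2(*(pts - centroid).T[::-1]))
    hull_edges = {
        frozenset((hull_order[i], hull_order[(i + 1) % 6])) for i in range(6)
    }
    for i, j in t.internal_lines:
        assert frozenset((i - 1, j - 1)) not in hull_edges


@pytest.mark.parametrize("fi", ALL_FORMS)
def test_longest_simple_path_has_five_edges(fi):
    """Exhaustive path search over the 6-node internal-line graph."""
    t = build_template(fi, "A")
    edges = {frozenset(e) for e in t.internal_lines}
    longest = 0
    for perm in itertools.permutations(range(1, 7)):
        length = 0
        for a, b in zip(perm, perm[1:]):
            if frozenset((a, b)) in edges:
                length += 1
            else:
                break
        longest = max(longest, length)
    assert longest == 5


def test_unknown_form_rejected():
    with pytest.raises(InvalidArgumentError):
        build_template("E", "A")
    with pytest.raises(InvalidArgumentError):
        build_template("A", "Z")


# ---------------------------------------------------------------------------
# angles


@pytest.mark.parametrize("deg", VALID_ANGLES)
def test_valid_angles(deg):
    assert Angle(deg).steps == deg // 45


@pytest.mark.parametrize("deg", [30, -140, 225, 181, 1])
def test_invalid_angles(deg):
    with pytest.raises(InvalidArgumentError):
        Angle(deg)


# ---------------------------------------------------------------------------
# main-shape rotation and reflection (exhaustive over the dihedral group)


def test_rotation_advances_counterclockwise():
    s = FigureState(main_state=1)
    assert rotate_main(s, 90).main_state == 3
    assert rotate_main(s, -45).main_state == 8
    assert rotate_main(s, 0) == s


def test_rotation_cancellation_exhaustive():
    for s in all_states():
        for deg in VALID_ANGLES:
            assert rotate_main(rotate_main(s, deg), -deg if deg != 180 else 180) == s


def test_rotation_touches_only_main_state():
    s = FigureState(main_state=2, flipped=True, trap_state=5, dot_corner=4,
                    present_lines=frozenset({1, 3}))
    r = rotate_main(s, 135)
    assert (r.flipped, r.trap_state, r.dot_corner, r.present_lines) == (
        s.flipped, s.trap_state, s.dot_corner, s.present_lines)


def test_reflections_are_involutions():
    for s in all_states():
        assert reflect_main(reflect_main(s, "x"), "x") == s
        assert reflect_main(reflect_main(s, "y"), "y") == s


def test_x_reflection_plus_half_turn_equals_y_reflection():
    for s in all_states():
        assert rotate_main(reflect_main(s, "x"), 180) == reflect_main(s, "y")


def test_reflection_rejects_unknown_axis():
    with pytest.raises(InvalidArgumentError):
        reflect_main(FigureState(), "z")


# ---------------------------------------------------------------------------
# trapezium


def test_trapezium_rotation_modular():
    s = FigureState(trap_state=1)
    assert rotate_trapezium(s, 180).trap_state == 5
    assert rotate_trapezium(s, 0) == s
    t = s
    for _ in range(8):
        t = rotate_trapezium(t, 45)
    assert t == s


def test_trapezium_independent_of_lines():
    s = FigureState(present_lines=frozenset({2, 5}))
    assert rotate_trapezium(s, -90).present_lines == s.present_lines


# ---------------------------------------------------------------------------
# subtraction


def test_subtract_removes_named_line():
    s = FigureState()
    assert subtract_line(s, 1).present_lines == frozenset({2, 3, 4, 5})


def test_subtract_contract_violations():
    with pytest.raises(InvalidArgumentError):
        subtract_line(FigureState(), 6)
    missing3 = FigureState(present_lines=frozenset({1, 2, 4, 5}))
    with pytest.raises(InfeasibleStateError):
        subtract_line(missing3, 3)


# ---------------------------------------------------------------------------
# dot movement, checked against a breadth-first search on the path graph


def _bfs_reachable(corner, n_edges, direction):
    """Independent oracle: walk the path graph edge by edge."""
    adj = {c: [] for c in range(1, 7)}
    for a, b in zip(range(1, 6), range(2, 7)):
        adj[a].append(b)
        adj[b].append(a)
    pos = corner
    for _ in range(n_edges):
        nxt = [n for n in adj[pos] if (n - pos) * direction > 0]
        if not nxt:
            return None
        pos = nxt[0]
    return pos


def test_move_dot_matches_bfs_oracle():
    for corner in range(1, 7):
        for n in range(0, 7):
            for direction in (-1, 1):
                s = FigureState(dot_corner=corner)
                expected = _bfs_reachable(corner, n, direction)
                if expected is None:
                    with pytest.raises(InfeasibleStateError):
                        move_dot(s, n, direction)
                else:
                    assert move_dot(s, n, direction).dot_corner == expected


def test_move_dot_zero_is_identity():
    s = FigureState(dot_corner=3)
    assert move_dot(s, 0, 1) == s


def test_dot_reach():
    assert dot_reach(1) == 5
    assert dot_reach(3) == 3
    assert dot_reach(6) == 5


# ---------------------------------------------------------------------------
# property: arbitrary transformation chains stay on the 16-element dihedral
# orbit and never touch unrelated fields

from hypothesis import given, settings, strategies as st

_moves = st.lists(
    st.one_of(
        st.tuples(st.just("rot"), st.sampled_from(VALID_ANGLES)),
        st.tuples(st.just("ref"), st.sampled_from(["x", "y"])),
        st.tuples(st.just("trap"), st.sampled_from(VALID_ANGLES)),
    ),
    max_size=12,
)


@settings(derandomize=True, max_examples=60)
@given(
    start=st.tuples(
        st.integers(1, 8), st.booleans(), st.integers(1, 8), st.integers(1, 6)
    ),
    moves=_moves,
)
def test_transformation_chains_preserve_untouched_fields(start, moves):
    s = FigureState(
        main_state=start[0], flipped=start[1], trap_state=start[2], dot_corner=start[3]
    )
    undo = []
    cur = s
    for kind, arg in moves:
        if kind == "rot":
            cur = rotate_main(cur, arg)
            undo.append(("rot", -arg if arg != 180 else 180))
        elif kind == "ref":
            cur = reflect_main(cur, arg)
            undo.append(("ref", arg))
        else:
            cur = rotate_trapezium(cur, arg)
            undo.append(("trap", -arg if arg != 180 else 180))
        assert 1 <= cur.main_state <= 8 and 1 <= cur.trap_state <= 8
        assert cur.dot_corner == s.dot_corner
        assert cur.present_lines == s.present_lines
    for kind, arg in reversed(undo):
        cur = {"rot": rotate_main, "ref": reflect_main, "trap": rotate_trapezium}[kind](
            cur, arg
        )
    assert cur == s
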
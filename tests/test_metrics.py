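"""Tests for the performance measures, including independent oracles."""

import itertools
import math

import numpy as np
import pytest

import gridlink as gl
from gridlink.metrics import (
    MetricsError,
    SubPath,
    classify_moves,
    compute_level_metrics,
    excess_moves,
    mean_velocity,
    mental_planning_time,
    motor_execution_time,
    movement_direction_changes,
    orthogonal_direction_changes,
    rdp_simplify,
    segment_subpaths,
    summarize_session,
    total_solving_time,
)
from gridlink.session import BoardSnapshot, Move, TouchEvent, segment_moves


def ev(t, kind, x=0.0, y=0.0):
    return TouchEvent(t, x, y, kind)


def make_move(samples):
    events = [
        TouchEvent(t, x, y, "down" if i == 0 else "up" if i == len(samples) - 1 else "move")
        for i, (t, x, y) in enumerate(samples)
    ]
    return Move(tuple(events))


# ---------------------------------------------------------------------------
# time measures
# ---------------------------------------------------------------------------

def test_tst_subtraction_example():
    events = [ev(1000, "down"), ev(8550, "solved")]
    assert total_solving_time(events) == pytest.approx(7.55)


def test_tst_undefined_without_solved():
    assert total_solving_time([ev(1000, "down"), ev(2000, "up")]) is None


def test_met_sums_move_durations():
    m1 = make_move([(0, 0, 0), (400, 10, 0)])
    m2 = make_move([(1000, 0, 0), (1600, 10, 0)])
    assert motor_execution_time([m1, m2]) == pytest.approx(1.0)
    assert motor_execution_time([]) == 0.0


def test_mpt_examples_and_error():
    assert mental_planning_time(10.0, 4.0) == pytest.approx(6.0)
    assert mental_planning_time(5.0, 5.0) == 0.0
    with pytest.raises(MetricsError):
        mental_planning_time(3.0, 4.0)


def test_tst_matches_simulator_schedule(puzzle_5555):
    profile = gl.PlayerProfile(drag_speed=1200.0, plan_pause_mean=0.8, plan_pause_sd=0.3)
    geom = gl.default_geometry(puzzle_5555)
    for seed in range(5):
        events, snaps, gt = gl.simulate_level(puzzle_5555, profile, geom, seed=seed)
        tst = total_solving_time(events)
        sample_period = 1.0 / profile.sample_rate
        assert tst == pytest.approx(gt["tst_expected"], abs=1e-9)
        met = motor_execution_time(segment_moves(events))
        assert met == pytest.approx(gt["met_expected"], abs=1e-9)
        assert mental_planning_time(tst, met) == pytest.approx(
            gt["pauses_in_tst"], abs=2 * sample_period + 0.01
        )


def test_met_matches_kinematics_oracle(puzzle_4444):
    # constant drag speed v, total drawn arc L  =>  MET ~ L / v
    v = 1000.0
    profile = gl.PlayerProfile(drag_speed=v)
    geom = gl.default_geometry(puzzle_4444)
    events, _, _ = gl.simulate_level(puzzle_4444, profile, geom, seed=6)
    moves = segment_moves(events)
    arc = sum(
        math.hypot(b.x - a.x, b.y - a.y)
        for mv in moves
        for a, b in zip(mv.events, mv.events[1:])
    )
    met = motor_execution_time(moves)
    assert met == pytest.approx(arc / v, abs=2 * len(moves) / profile.sample_rate)


# ---------------------------------------------------------------------------
# accuracy measures
# ---------------------------------------------------------------------------

def test_classify_error_free_session(puzzle_5555, perfect_profile):
    geom = gl.default_geometry(puzzle_5555)
    events, snaps, _ = gl.simulate_level(puzzle_5555, perfect_profile, geom, seed=9)
    moves = segment_moves(events)
    false, correct = classify_moves(moves, snaps, puzzle_5555)
    assert (false, correct) == (0, puzzle_5555.n_pairs)


def test_classify_injected_errors_ground_truth(puzzle_5555):
    profile = gl.PlayerProfile(drag_speed=1100.0, plan_pause_mean=0.3,
                               plan_pause_sd=0.1, error_prob=0.7)
    geom = gl.default_geometry(puzzle_5555)
    hits = 0
    for seed in range(10):
        events, snaps, gt = gl.simulate_level(puzzle_5555, profile, geom, seed=seed)
        moves = segment_moves(events)
        false, correct = classify_moves(moves, snaps, puzzle_5555)
        assert false == gt["errors"]
        assert correct == puzzle_5555.n_pairs
        hits += gt["errors"]
    assert hits > 0


def test_classify_drawn_deleted_redrawn_is_false(puzzle_4444, perfect_profile):
    """A correct path deleted before the end of the level counts as false."""
    geom = gl.default_geometry(puzzle_4444)
    events, snaps, _ = gl.simulate_level(puzzle_4444, perfect_profile, geom, seed=12)
    moves = segment_moves(events)
    # identify the first move's label from the snapshot diff
    first_label = next(
        lab for lab, cells in snaps[-1].label_cells().items()
        if _post_state(snaps, moves[0].t_up).get(lab) == cells
    )
    path_cells = _post_state(snaps, moves[0].t_up)[first_label]
    dots = {c for p in puzzle_4444.pairs if p.label == first_label for c in (p.a, p.b)}
    t0 = moves[0].t_up
    # deletion tap: path reduced back to its dots, then redrawn identically
    delete_move = make_move([(t0 + 10, 0, 0), (t0 + 60, 0, 0)])
    redraw_move = make_move([(t0 + 100, 0, 0), (t0 + 200, 0, 0)])
    state_t0 = max((s for s in snaps if s.t <= t0), key=lambda s: s.t)
    cleared = _with_label_cells(state_t0, first_label, dots)
    restored = _with_label_cells(state_t0, first_label, path_cells)
    timeline = [s for s in snaps if s.t <= t0]
    timeline += [BoardSnapshot(t0 + 60, cleared), BoardSnapshot(t0 + 200, restored)]
    timeline += [_shift(s, 300) for s in snaps if s.t > t0]
    all_moves = [moves[0], delete_move, redraw_move] + [
        _shift_move(m, 300) for m in moves[1:]
    ]
    false, correct = classify_moves(all_moves, timeline, puzzle_4444)
    assert false >= 2  # the deleted original and the deletion tap itself
    assert correct == puzzle_4444.n_pairs


def _post_state(snaps, t):
    best = None
    for s in snaps:
        if s.t <= t:
            best = s
    return best.label_cells() if best else {}


def _with_label_cells(snapshot, label, cells):
    grid = [list(row) for row in snapshot.cells]
    for r, row in enumerate(grid):
        for c, state in enumerate(row):
            if state == label:
                grid[r][c] = "0"
    for cell in cells:
        grid[cell.row][cell.col] = label
    return tuple(tuple(row) for row in grid)


def _shift(snapshot, dt):
    return BoardSnapshot(snapshot.t + dt, snapshot.cells)


def _shift_move(move, dt):
    return Move(tuple(TouchEvent(e.t + dt, e.x, e.y, e.kind) for e in move.events))


def test_classify_requires_final_match(puzzle_4444, perfect_profile):
    geom = gl.default_geometry(puzzle_4444)
    events, snaps, _ = gl.simulate_level(puzzle_4444, perfect_profile, geom, seed=2)
    moves = segment_moves(events)
    with pytest.raises(MetricsError, match="final snapshot"):
        classify_moves(moves, snaps[:-1], puzzle_4444)


def test_excess_moves_arithmetic():
    assert excess_moves(7, 5) == 2
    assert excess_moves(5, 5) == 0
    assert excess_moves(5, 5, hint_pairs=1) == 1
    with pytest.raises(MetricsError):
        excess_moves(3, 5)


# ---------------------------------------------------------------------------
# RDP and sub-paths
# ---------------------------------------------------------------------------

def test_rdp_collinear_keeps_endpoints_only():
    pts = np.array([[0, 0], [1, 0], [2, 0], [3, 0], [4, 0]], dtype=float)
    assert rdp_simplify(pts, 0.5) == [0, 4]


def test_rdp_l_trace_keeps_corner():
    pts = np.array([[0, 0], [50, 0], [100, 0], [100, 50], [100, 100]], dtype=float)
    assert rdp_simplify(pts, 10.0) == [0, 2, 4]


def test_rdp_validates_input():
    with pytest.raises(MetricsError):
        rdp_simplify(np.zeros((1, 2)), 1.0)
    with pytest.raises(MetricsError):
        rdp_simplify(np.zeros((3, 2)), -1.0)


def rdp_exhaustive_oracle(pts, eps):
    """All minimum-cardinality vertex subsets approximating within eps."""
    n = len(pts)

    def ok(i, j):
        seg = pts[j] - pts[i]
        norm = np.hypot(*seg)
        for k in range(i + 1, j):
            rel = pts[k] - pts[i]
            d = np.hypot(*rel) if norm == 0 else abs(seg[0] * rel[1] - seg[1] * rel[0]) / norm
            if d > eps:
                return False
        return True

    best, best_size = [], n + 1
    interior = list(range(1, n - 1))
    for size in range(0, len(interior) + 1):
        if size + 2 > best_size:
            break
        for combo in itertools.combinations(interior, size):
            subset = [0, *combo, n - 1]
            if all(ok(i, j) for i, j in zip(subset, subset[1:])):
                if size + 2 < best_size:
                    best, best_size = [subset], size + 2
                elif size + 2 == best_size:
                    best.append(subset)
        if best:
            break
    return best


def test_rdp_matches_exhaustive_subset_oracle(rng):
    for _ in range(30):
        # random rectilinear trace, <= 12 points. Legs get distinct lengths:
        # with equal legs a U-shaped trace has its chord parallel to the
        # middle leg, a known RDP degeneracy where an extra mid-leg vertex
        # is retained and the minimal subset is not reproduced.
        eps = 20.0
        n_seg = int(rng.integers(1, 4))
        step_counts = list(rng.permutation([2, 3, 4])[:n_seg])
        pts = [np.array([0.0, 0.0])]
        direction = np.array([1.0, 0.0])
        for steps in step_counts:
            for _ in range(int(steps)):
                pts.append(pts[-1] + direction * 60.0)
            direction = np.array([direction[1], direction[0]]) * rng.choice([-1.0, 1.0])
        pts = np.array(pts[:12])
        jitter = rng.uniform(-eps / 6, eps / 6, size=pts.shape)
        jitter[0] = jitter[-1] = 0
        noisy = pts + jitter
        got = rdp_simplify(noisy, eps)
        assert got in rdp_exhaustive_oracle(noisy, eps)


def test_subpath_counts_and_axes():
    straight = make_move([(0, 0, 0), (20, 50, 0), (40, 100, 0)])
    subs = segment_subpaths(straight, epsilon=5.0)
    assert len(subs) == 1 and subs[0].axis == "horizontal"

    l_move = make_move([
        (0, 0, 0), (20, 60, 0), (40, 120, 0), (60, 120, 60), (80, 120, 120),
    ])
    subs = segment_subpaths(l_move, epsilon=10.0)
    assert len(subs) == 2
    assert [s.axis for s in subs] == ["horizontal", "vertical"]


def test_subpaths_fencepost_n_turns(puzzle_5555, perfect_profile):
    geom = gl.default_geometry(puzzle_5555)
    events, _, _ = gl.simulate_level(puzzle_5555, perfect_profile, geom, seed=3)
    eps = 0.25 * geom.cell_size
    for mv in segment_moves(events):
        pts = np.array([(e.x, e.y) for e in mv.events])
        turns = len(rdp_simplify(pts, eps)) - 2
        assert len(segment_subpaths(mv, epsilon=eps)) == turns + 1


def test_rdp_turns_match_solution_turn_cells(puzzle_5555):
    """Detected turns sit on the solution path's turn cells (jitter < eps/2)."""
    geom = gl.default_geometry(puzzle_5555)
    profile = gl.PlayerProfile(drag_speed=1000.0, jitter_sd=4.0)  # << eps/2 = 12.5
    events, snaps, _ = gl.simulate_level(puzzle_5555, profile, geom, seed=7)
    eps = 0.25 * geom.cell_size
    moves = segment_moves(events)
    by_label = {p.label: p for p in puzzle_5555.solution}
    for mv in moves:
        pts = np.array([(e.x, e.y) for e in mv.events])
        kept = rdp_simplify(pts, eps)
        start = gl.map_touch_to_cell(mv.events[0].x, mv.events[0].y, geom, puzzle_5555.board)
        label = next(l for l, p in by_label.items() if start in (p.cells[0], p.cells[-1]))
        path = by_label[label]
        corner_cells = {
            path.cells[i]
            for i in range(1, len(path.cells) - 1)
            if gl.count_turns(gl.GridPath("x", path.cells[i - 1 : i + 2])) == 1
        }
        detected = {
            gl.map_touch_to_cell(pts[i][0], pts[i][1], geom, puzzle_5555.board)
            for i in kept[1:-1]
        }
        assert detected == corner_cells


# ---------------------------------------------------------------------------
# velocity and direction changes
# ---------------------------------------------------------------------------

def _subpath(samples, axis):
    return SubPath(np.array(samples, dtype=float), axis)


def test_mean_velocity_examples():
    sp = _subpath([(0, 0, 0), (500, 500, 0)], "horizontal")
    assert mean_velocity([sp]) == pytest.approx(1000.0)
    sp2 = _subpath([(0, 0, 0), (1000, 800, 0)], "horizontal")
    sp3 = _subpath([(0, 0, 0), (1000, 1200, 0)], "horizontal")
    assert mean_velocity([sp2, sp3]) == pytest.approx(1000.0)


def test_mean_velocity_total_mode_weighted():
    sp2 = _subpath([(0, 0, 0), (1000, 800, 0)], "horizontal")
    sp3 = _subpath([(0, 0, 0), (1000, 1200, 0)], "horizontal")
    assert mean_velocity([sp2, sp3], mode="total") == pytest.approx(1000.0)
    with pytest.raises(MetricsError):
        mean_velocity([sp2], mode="banana")


def test_mean_velocity_excludes_zero_duration():
    sp = _subpath([(0, 0, 0), (500, 500, 0)], "horizontal")
    degenerate = _subpath([(0, 0, 0), (0, 10, 0)], "horizontal")
    with pytest.warns(UserWarning, match="zero-duration"):
        assert mean_velocity([sp, degenerate]) == pytest.approx(1000.0)


def test_mdc_monotone_zero():
    sp = _subpath([(0, 0, 0), (10, 5, 0), (20, 10, 0), (30, 10, 0)], "horizontal")
    assert movement_direction_changes([sp]) == 0


def test_mdc_advance_back_advance_two():
    sp = _subpath([(0, 0, 0), (10, 10, 0), (20, 5, 0), (30, 15, 0)], "horizontal")
    assert movement_direction_changes([sp]) == 2


def test_orthogonal_reversals_diagnostic():
    sp = _subpath([(0, 0, 0), (10, 10, 2), (20, 20, -2), (30, 30, 2)], "horizontal")
    assert orthogonal_direction_changes([sp]) == 2
    assert movement_direction_changes([sp]) == 0


def test_mdc_ground_truth_recovery(puzzle_5555):
    profile = gl.PlayerProfile(drag_speed=1000.0, reversal_rate=2.0)
    geom = gl.default_geometry(puzzle_5555)
    eps = 0.25 * geom.cell_size
    seen = 0
    for seed in range(10):
        events, _, gt = gl.simulate_level(puzzle_5555, profile, geom, seed=seed)
        subs = []
        for mv in segment_moves(events):
            subs.extend(segment_subpaths(mv, epsilon=eps))
        assert movement_direction_changes(subs) == gt["reversals"]
        seen += gt["reversals"]
    assert seen > 0


def test_mve_jitter_only_inflates(puzzle_4444):
    v = 1500.0
    geom = gl.default_geometry(puzzle_4444)
    base = gl.PlayerProfile(drag_speed=v)
    noisy = gl.PlayerProfile(drag_speed=v, jitter_sd=3.0)
    m0 = compute_level_metrics(*gl.simulate_level(puzzle_4444, base, geom, seed=3)[:2],
                               puzzle_4444, geom)
    m1 = compute_level_metrics(*gl.simulate_level(puzzle_4444, noisy, geom, seed=3)[:2],
                               puzzle_4444, geom)
    assert m0.mve == pytest.approx(v, rel=0.02)
    assert m1.mve >= m0.mve * 0.999


# ---------------------------------------------------------------------------
# pipeline and aggregation
# ---------------------------------------------------------------------------

def test_conservation_tst_met_mpt(puzzle_5555):
    profile = gl.PlayerProfile(drag_speed=1300.0, plan_pause_mean=0.6, plan_pause_sd=0.3,
                               jitter_sd=2.0, reversal_rate=1.0, error_prob=0.3)
    geom = gl.default_geometry(puzzle_5555)
    for seed in range(10):
        events, snaps, _ = gl.simulate_level(puzzle_5555, profile, geom, seed=seed)
        m = compute_level_metrics(events, snaps, puzzle_5555, geom)
        assert m.tst == pytest.approx(m.met + m.mpt, abs=1e-3)


def test_injected_error_never_decreases_counts(puzzle_4444):
    """Prepend a wrong partial move to a clean session: every affected
    measure moves the right way."""
    geom = gl.default_geometry(puzzle_4444)
    profile = gl.PlayerProfile(drag_speed=1000.0, plan_pause_mean=1.0)
    events, snaps, _ = gl.simulate_level(puzzle_4444, profile, geom, seed=21)
    base = compute_level_metrics(events, snaps, puzzle_4444, geom)

    moves = segment_moves(events)
    final = snaps[-1].label_cells()
    first_label = next(
        lab for lab, cells in final.items()
        if _post_state(snaps, moves[0].t_up).get(lab) == cells
    )
    path = next(p for p in puzzle_4444.solution if p.label == first_label)
    start = moves[0].events[0]
    start_cell = gl.map_touch_to_cell(start.x, start.y, geom, puzzle_4444.board)
    cells = path.cells if path.cells[0] == start_cell else path.cells[::-1]
    partial = cells[1]  # one interior cell of the eventual path
    t0 = moves[0].t_down
    x0, y0 = geom.cell_center(cells[0])
    x1, y1 = geom.cell_center(partial)
    injected_events = [
        TouchEvent(t0 - 600, x0, y0, "down"),
        TouchEvent(t0 - 500, (x0 + x1) / 2, (y0 + y1) / 2, "move"),
        TouchEvent(t0 - 400, x1, y1, "up"),
    ]
    assert t0 >= 700  # the 1 s planning pause leaves room for the injection
    grid = [list(row) for row in snaps[0].cells]
    grid[partial.row][partial.col] = first_label
    injected_snap = BoardSnapshot(t0 - 450, tuple(tuple(r) for r in grid))
    events2 = injected_events + events
    snaps2 = [snaps[0], injected_snap] + list(snaps[1:])
    with_err = compute_level_metrics(events2, snaps2, puzzle_4444, geom)
    assert with_err.false_moves == base.false_moves + 1
    assert with_err.excess_moves == base.excess_moves + 1
    assert with_err.met >= base.met
    assert with_err.tst >= base.tst


def test_summarize_examples():
    mk = lambda tst: gl.LevelMetrics(True, tst, tst / 2, tst / 2, 0, 0, 0, 1000.0, 0)
    summary = summarize_session([mk(5.0), mk(7.0), mk(9.0)])
    assert summary.medians["tst"] == 7.0
    same = summarize_session([mk(4.0)] * 3)
    assert same.medians["tst"] == 4.0 and same.iqrs["tst"] == 0.0


def test_summarize_requires_solved_level():
    unsolved = gl.LevelMetrics(False, None, 1.0, None, 2, None, 0, 900.0, 3)
    with pytest.raises(MetricsError):
        summarize_session([unsolved])


def test_summarize_matches_sort_oracle(rng):
    for _ in range(50):
        values = rng.uniform(1, 60, size=int(rng.integers(1, 25)))
        mk = lambda tst: gl.LevelMetrics(True, float(tst), 0.0, float(tst), 0, 0, 0, 500.0, 0)
        summary = summarize_session([mk(v) for v in values])
        s = sorted(values)
        n = len(s)
        oracle = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
        assert summary.medians["tst"] == pytest.approx(oracle)


def test_unsolved_level_flagged(puzzle_4444, perfect_profile):
    geom = gl.default_geometry(puzzle_4444)
    events, snaps, _ = gl.simulate_level(puzzle_4444, perfect_profile, geom, seed=14)
    truncated = [e for e in events if e.kind != "solved"]
    m = compute_level_metrics(truncated, snaps, puzzle_4444, geom)
    assert not m.solved and m.tst is None and m.mpt is None
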
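"""Cognitive and motor performance measures for one played level.

Seven measures are computed per level from the touch log and the
snapshot log:

* ``tst`` — total solving time: first touch to the solved event (s);
* ``met`` — motor execution time: summed drag-move durations (s);
* ``mpt`` — mental planning time: ``tst - met`` (s);
* ``false_moves`` — drawn paths absent from the final solution, or
  deleted/overwritten before the level was solved;
* ``excess_moves`` — total moves minus the number of dot pairs;
* ``mve`` — mean drag velocity over detected sub-paths (px/s);
* ``mdc`` — movement direction changes: along-axis sign reversals
  within sub-paths, summed over the level.

Drag moves are split into axis-aligned sub-paths at the turns detected
by Ramer-Douglas-Peucker polyline simplification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .puzzle import Cell, Puzzle
from .session import BoardGeometry, BoardSnapshot, Move, TouchEvent, segment_moves


class MetricsError(ValueError):
    """Inconsistent logs (e.g. final state not matching the solution)."""


@dataclass(frozen=True)
class MetricsConfig:
    #: RDP tolerance as a fraction of the cell size: below half a cell so
    #: true corners survive, above typical touch jitter.
    rdp_epsilon_cells: float = 0.25
    #: 'per_subpath': unweighted mean of sub-path arc speeds (default);
    #: 'total': total arc length over total time.
    mve_mode: str = "per_subpath"


@dataclass(frozen=True)
class SubPath:
    """Axis-aligned stretch of one drag, delimited by detected turns."""

    points: np.ndarray  # (n, 3) columns t_ms, x, y
    axis: str  # 'horizontal' | 'vertical'

    @property
    def duration(self) -> float:
        return (self.points[-1, 0] - self.points[0, 0]) / 1000.0

    @property
    def arc_length(self) -> float:
        d = np.diff(self.points[:, 1:3], axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class LevelMetrics:
    solved: bool
    tst: float | None
    met: float
    mpt: float | None
    false_moves: int
    excess_moves: int | None
    hints: int
    mve: float | None
    mdc: int


@dataclass
class SessionMetrics:
    """Per-measure aggregates (median / IQR / SD) over solved levels."""

    n_levels: int
    medians: dict[str, float] = field(default_factory=dict)
    iqrs: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# time measures
# ---------------------------------------------------------------------------

def total_solving_time(events: list[TouchEvent]) -> float | None:
    """Seconds from the first touch down to the solved event, or None."""
    downs = [e.t for e in events if e.kind == "down"]
    solved = [e.t for e in events if e.kind == "solved"]
    if not solved or not downs:
        return None
    return (solved[-1] - downs[0]) / 1000.0


def motor_execution_time(moves: list[Move]) -> float:
    """Sum of drag durations in seconds (false moves are moves too)."""
    return sum(m.duration for m in moves)


def mental_planning_time(tst: float, met: float) -> float:
    if met > tst + 1e-9:
        raise MetricsError(f"MET ({met}) exceeds TST ({tst}): inconsistent segmentation")
    return max(0.0, tst - met)


# ---------------------------------------------------------------------------
# accuracy measures
# ---------------------------------------------------------------------------

def _state_at(snapshots: list[BoardSnapshot], t: int, strict_before: bool = False):
    """Last snapshot at (or strictly before) time t, else None."""
    best = None
    for s in snapshots:
        if (s.t < t) if strict_before else (s.t <= t):
            best = s
        else:
            break
    return best


def solution_label_cells(puzzle: Puzzle) -> dict[str, frozenset[Cell]]:
    if puzzle.solution is None:
        raise MetricsError("puzzle has no reference solution")
    return {p.label: frozenset(p.cells) for p in puzzle.solution}


def classify_moves(
    moves: list[Move], snapshots: list[BoardSnapshot], puzzle: Puzzle
) -> tuple[int, int]:
    """Split moves into (false, correct) using the snapshot timeline.

    A move is *correct* when the path it leaves for its label equals
    that label's solution path and survives unchanged to the end of the
    level; anything else (wrong or partial paths, deletions, no-op
    taps, paths later cleared or overwritten) is a false move.
    """
    if not snapshots:
        raise MetricsError("no snapshots recorded")
    target = solution_label_cells(puzzle)
    final = snapshots[-1].label_cells()
    if final != target:
        raise MetricsError("final snapshot does not match the reference solution")

    false_count = 0
    for mv in moves:
        pre = _state_at(snapshots, mv.t_down, strict_before=True)
        if pre is None:
            pre = snapshots[0]  # initial board state
        # walk every state change inside the move window so mid-move
        # resets (redraw over an old path) attribute to the right label
        window = [pre] + [s for s in snapshots if mv.t_down <= s.t <= mv.t_up]
        changed: set[str] = set()
        states = [s.label_cells() for s in window]
        for a, b in zip(states, states[1:]):
            changed |= {
                lab
                for lab in set(a) | set(b)
                if a.get(lab, frozenset()) != b.get(lab, frozenset())
            }
        if len(changed) != 1:
            false_count += 1  # no-op tap or multi-label disturbance
            continue
        label = next(iter(changed))
        drawn = states[-1].get(label, frozenset())
        if drawn != target.get(label):
            false_count += 1
            continue
        survived = all(
            s.label_cells().get(label, frozenset()) == drawn
            for s in snapshots
            if s.t > mv.t_up
        )
        if not survived:
            false_count += 1
    return false_count, len(moves) - false_count


def excess_moves(total_moves: int, n_pairs: int, hint_pairs: int = 0) -> int:
    """Moves beyond the optimum of one per (non-hinted) pair."""
    effective = n_pairs - hint_pairs
    excess = total_moves - effective
    if excess < 0:
        raise MetricsError(
            f"{total_moves} moves cannot solve {effective} pairs: inconsistent logs"
        )
    return excess


# ---------------------------------------------------------------------------
# movement measures
# ---------------------------------------------------------------------------

def rdp_simplify(points: np.ndarray, epsilon: float) -> list[int]:
    """Ramer-Douglas-Peucker simplification; returns retained indices.

    Recursively keeps the point with maximum perpendicular distance to
    the chord while that distance exceeds ``epsilon``. Endpoints are
    always retained; interior retained vertices are the detected turns.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise MetricsError("rdp_simplify expects an (n >= 2, 2) point array")
    if epsilon < 0:
        raise MetricsError("epsilon must be >= 0")
    keep = [0, len(pts) - 1]
    stack = [(0, len(pts) - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        seg = pts[j] - pts[i]
        norm = np.hypot(*seg)
        mid = pts[i + 1 : j]
        if norm == 0.0:
            dist = np.hypot(mid[:, 0] - pts[i, 0], mid[:, 1] - pts[i, 1])
        else:
            rel = mid - pts[i]
            dist = np.abs(seg[0] * rel[:, 1] - seg[1] * rel[:, 0]) / norm
        k = int(np.argmax(dist))
        if dist[k] > epsilon:
            k += i + 1
            keep.append(k)
            stack.append((i, k))
            stack.append((k, j))
    return sorted(keep)


def _move_points(move: Move) -> np.ndarray:
    return np.array([(e.t, e.x, e.y) for e in move.events], dtype=float)


def segment_subpaths(move: Move, turn_indices: list[int] | None = None,
                     epsilon: float = 0.0) -> list[SubPath]:
    """Cut a move into sub-paths at the detected turns.

    ``turn_indices`` are the retained vertices from :func:`rdp_simplify`
    (computed here with ``epsilon`` when omitted). A straight move
    yields a single sub-path; each sub-path's axis is assigned from its
    dominant displacement. Sub-paths with fewer than 2 samples are
    merged into their neighbor with a warning.
    """
    pts = _move_points(move)
    if turn_indices is None:
        turn_indices = rdp_simplify(pts[:, 1:3], epsilon)
    idx = sorted(set(turn_indices) | {0, len(pts) - 1})
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise MetricsError("turn indices must be strictly increasing")
    subpaths: list[SubPath] = []
    for i, j in zip(idx, idx[1:]):
        seg = pts[i : j + 1]
        if len(seg) < 2:
            warnings.warn("sub-path with < 2 samples merged into neighbor")
            continue
        dx = abs(seg[-1, 1] - seg[0, 1])
        dy = abs(seg[-1, 2] - seg[0, 2])
        axis = "horizontal" if dx >= dy else "vertical"
        subpaths.append(SubPath(seg, axis))
    return subpaths


def mean_velocity(subpaths: list[SubPath], mode: str = "per_subpath") -> float | None:
    """Average movement speed in px/s over the detected sub-paths."""
    if mode not in ("per_subpath", "total"):
        raise MetricsError(f"unknown MVE mode {mode!r}")
    usable = []
    for sp in subpaths:
        if sp.duration <= 0:
            warnings.warn("excluding zero-duration sub-path from MVE")
            continue
        usable.append(sp)
    if not usable:
        return None
    if mode == "total":
        return sum(sp.arc_length for sp in usable) / sum(sp.duration for sp in usable)
    return float(np.mean([sp.arc_length / sp.duration for sp in usable]))


def _axis_reversals(sp: SubPath, orthogonal: bool = False) -> int:
    col = 1 if (sp.axis == "horizontal") != orthogonal else 2
    deltas = np.diff(sp.points[:, col])
    signs = np.sign(deltas)
    signs = signs[signs != 0]  # zero components skipped
    if len(signs) < 2:
        return 0
    return int(np.count_nonzero(signs[1:] != signs[:-1]))


def movement_direction_changes(subpaths: list[SubPath]) -> int:
    """Along-axis movement reversals summed over sub-paths."""
    return sum(_axis_reversals(sp) for sp in subpaths)


def orthogonal_direction_changes(subpaths: list[SubPath]) -> int:
    """Reversals on the off-axis component (diagnostic only)."""
    return sum(_axis_reversals(sp, orthogonal=True) for sp in subpaths)


# ---------------------------------------------------------------------------
# level pipeline and session aggregation
# ---------------------------------------------------------------------------

def compute_level_metrics(
    events: list[TouchEvent],
    snapshots: list[BoardSnapshot],
    puzzle: Puzzle,
    geometry: BoardGeometry,
    config: MetricsConfig | None = None,
) -> LevelMetrics:
    """Run the full per-level measurement pipeline."""
    config = config or MetricsConfig()
    hints = sum(1 for e in events if e.kind == "hint")
    moves = segment_moves(events)
    tst = total_solving_time(events)
    met = motor_execution_time(moves)
    solved = tst is not None
    mpt = mental_planning_time(tst, met) if solved else None

    eps = config.rdp_epsilon_cells * geometry.cell_size
    subpaths: list[SubPath] = []
    for mv in moves:
        subpaths.extend(segment_subpaths(mv, epsilon=eps))
    mve = mean_velocity(subpaths, config.mve_mode)
    mdc = movement_direction_changes(subpaths)

    if solved:
        false_count, _ = classify_moves(moves, snapshots, puzzle)
        excess = excess_moves(len(moves), puzzle.n_pairs, hint_pairs=hints)
    else:
        false_count, excess = len(moves), None
    return LevelMetrics(
        solved=solved,
        tst=tst,
        met=met,
        mpt=mpt,
        false_moves=false_count,
        excess_moves=excess,
        hints=hints,
        mve=mve,
        mdc=mdc,
    )


_MEASURES = ("tst", "met", "mpt", "false_moves", "excess_moves", "hints", "mve", "mdc")


def summarize_session(level_metrics: list[LevelMetrics]) -> SessionMetrics:
    """Median, IQR and SD of each measure across solved levels."""
    solved = [m for m in level_metrics if m.solved]
    if not solved:
        raise MetricsError("no solved level to aggregate")
    out = SessionMetrics(n_levels=len(solved))
    for name in _MEASURES:
        values = [getattr(m, name) for m in solved]
        values = [v for v in values if v is not None]
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        out.medians[name] = float(median(values))
        q1, q3 = np.percentile(arr, [25, 75])
        out.iqrs[name] = float(q3 - q1)
        out.sds[name] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return out
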
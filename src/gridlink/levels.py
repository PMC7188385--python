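"""Graded difficulty levels and random full-cover puzzle generation.

Difficulty is a tuple ``(width, height, n_paths, n_turns)``: board
dimensions, number of dot pairs, and the exact total number of path
turns of the reference solution. The generator produces a random
full-cover path partition matching the tuple, using two routes:

* *frontier growth* — seed ``n_paths`` walk heads at random cells and
  grow them by randomized frontier expansion (optionally biased toward
  straight continuation) until the board is covered, then accept if the
  turn total matches;
* *snake cut* — cut a boustrophedon cover into ``n_paths`` pieces,
  placing cuts at sites that each remove 0, 1 or 2 turns, which reaches
  any turn total in ``[2*(rows - k), 2*(rows - 1)]`` exactly.

Growth gives variety; the snake cut guarantees termination for every
turn total it can reach. Some extreme tuples admit no full cover at all
(or none we can construct); :func:`feasible_turns` reports the turn
totals the generator supports for a given board and path count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .puzzle import Board, Cell, DotPair, GridPath, Puzzle, count_turns, solve_brute_force

_DOT_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

MIN_DIM, MAX_DIM = 4, 8
MIN_PATHS = 4
MIN_TURNS = 4


class GenerationError(RuntimeError):
    """Raised when rejection sampling exhausts its attempt budget."""


@dataclass(frozen=True, order=True)
class DifficultyLevel:
    """One graded difficulty tuple (width, height, paths, turns)."""

    width: int
    height: int
    n_paths: int
    n_turns: int

    def __post_init__(self) -> None:
        m = max(self.width, self.height)
        if not (MIN_DIM <= self.width <= MAX_DIM and MIN_DIM <= self.height <= MAX_DIM):
            raise ValueError(f"board dimensions must be in [{MIN_DIM},{MAX_DIM}]: {self}")
        if not (MIN_PATHS <= self.n_paths <= m):
            raise ValueError(f"n_paths must be in [{MIN_PATHS},{m}]: {self}")
        # n_turns == 0 is reserved for the first practice puzzle
        if self.n_turns != 0 and not (MIN_TURNS <= self.n_turns <= m):
            raise ValueError(f"n_turns must be 0 or in [{MIN_TURNS},{m}]: {self}")

    @property
    def area(self) -> int:
        return self.width * self.height

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.width, self.height, self.n_paths, self.n_turns)


@dataclass
class LevelSet:
    """An ordered collection of levels forming one assessment set."""

    set_id: str  # "A" | "B" | "practice"
    version: str  # "short" | "medium" | "long" | "full" | "practice"
    levels: list[DifficultyLevel]
    order_seed: int | None = None


@dataclass(frozen=True)
class GenerationConfig:
    seed: int | None = None
    max_attempts: int = 10_000
    solver_check: bool = False

    def __post_init__(self) -> None:
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


# ---------------------------------------------------------------------------
# feasibility
# ---------------------------------------------------------------------------

def _snake_intervals(width: int, height: int, n_paths: int) -> list[tuple[int, int]]:
    out = []
    for rows in {height, width}:
        if n_paths <= rows:
            out.append((2 * (rows - n_paths), 2 * (rows - 1)))
    return out

# Turn totals only reachable by frontier growth (verified empirically:
# the snake-cut intervals of the 4x8 board leave these holes, yet random
# growth finds full covers for them at a usable rate).
_GROWTH_ONLY: dict[tuple[int, int, int], frozenset[int]] = {
    (4, 8, 4): frozenset({7}),
    (4, 8, 5): frozenset({4, 5}),
}


def feasible_turns(width: int, height: int, n_paths: int) -> frozenset[int]:
    """Turn totals in ``[4, max(w, h)]`` the generator can realise.

    The returned set excludes tuples for which no full cover is known:
    e.g. ``(8, 8)`` with 4 paths admits no cover with fewer than 8 turns
    (a path of ``s`` segments covers at most ``7s + 1`` cells, so 64
    cells with 4 paths need at least ``ceil(60/7) - 4 + ...`` segments),
    and nearby low-turn tuples were never realised in large randomized
    sweeps.
    """
    m = max(width, height)
    ok: set[int] = set()
    for lo, hi in _snake_intervals(width, height, n_paths):
        ok.update(range(max(MIN_TURNS, lo), min(m, hi) + 1))
    key = (min(width, height), max(width, height), n_paths)
    ok.update(_GROWTH_ONLY.get(key, frozenset()))
    return frozenset(t for t in ok if MIN_TURNS <= t <= m)


# ---------------------------------------------------------------------------
# frontier-growth route
# ---------------------------------------------------------------------------

def _grow_cover(
    width: int, height: int, k: int, rng: np.random.Generator, bias: float
) -> list[list[Cell]] | None:
    """One attempt at a random full-cover partition into k paths."""
    n = width * height
    starts = rng.choice(n, size=k, replace=False)
    paths: list[list[tuple[int, int]]] = [[(int(s) % width, int(s) // width)] for s in starts]
    covered = {p[0] for p in paths}
    ends = [(i, side) for i in range(k) for side in (0, 1)]
    while len(covered) < n:
        if not ends:
            return None
        ei = int(rng.integers(len(ends)))
        pi, side = ends[ei]
        path = paths[pi]
        c, r = path[0] if side == 0 else path[-1]
        nbrs = [
            (c + dc, r + dr)
            for dc, dr in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= c + dc < width and 0 <= r + dr < height and (c + dc, r + dr) not in covered
        ]
        if not nbrs:
            ends.pop(ei)
            continue
        if len(path) >= 2 and bias != 1.0:
            pc, pr = path[1] if side == 0 else path[-2]
            straight = (2 * c - pc, 2 * r - pr)
            weights = np.array([bias if nb == straight else 1.0 for nb in nbrs])
            nb = nbrs[int(rng.choice(len(nbrs), p=weights / weights.sum()))]
        else:
            nb = nbrs[int(rng.integers(len(nbrs)))]
        if side == 0:
            path.insert(0, nb)
        else:
            path.append(nb)
        covered.add(nb)
    if any(len(p) < 3 for p in paths):
        return None
    return [[Cell(c, r) for c, r in p] for p in paths]


# ---------------------------------------------------------------------------
# snake-cut route
# ---------------------------------------------------------------------------

def _snake_sequence(width: int, height: int) -> list[tuple[int, int]]:
    seq = []
    for r in range(height):
        cols = range(width) if r % 2 == 0 else range(width - 1, -1, -1)
        seq.extend((c, r) for c in cols)
    return seq


def _cut_snake(
    width: int, height: int, k: int, t: int, rng: np.random.Generator, tries: int = 400
) -> list[list[Cell]] | None:
    """Cut a boustrophedon cover into k pieces with exactly t turns total.

    Each of the ``height - 1`` row transitions carries two adjacent turn
    cells. Cutting between them removes both turns; cutting one cell
    earlier removes one; mid-row cuts remove none. Cuts are assigned to
    distinct transitions / rows so pieces stay >= 3 cells apart.
    """
    orients = []
    if k <= height and 2 * (height - k) <= t <= 2 * (height - 1):
        orients.append(False)  # row-major as-is
    if k <= width and 2 * (width - k) <= t <= 2 * (width - 1):
        orients.append(True)  # transpose
    if not orients:
        return None
    for _ in range(tries):
        transpose = bool(orients[int(rng.integers(len(orients)))])
        W, H = (height, width) if transpose else (width, height)
        seq = _snake_sequence(W, H)
        n = len(seq)
        d = 2 * (H - 1) - t  # turns to remove
        n_cuts = k - 1
        # split the removal budget into 2s and 1s
        a = int(rng.integers(max(0, d - n_cuts), d // 2 + 1))  # cuts removing 2
        b = d - 2 * a  # cuts removing 1
        if a + b > n_cuts or b < 0:
            continue
        transitions = rng.permutation(H - 1)
        sites = [int((r + 1) * W - 1) for r in transitions[:a]]
        sites += [int((r + 1) * W - 2) for r in transitions[a : a + b]]
        # zero-removal cuts sit strictly inside an unused row
        free_rows = rng.permutation(H)
        needed = n_cuts - a - b
        for r in free_rows:
            if needed == 0:
                break
            lo, hi = r * W + 1, (r + 1) * W - 3
            if hi < lo:
                continue
            cand = int(rng.integers(lo, hi + 1))
            if all(abs(cand - s) >= 3 for s in sites):
                sites.append(cand)
                needed -= 1
        if needed > 0:
            continue
        sites.sort()
        if sites[0] < 2 or sites[-1] > n - 4:
            continue
        if any(y - x < 3 for x, y in zip(sites, sites[1:])):
            continue
        pieces, prev = [], 0
        for s in sites:
            pieces.append(seq[prev : s + 1])
            prev = s + 1
        pieces.append(seq[prev:])
        if sum(count_turns([Cell(*c) for c in p]) for p in pieces) != t:
            continue
        if transpose:
            pieces = [[(r, c) for c, r in p] for p in pieces]
        if rng.random() < 0.5:
            pieces = [[(width - 1 - c, r) for c, r in p] for p in pieces]
        if rng.random() < 0.5:
            pieces = [[(c, height - 1 - r) for c, r in p] for p in pieces]
        if rng.random() < 0.5:
            pieces = [p[::-1] for p in pieces]
        return [[Cell(c, r) for c, r in p] for p in pieces]
    return None


# ---------------------------------------------------------------------------
# public generator
# ---------------------------------------------------------------------------

def _paths_to_puzzle(board: Board, cover: list[list[Cell]], rng: np.random.Generator) -> Puzzle:
    order = rng.permutation(len(cover))
    pairs, paths = [], []
    for i, pi in enumerate(order):
        label = _DOT_ALPHABET[i]
        cells = cover[int(pi)]
        pairs.append(DotPair(label, cells[0], cells[-1]))
        paths.append(GridPath(label, cells))
    return Puzzle(board, pairs, paths)


def generate_puzzle(level: DifficultyLevel, config: GenerationConfig | None = None) -> Puzzle:
    """Generate a random puzzle whose reference solution matches ``level``.

    Deterministic given ``config.seed``. Raises :class:`GenerationError`
    naming the level when the attempt budget is exhausted, which signals
    infeasible (see :func:`feasible_turns`) or unlucky parameters.
    """
    config = config or GenerationConfig()
    rng = np.random.default_rng(config.seed)
    w, h, k, t = level.as_tuple()
    board = Board(w, h)
    m = max(w, h)

    snake_possible = any(lo <= t <= hi for lo, hi in _snake_intervals(w, h, k))
    if snake_possible:
        # growth is the diversity route; its hit rate collapses on large
        # boards, where the snake cut takes over after a short budget
        cells = w * h
        growth_budget = 250 if cells <= 20 else 100 if cells <= 25 else 40 if cells <= 30 else 15
        growth_budget = min(config.max_attempts, growth_budget)
    else:
        growth_budget = config.max_attempts
    # low targets need a strong straight-continuation bias
    biases = [10.0, 30.0, 100.0] if t <= m else [1.0, 3.0, 10.0, 30.0]

    cover = None
    for attempt in range(growth_budget):
        cand = _grow_cover(w, h, k, rng, biases[attempt % len(biases)])
        if cand is not None and sum(count_turns(p) for p in cand) == t:
            cover = cand
            break
    if cover is None and snake_possible:
        cover = _cut_snake(w, h, k, t, rng)
    if cover is None:
        raise GenerationError(
            f"could not generate a puzzle for level {level.as_tuple()} "
            f"within {config.max_attempts} attempts"
        )
    puzzle = _paths_to_puzzle(board, cover, rng)
    if config.solver_check:
        found = solve_brute_force(puzzle)
        want = {p.label: p.cells for p in puzzle.solution or []}
        ok = any(
            {q.label: q.cells for q in sol} == want
            or {q.label: q.cells[::-1] for q in sol} == want
            for sol in found
        )
        if not ok:
            raise GenerationError(f"solver check failed for level {level.as_tuple()}")
    return puzzle


# ---------------------------------------------------------------------------
# the graded level space
# ---------------------------------------------------------------------------

def enumerate_level_space() -> list[DifficultyLevel]:
    """All (w, h, p, t) with w, h in [4, 8] and p, t in [4, max(w, h)]."""
    out = []
    for w, h in itertools.product(range(MIN_DIM, MAX_DIM + 1), repeat=2):
        m = max(w, h)
        for p in range(MIN_PATHS, m + 1):
            for t in range(MIN_TURNS, m + 1):
                out.append(DifficultyLevel(w, h, p, t))
    return sorted(out)


def board_sizes(space: list[DifficultyLevel] | None = None) -> set[tuple[int, int]]:
    space = space if space is not None else enumerate_level_space()
    return {(lv.width, lv.height) for lv in space}


def _draw_turns(width: int, height: int, n_paths: int, rng: np.random.Generator) -> int:
    """Uniform draw over the feasible turn totals for this board/path count."""
    choices = sorted(feasible_turns(width, height, n_paths))
    if not choices:
        raise GenerationError(f"no feasible turn total for ({width},{height},{n_paths})")
    return int(choices[int(rng.integers(len(choices)))])


def build_parallel_sets(
    space: list[DifficultyLevel] | None = None, turn_seed: int | None = None
) -> tuple[LevelSet, LevelSet]:
    """Construct the two parallel sets A and B over (w, h, p) triples.

    Square boards appear identically in both sets. For each unordered
    non-square board pair and each path count, the orientation
    alternates between the sets, starting with (larger, smaller) in set
    A at the lowest path count. One turn total is drawn per retained
    level and set.
    """
    rng = np.random.default_rng(turn_seed)
    dims = range(MIN_DIM, MAX_DIM + 1)
    triples_a: list[tuple[int, int, int]] = []
    triples_b: list[tuple[int, int, int]] = []
    for d in dims:
        for p in range(MIN_PATHS, d + 1):
            triples_a.append((d, d, p))
            triples_b.append((d, d, p))
    for lo, hi in itertools.combinations(dims, 2):
        for j, p in enumerate(range(MIN_PATHS, hi + 1)):
            if j % 2 == 0:
                triples_a.append((hi, lo, p))
                triples_b.append((lo, hi, p))
            else:
                triples_a.append((lo, hi, p))
                triples_b.append((hi, lo, p))
    levels_a = [
        DifficultyLevel(w, h, p, _draw_turns(w, h, p, rng)) for w, h, p in sorted(triples_a)
    ]
    levels_b = [
        DifficultyLevel(w, h, p, _draw_turns(w, h, p, rng)) for w, h, p in sorted(triples_b)
    ]
    return (
        LevelSet("A", "full", levels_a, order_seed=turn_seed),
        LevelSet("B", "full", levels_b, order_seed=turn_seed),
    )


_VERSION_DIMS = {
    "short": frozenset({4, 5, 6}),
    "medium": frozenset({4, 5, 6, 7}),
    "long": frozenset({4, 5, 6, 7, 8}),
}


def build_version(
    full_set: LevelSet, version: str, order_seed: int | None = None
) -> LevelSet:
    """Restrict a full set to a version's board dimensions and shuffle.

    ``short`` keeps boards with dimensions in {4, 5, 6}, ``medium`` in
    {4..7}, ``long`` in {4..8}; presentation order is then shuffled
    reproducibly with ``order_seed``.
    """
    if version not in _VERSION_DIMS:
        raise ValueError(f"unknown version {version!r}; expected one of {sorted(_VERSION_DIMS)}")
    dims = _VERSION_DIMS[version]
    levels = [lv for lv in full_set.levels if lv.width in dims and lv.height in dims]
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(levels))
    return LevelSet(
        full_set.set_id, version, [levels[int(i)] for i in order], order_seed=order_seed
    )


def build_practice_block() -> LevelSet:
    """The fixed three-puzzle practice block."""
    levels = [
        DifficultyLevel(4, 4, 4, 0),
        DifficultyLevel(4, 4, 4, 4),
        DifficultyLevel(5, 5, 5, 5),
    ]
    return LevelSet("practice", "practice", levels)


def assign_version(moca: float, tmt_b: float) -> str:
    """Map screening scores to a set version (short precedence first)."""
    if not 0 <= moca <= 30:
        raise ValueError(f"MoCA score must be in [0, 30], got {moca}")
    if tmt_b <= 0:
        raise ValueError(f"TMT-B time must be positive, got {tmt_b}")
    if moca < 23 or tmt_b > 120:
        return "short"
    if moca > 28 and tmt_b < 120:
        return "long"
    return "medium"


def rank_difficulty(levels: list[DifficultyLevel]) -> list[tuple[DifficultyLevel, int]]:
    """Order levels by board area then path count; 1-based rank.

    Ties broken by turn count, then lexicographically by (width,
    height). Equal-key levels still receive distinct consecutive ranks
    (stable order).
    """
    ordered = sorted(levels, key=lambda lv: (lv.area, lv.n_paths, lv.n_turns, lv.width, lv.height))
    return [(lv, i + 1) for i, lv in enumerate(ordered)]
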
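"""Core data model for grid link puzzles.

A puzzle lives on a rectangular board of cells. Labelled dots come in
pairs; a solution connects every pair with an orthogonal, non-crossing
path such that the paths jointly cover every cell of the board exactly
once. This module holds the domain types, the rule validator, path
geometry helpers (turn counting, city-block distance), an exhaustive
backtracking solver used as a testing oracle, and a plain-text grid
format.

Coordinates are 0-based ``(col, row)`` with the origin at the top-left.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence


class PuzzleError(ValueError):
    """Raised for malformed puzzles, paths, or grid text."""


@dataclass(frozen=True, order=True)
class Cell:
    """A board cell addressed by 0-based column and row."""

    col: int
    row: int

    def neighbors(self) -> tuple["Cell", "Cell", "Cell", "Cell"]:
        c, r = self.col, self.row
        return (Cell(c + 1, r), Cell(c - 1, r), Cell(c, r + 1), Cell(c, r - 1))


@dataclass(frozen=True)
class Board:
    """Rectangular playing area, ``width`` x ``height`` cells."""

    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise PuzzleError(f"board must be at least 2x2, got {self.width}x{self.height}")

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    def contains(self, cell: Cell) -> bool:
        return 0 <= cell.col < self.width and 0 <= cell.row < self.height

    def cells(self) -> Iterator[Cell]:
        for row in range(self.height):
            for col in range(self.width):
                yield Cell(col, row)


@dataclass(frozen=True)
class DotPair:
    """Two identical dots that must be joined by a single path."""

    label: str
    a: Cell
    b: Cell

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise PuzzleError(f"pair {self.label!r}: dots must occupy distinct cells")


@dataclass(frozen=True)
class GridPath:
    """An ordered sequence of cells joined by unit horizontal/vertical steps."""

    label: str
    cells: tuple[Cell, ...]

    def __init__(self, label: str, cells: Iterable[Cell]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "cells", tuple(cells))

    def __len__(self) -> int:
        return len(self.cells)

    def reversed(self) -> "GridPath":
        return GridPath(self.label, self.cells[::-1])


@dataclass
class Puzzle:
    """A board, its dot pairs, and (optionally) a reference solution."""

    board: Board
    pairs: list[DotPair]
    solution: list[GridPath] | None = None

    def __post_init__(self) -> None:
        labels = [p.label for p in self.pairs]
        if len(set(labels)) != len(labels):
            raise PuzzleError("pair labels must be unique")
        dots = [c for p in self.pairs for c in (p.a, p.b)]
        if len(set(dots)) != len(dots):
            raise PuzzleError("dots must occupy distinct cells")
        for p in self.pairs:
            for c in (p.a, p.b):
                if not self.board.contains(c):
                    raise PuzzleError(f"dot {p.label!r} at {c} is off the board")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_by_label(self, label: str) -> DotPair:
        for p in self.pairs:
            if p.label == label:
                return p
        raise KeyError(label)

    def dot_cells(self) -> dict[Cell, str]:
        return {c: p.label for p in self.pairs for c in (p.a, p.b)}


@dataclass(frozen=True)
class Violation:
    """One named rule violation found by :func:`validate_solution`."""

    rule: str
    detail: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def rules(self) -> set[str]:
        return {v.rule for v in self.violations}


def step(a: Cell, b: Cell) -> tuple[int, int]:
    return (b.col - a.col, b.row - a.row)


def count_turns(path: GridPath | Sequence[Cell]) -> int:
    """Number of interior cells where the step direction changes.

    A turn is a switch between horizontal and vertical movement while
    walking the cell sequence; straight runs contribute nothing.
    """
    cells = path.cells if isinstance(path, GridPath) else tuple(path)
    if len(cells) < 2:
        raise PuzzleError("need at least 2 cells to define a direction")
    turns = 0
    for i in range(1, len(cells) - 1):
        if step(cells[i - 1], cells[i]) != step(cells[i], cells[i + 1]):
            turns += 1
    return turns


def city_block_distance(pair: DotPair) -> int:
    """Manhattan distance |dcol| + |drow| between the two dots of a pair."""
    return abs(pair.a.col - pair.b.col) + abs(pair.a.row - pair.b.row)


def mean_city_block_distance(puzzle: Puzzle) -> float:
    """Average city-block distance over all pairs of the puzzle."""
    if not puzzle.pairs:
        raise PuzzleError("puzzle has no pairs")
    return sum(city_block_distance(p) for p in puzzle.pairs) / len(puzzle.pairs)


def validate_solution(puzzle: Puzzle, paths: Sequence[GridPath]) -> ValidationReport:
    """Check a set of paths against the four puzzle rules.

    Every violation is reported (the report never raises): unknown or
    duplicated labels, non-orthogonal steps, revisited cells, paths
    shorter than three cells, endpoint mismatches against the pair's
    dots, two paths sharing a cell or a path crossing a foreign dot
    ("crossing"), and board cells left uncovered.
    """
    report = ValidationReport()
    add = report.violations.append
    known = {p.label for p in puzzle.pairs}
    dots = puzzle.dot_cells()

    seen_labels: set[str] = set()
    occupied: dict[Cell, str] = {}
    for path in paths:
        if path.label not in known:
            add(Violation("unknown-label", f"path label {path.label!r} has no dot pair"))
            continue
        if path.label in seen_labels:
            add(Violation("duplicate-path", f"label {path.label!r} drawn more than once"))
            continue
        seen_labels.add(path.label)
        cells = path.cells
        if len(cells) < 3:
            add(Violation("path-too-short", f"path {path.label!r} has {len(cells)} cells (< 3)"))
        if len(set(cells)) != len(cells):
            add(Violation("revisited-cell", f"path {path.label!r} visits a cell twice"))
        for a, b in zip(cells, cells[1:]):
            dc, dr = step(a, b)
            if abs(dc) + abs(dr) != 1:
                add(Violation("non-orthogonal-step", f"path {path.label!r}: {a} -> {b}"))
        pair = puzzle.pair_by_label(path.label)
        if cells and {cells[0], cells[-1]} != {pair.a, pair.b}:
            add(Violation("endpoint-mismatch", f"path {path.label!r} endpoints are not its dots"))
        for c in cells:
            if not puzzle.board.contains(c):
                add(Violation("uncovered-cell", f"path {path.label!r} leaves the board at {c}"))
                continue
            other = occupied.get(c)
            if other is not None and not (other == path.label):
                add(Violation("crossing", f"paths {other!r} and {path.label!r} share {c}"))
            occupied[c] = path.label
            dot_label = dots.get(c)
            if dot_label is not None and dot_label != path.label:
                add(Violation("crossing", f"path {path.label!r} crosses dot {dot_label!r} at {c}"))

    for label in known - seen_labels:
        add(Violation("missing-path", f"pair {label!r} is not connected"))
    for cell in puzzle.board.cells():
        if cell not in occupied:
            add(Violation("uncovered-cell", f"cell {cell} is not covered by any path"))
    return report


# ---------------------------------------------------------------------------
# brute-force solver (testing oracle)
# ---------------------------------------------------------------------------

def solve_brute_force(puzzle: Puzzle, max_board_cells: int = 25) -> list[list[GridPath]]:
    """Enumerate every full-cover solution by exhaustive backtracking.

    Exponential; refuses boards larger than ``max_board_cells`` cells.
    Paths are reported oriented from each pair's ``a`` dot, so the
    result is canonical and order-stable (pairs in puzzle order).
    """
    board = puzzle.board
    if board.n_cells > max_board_cells:
        raise PuzzleError(
            f"board has {board.n_cells} cells, above the solver limit of {max_board_cells}"
        )
    pairs = list(puzzle.pairs)
    solutions: list[list[GridPath]] = []
    # all dots stay blocked; a path may only terminate on its own pair's dots
    used: set[Cell] = {c for p in pairs for c in (p.a, p.b)}

    def extend_guarded(idx: int, acc: list[GridPath]) -> None:
        if idx == len(pairs):
            if len(used) == board.n_cells:
                solutions.append(list(acc))
            return
        pair = pairs[idx]
        target = pair.b

        def walk(cell: Cell, trail: list[Cell]) -> None:
            for nxt in cell.neighbors():
                if not board.contains(nxt):
                    continue
                if nxt == target:
                    if len(trail) + 1 >= 3:
                        acc.append(GridPath(pair.label, trail + [nxt]))
                        extend_guarded(idx + 1, acc)
                        acc.pop()
                    continue
                if nxt in used:
                    continue
                used.add(nxt)
                trail.append(nxt)
                walk(nxt, trail)
                trail.pop()
                used.discard(nxt)

        walk(pair.a, [pair.a])

    extend_guarded(0, [])
    return solutions


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------

_DOT_ALPHABET = string.ascii_uppercase


def write_grid_text(puzzle: Puzzle, stream: IO[str] | None = None) -> str:
    """Render the puzzle as newline-separated rows of '.' and dot letters."""
    grid = [["." for _ in range(puzzle.board.width)] for _ in range(puzzle.board.height)]
    for pair in puzzle.pairs:
        for cell in (pair.a, pair.b):
            grid[cell.row][cell.col] = pair.label
    text = "\n".join("".join(row) for row in grid) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def read_grid_text(source: IO[str] | str) -> Puzzle:
    """Parse a '.'/letter grid back into a :class:`Puzzle` (no solution).

    Raises :class:`PuzzleError` naming line and column for ragged rows,
    unknown characters, or a letter not appearing exactly twice.
    """
    text = source if isinstance(source, str) else source.read()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise PuzzleError("empty grid text")
    width = len(lines[0])
    positions: dict[str, list[Cell]] = {}
    for r, line in enumerate(lines):
        if len(line) != width:
            raise PuzzleError(f"line {r + 1}: ragged row (expected width {width}, got {len(line)})")
        for c, ch in enumerate(line):
            if ch == ".":
                continue
            if ch not in _DOT_ALPHABET:
                raise PuzzleError(f"line {r + 1}, column {c + 1}: unknown character {ch!r}")
            positions.setdefault(ch, []).append(Cell(c, r))
    pairs = []
    for label in sorted(positions):
        cells = positions[label]
        if len(cells) != 2:
            raise PuzzleError(f"letter {label!r} appears {len(cells)} time(s), expected 2")
        pairs.append(DotPair(label, cells[0], cells[1]))
    return Puzzle(Board(width, len(lines)), pairs)


def to_record(puzzle: Puzzle) -> dict:
    """Structured, JSON-serialisable record including the solution."""
    rec: dict = {
        "width": puzzle.board.width,
        "height": puzzle.board.height,
        "pairs": [
            {"label": p.label, "a": [p.a.col, p.a.row], "b": [p.b.col, p.b.row]}
            for p in puzzle.pairs
        ],
    }
    if puzzle.solution is not None:
        rec["solution"] = [
            {"label": path.label, "cells": [[c.col, c.row] for c in path.cells]}
            for path in puzzle.solution
        ]
    return rec


def from_record(rec: dict) -> Puzzle:
    board = Board(rec["width"], rec["height"])
    pairs = [
        DotPair(p["label"], Cell(*p["a"]), Cell(*p["b"])) for p in rec["pairs"]
    ]
    solution = None
    if "solution" in rec:
        solution = [
            GridPath(s["label"], [Cell(*c) for c in s["cells"]]) for s in rec["solution"]
        ]
    return Puzzle(board, pairs, solution)


def write_record(puzzle: Puzzle, stream: IO[str]) -> None:
    json.dump(to_record(puzzle), stream, indent=1)
    stream.write("\n")


def read_record(stream: IO[str]) -> Puzzle:
    return from_record(json.load(stream))
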
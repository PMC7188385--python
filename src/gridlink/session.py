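"""Per-level session files: touch-event streams and board snapshots.

Each played level produces two plain-text files: a touch log (one
time-stamped event per line) and a snapshot log recording the board
cell states at every change. This module reads and writes both formats,
maps pixel coordinates to board cells, and segments the raw event
stream into drag moves (down ... up spans).

Timestamps are integer milliseconds; durations are reported in seconds.
Pixel origin is top-left with y increasing downward; cells are
half-open: ``[origin + i * size, origin + (i + 1) * size)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO

from .puzzle import Board, Cell

EVENT_KINDS = ("down", "move", "up", "hint", "solved")

TOUCH_HEADER = "t_ms,x_px,y_px,kind"


class SessionError(ValueError):
    """Malformed session file or event stream."""


@dataclass(frozen=True)
class BoardGeometry:
    """Placement of the board on the touch screen, in pixels."""

    origin_x: float
    origin_y: float
    cell_size: float
    screen_width: float
    screen_height: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise SessionError("cell_size must be positive")

    def fits(self, board: Board) -> bool:
        return (
            self.origin_x >= 0
            and self.origin_y >= 0
            and self.origin_x + board.width * self.cell_size <= self.screen_width
            and self.origin_y + board.height * self.cell_size <= self.screen_height
        )

    def cell_center(self, cell: Cell) -> tuple[float, float]:
        return (
            self.origin_x + (cell.col + 0.5) * self.cell_size,
            self.origin_y + (cell.row + 0.5) * self.cell_size,
        )

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "cell_size": self.cell_size,
            "screen_width": self.screen_width,
            "screen_height": self.screen_height,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoardGeometry":
        return cls(**{k: d[k] for k in (
            "origin_x", "origin_y", "cell_size", "screen_width", "screen_height")})


@dataclass(frozen=True)
class TouchEvent:
    t: int  # milliseconds
    x: float
    y: float
    kind: str

    def __post_init__(self) -> None:
        if self.t < 0:
            raise SessionError(f"negative timestamp {self.t}")
        if self.kind not in EVENT_KINDS:
            raise SessionError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class Move:
    """One drag: events from a touch down to the matching release."""

    events: tuple[TouchEvent, ...]

    def __post_init__(self) -> None:
        if not self.events or self.events[0].kind != "down" or self.events[-1].kind != "up":
            raise SessionError("a move must start with 'down' and end with 'up'")
        ts = [e.t for e in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise SessionError("move timestamps must be non-decreasing")

    @property
    def t_down(self) -> int:
        return self.events[0].t

    @property
    def t_up(self) -> int:
        return self.events[-1].t

    @property
    def duration(self) -> float:
        """Seconds between touch down and release."""
        return (self.t_up - self.t_down) / 1000.0


@dataclass(frozen=True)
class BoardSnapshot:
    """Cell states at time ``t``: '0' for empty, else a path label."""

    t: int
    cells: tuple[tuple[str, ...], ...]  # [row][col]

    @property
    def height(self) -> int:
        return len(self.cells)

    @property
    def width(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def label_cells(self) -> dict[str, frozenset[Cell]]:
        """Cells occupied per label (empty cells skipped)."""
        out: dict[str, set[Cell]] = {}
        for r, row in enumerate(self.cells):
            for c, state in enumerate(row):
                if state != "0":
                    out.setdefault(state, set()).add(Cell(c, r))
        return {k: frozenset(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# touch log I/O
# ---------------------------------------------------------------------------

def write_touch_log(events: list[TouchEvent], stream: IO[str] | None = None) -> str:
    lines = [TOUCH_HEADER]
    lines += [f"{e.t},{e.x!r},{e.y!r},{e.kind}" for e in events]
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def read_touch_log(source: IO[str] | str) -> list[TouchEvent]:
    """Parse a delimited touch log; events returned sorted by time.

    Non-monotone timestamps trigger a warning and a stable sort; any
    malformed line raises :class:`SessionError` with its line number.
    """
    text = source if isinstance(source, str) else source.read()
    lines = text.splitlines()
    if not lines or lines[0].strip() != TOUCH_HEADER:
        raise SessionError(f"line 1: expected header {TOUCH_HEADER!r}")
    events: list[TouchEvent] = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise SessionError(f"line {i}: expected 4 comma-separated fields, got {len(parts)}")
        try:
            ev = TouchEvent(int(parts[0]), float(parts[1]), float(parts[2]), parts[3].strip())
        except (ValueError, SessionError) as exc:
            raise SessionError(f"line {i}: {exc}") from exc
        events.append(ev)
    if any(b.t < a.t for a, b in zip(events, events[1:])):
        warnings.warn("touch log timestamps are not monotone; applying a stable sort")
        events.sort(key=lambda e: e.t)
    return events


# ---------------------------------------------------------------------------
# move segmentation
# ---------------------------------------------------------------------------

def segment_moves(events: list[TouchEvent]) -> list[Move]:
    """Split a time-sorted event stream into down...up drag moves.

    'move' samples outside any down/up span are treated as sensor noise
    and discarded with a warning; an unmatched trailing 'down' drops the
    unfinished drag with a warning; an 'up' without a preceding 'down'
    is an error. 'hint' and 'solved' events never join a move.
    """
    moves: list[Move] = []
    current: list[TouchEvent] | None = None
    stray = 0
    for ev in events:
        if ev.kind == "down":
            if current is not None:
                raise SessionError(f"nested 'down' at t={ev.t} before previous release")
            current = [ev]
        elif ev.kind == "move":
            if current is None:
                stray += 1
            else:
                current.append(ev)
        elif ev.kind == "up":
            if current is None:
                raise SessionError(f"'up' at t={ev.t} without a matching 'down'")
            current.append(ev)
            moves.append(Move(tuple(current)))
            current = None
        # hint/solved: never inside a move by construction of the formats
    if stray:
        warnings.warn(f"discarded {stray} stray 'move' event(s) outside any drag")
    if current is not None:
        warnings.warn(f"dropping unfinished drag starting at t={current[0].t}")
    return moves


def map_touch_to_cell(x: float, y: float, geometry: BoardGeometry, board: Board) -> Cell | None:
    """Pixel point -> board cell, or None when outside the board rectangle."""
    col = int((x - geometry.origin_x) // geometry.cell_size)
    row = int((y - geometry.origin_y) // geometry.cell_size)
    if x < geometry.origin_x or y < geometry.origin_y:
        return None
    if col >= board.width or row >= board.height:
        return None
    return Cell(col, row)


# ---------------------------------------------------------------------------
# snapshot I/O
# ---------------------------------------------------------------------------

def write_snapshots(snapshots: list[BoardSnapshot], stream: IO[str] | None = None) -> str:
    blocks = []
    for snap in snapshots:
        rows = [" ".join(row) for row in snap.cells]
        blocks.append("\n".join([f"t {snap.t}"] + rows))
    text = "\n\n".join(blocks) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def read_snapshots(source: IO[str] | str, board: Board | None = None) -> list[BoardSnapshot]:
    """Parse snapshot records; checked against ``board`` dims if given."""
    text = source if isinstance(source, str) else source.read()
    snapshots: list[BoardSnapshot] = []
    for block in text.split("\n\n"):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if not lines:
            continue
        if not lines[0].startswith("t "):
            raise SessionError(f"snapshot block must start with 't <ms>': {lines[0]!r}")
        t = int(lines[0][2:])
        cells = tuple(tuple(ln.split()) for ln in lines[1:])
        if board is not None:
            if len(cells) != board.height or any(len(r) != board.width for r in cells):
                raise SessionError(
                    f"snapshot at t={t}: dimensions do not match the "
                    f"{board.width}x{board.height} board"
                )
        snapshots.append(BoardSnapshot(t, cells))
    snapshots.sort(key=lambda s: s.t)
    return snapshots
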
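"""Synthetic players: seeded touch logs and snapshots for any puzzle.

The simulator drags each solution path along the board cell centers at
a configurable speed, with planning pauses before each path, orthogonal
touch jitter, occasional along-axis back-and-forth excursions (each one
produces exactly two direction reversals), and optional error moves (a
wrong partial path drawn first, then replaced by the correct one).
Every stochastic choice derives from one seeded generator, so identical
seeds give identical logs, and a ground-truth record accompanies each
level for oracle-style testing.

Group archetypes (YA, OA, OOA, PD, HD) bundle illustrative parameter
presets whose ordering mirrors the contrasts seen between young adults,
healthy elderly and movement-disorder patients; they are tuning points,
not fits.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .levels import DifficultyLevel, GenerationConfig, generate_puzzle, rank_difficulty
from .puzzle import Puzzle, to_record
from .session import (
    BoardGeometry,
    BoardSnapshot,
    TouchEvent,
    write_snapshots,
    write_touch_log,
)


@dataclass(frozen=True)
class PlayerProfile:
    drag_speed: float  # px/s along the path
    speed_cv: float = 0.0  # per-move multiplicative speed variation
    plan_pause_mean: float = 0.0  # s per path, log-normal
    plan_pause_sd: float = 0.0
    jitter_sd: float = 0.0  # px orthogonal noise per sample
    reversal_rate: float = 0.0  # expected axis reversals per sub-path
    error_prob: float = 0.0  # chance a pair is first drawn wrongly
    sample_rate: float = 60.0  # Hz

    def __post_init__(self) -> None:
        if self.drag_speed <= 0 or self.sample_rate <= 0:
            raise ValueError("drag_speed and sample_rate must be positive")
        for name in ("speed_cv", "plan_pause_mean", "plan_pause_sd", "jitter_sd",
                     "reversal_rate", "error_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroupArchetype:
    name: str
    profile: PlayerProfile
    age_range: tuple[int, int]
    moca: tuple[float, float]  # mean, sd
    tmt_a: tuple[float, float]
    tmt_b: tuple[float, float]
    smt: tuple[float, float]


#: Illustrative presets: speeds ordered YA > OA ~ PD > OOA ~ HD, error
#: rate maximal for HD. Covariate ranges follow the study populations
#: these archetypes emulate.
ARCHETYPES: dict[str, GroupArchetype] = {
    "YA": GroupArchetype(
        "YA",
        PlayerProfile(2658.0, 0.10, 0.85, 0.45, 1.5, 0.3, 0.04),
        (18, 31), (28.6, 1.5), (26.4, 9.4), (50.8, 19.3), (14.4, 3.1),
    ),
    "OA": GroupArchetype(
        "OA",
        PlayerProfile(1701.0, 0.12, 2.9, 1.6, 2.0, 0.6, 0.06),
        (64, 79), (27.2, 2.9), (36.2, 7.7), (107.7, 43.2), (32.2, 10.1),
    ),
    "OOA": GroupArchetype(
        "OOA",
        PlayerProfile(1151.0, 0.15, 5.0, 2.6, 3.0, 1.0, 0.10),
        (86, 98), (23.4, 4.2), (66.9, 33.1), (145.5, 18.7), (43.4, 20.3),
    ),
    "PD": GroupArchetype(
        "PD",
        PlayerProfile(1665.0, 0.13, 2.7, 1.5, 2.5, 0.9, 0.07),
        (59, 76), (26.3, 3.4), (45.3, 11.5), (122.5, 68.7), (24.8, 11.1),
    ),
    "HD": GroupArchetype(
        "HD",
        PlayerProfile(1065.0, 0.18, 7.0, 3.6, 4.0, 2.5, 0.30),
        (35, 66), (18.3, 6.2), (98.2, 80.0), (227.0, 17.9), (50.4, 35.2),
    ),
}


def default_geometry(puzzle: Puzzle, cell_size: float = 100.0) -> BoardGeometry:
    """A geometry that centers the board on a nominal tablet screen."""
    w = puzzle.board.width * cell_size
    h = puzzle.board.height * cell_size
    screen_w, screen_h = max(w + 100, 1366), max(h + 100, 1024)
    return BoardGeometry(
        origin_x=(screen_w - w) / 2,
        origin_y=(screen_h - h) / 2,
        cell_size=cell_size,
        screen_width=screen_w,
        screen_height=screen_h,
    )


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if mean <= 0:
        return 0.0
    if sd <= 0:
        return mean
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _drag_samples(
    corners: list[tuple[float, float]],
    speed: float,
    profile: PlayerProfile,
    rng: np.random.Generator,
) -> tuple[list[tuple[float, float, float]], int]:
    """Sample one drag along a corner polyline.

    Samples run at ``sample_rate`` with an extra exact sample at every
    corner, so turn geometry and per-segment speed are preserved.
    Returns (samples [(t_s, x, y)], injected_reversals).
    """
    dt = 1.0 / profile.sample_rate
    samples: list[tuple[float, float, float]] = [(0.0, corners[0][0], corners[0][1])]
    t = 0.0
    reversals = 0
    for (x0, y0), (x1, y1) in zip(corners, corners[1:]):
        seg_len = math.hypot(x1 - x0, y1 - y0)
        if seg_len == 0:
            continue
        ux, uy = (x1 - x0) / seg_len, (y1 - y0) / seg_len
        seg_dur = seg_len / speed
        # plain samples strictly inside the segment
        offsets = [dt * i for i in range(1, int(seg_dur / dt) + 1) if dt * i < seg_dur]
        # back-and-forth excursions: each adds two axis reversals
        n_exc = rng.poisson(profile.reversal_rate / 2.0) if profile.reversal_rate > 0 else 0
        exc_at: list[tuple[float, float]] = []
        for _ in range(n_exc):
            u = float(rng.uniform(0.25, 0.85)) * seg_len
            d = min(0.2 * u, float(rng.uniform(0.5, 1.5)) * speed * dt)
            if d >= 1.0:
                exc_at.append((u, d))
        exc_at.sort()
        shift = 0.0
        events: list[tuple[float, float]] = [(off, off * speed) for off in offsets]
        pos_events: list[tuple[float, float]] = []
        ei = 0
        for off, s in events:
            while ei < len(exc_at) and exc_at[ei][0] <= s:
                u, d = exc_at[ei]
                t_u = u / speed + shift
                pos_events.append((t_u, u))
                pos_events.append((t_u + d / speed, u - d))
                pos_events.append((t_u + 2 * d / speed, u))
                shift += 2 * d / speed
                reversals += 2
                ei += 1
            pos_events.append((off + shift, s))
        while ei < len(exc_at):
            u, d = exc_at[ei]
            t_u = u / speed + shift
            pos_events.append((t_u, u))
            pos_events.append((t_u + d / speed, u - d))
            pos_events.append((t_u + 2 * d / speed, u))
            shift += 2 * d / speed
            reversals += 2
            ei += 1
        for t_off, s in pos_events:
            px, py = x0 + ux * s, y0 + uy * s
            if profile.jitter_sd > 0:
                j = float(rng.normal(0.0, profile.jitter_sd))
                px, py = px - uy * j, py + ux * j
            samples.append((t + t_off, px, py))
        t += seg_dur + shift
        samples.append((t, x1, y1))  # exact corner / endpoint sample
    return samples, reversals


def simulate_level(
    puzzle: Puzzle,
    profile: PlayerProfile,
    geometry: BoardGeometry | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[TouchEvent], list[BoardSnapshot], dict]:
    """Play one puzzle; returns (touch events, snapshots, ground truth).

    Ground truth records the injected pauses, error moves and reversal
    counts plus the exact TST/MET/MPT implied by the emitted integer
    timestamps, for use as an independent oracle downstream.
    """
    if puzzle.solution is None:
        raise ValueError("simulate_level needs a puzzle with a reference solution")
    geometry = geometry or default_geometry(puzzle)
    if not geometry.fits(puzzle.board):
        raise ValueError("geometry too small for the board")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    events: list[TouchEvent] = []
    snapshots: list[BoardSnapshot] = []
    grid = [["0"] * puzzle.board.width for _ in range(puzzle.board.height)]
    for pair in puzzle.pairs:
        for cell in (pair.a, pair.b):
            grid[cell.row][cell.col] = pair.label

    def snap(t_ms: int) -> None:
        snapshots.append(BoardSnapshot(t_ms, tuple(tuple(r) for r in grid)))

    snap(0)
    t_cursor = 0.0  # seconds
    gt: dict = {
        "errors": 0,
        "reversals": 0,
        "pauses": [],
        "move_speeds": [],
        "n_moves": 0,
    }

    def play_drag(cells, label, clear_first: bool) -> None:
        nonlocal t_cursor
        speed = profile.drag_speed * max(
            0.05, 1.0 + float(rng.normal(0.0, profile.speed_cv)) if profile.speed_cv else 1.0
        )
        corners = [geometry.cell_center(c) for c in cells]
        samples, rev = _drag_samples(corners, speed, profile, rng)
        gt["reversals"] += rev
        gt["move_speeds"].append(speed)
        gt["n_moves"] += 1
        t0 = t_cursor
        down_ms = round(t0 * 1000)
        if clear_first:
            # touching the start dot resets the label's path
            for r in range(puzzle.board.height):
                for c in range(puzzle.board.width):
                    if grid[r][c] == label:
                        grid[r][c] = "0"
            pair = puzzle.pair_by_label(label)
            for cell in (pair.a, pair.b):
                grid[cell.row][cell.col] = label
            snap(down_ms)
        # cell boundaries along the polyline at the midpoints between centers
        cum = [0.0]
        for (x0, y0), (x1, y1) in zip(corners, corners[1:]):
            cum.append(cum[-1] + math.hypot(x1 - x0, y1 - y0))
        next_cell = 1
        covered = 0.0
        for i, (t_off, x, y) in enumerate(samples):
            kind = "down" if i == 0 else ("up" if i == len(samples) - 1 else "move")
            t_ms = round((t0 + t_off) * 1000)
            events.append(TouchEvent(t_ms, x, y, kind))
            # progress along the unjittered polyline (corner samples are exact)
            covered = max(covered, min(cum[-1], speed * _progress(t_off, samples, i)))
            while next_cell < len(cells) and covered >= (cum[next_cell - 1] + cum[next_cell]) / 2:
                cell = cells[next_cell]
                if grid[cell.row][cell.col] != label:
                    grid[cell.row][cell.col] = label
                    snap(t_ms)
                next_cell += 1
        # ensure every cell of the drawn path is set by release
        changed = False
        for cell in cells:
            if grid[cell.row][cell.col] != label:
                grid[cell.row][cell.col] = label
                changed = True
        if changed:
            snap(events[-1].t)
        t_cursor = t0 + samples[-1][0]

    def _progress(t_off: float, samples, i) -> float:
        # excursions pause forward progress; approximate by elapsed time
        return t_off

    order = rng.permutation(len(puzzle.solution))
    pauses_in_tst = 0.0
    last_up_t = None
    for oi, pi in enumerate(order):
        path = puzzle.solution[int(pi)]
        cells = list(path.cells)
        if bool(rng.random() < 0.5):
            cells = cells[::-1]
        pause = _lognormal(rng, profile.plan_pause_mean, profile.plan_pause_sd)
        gt["pauses"].append(pause)
        if oi > 0:
            pauses_in_tst += pause
        t_cursor += pause
        if rng.random() < profile.error_prob:
            # wrong first attempt: a truncated path, later overwritten
            cut = int(rng.integers(2, len(cells) - 1)) if len(cells) > 3 else 2
            play_drag(cells[:cut], path.label, clear_first=False)
            gt["errors"] += 1
            gap = _lognormal(rng, max(profile.plan_pause_mean, 0.2),
                             max(profile.plan_pause_sd, 0.1))
            pauses_in_tst += gap
            t_cursor += gap
            play_drag(cells, path.label, clear_first=True)
        else:
            play_drag(cells, path.label, clear_first=False)
        last_up_t = events[-1].t

    events.append(TouchEvent(last_up_t, *geometry.cell_center(cells[-1]), "solved"))

    downs = [e.t for e in events if e.kind == "down"]
    ups = [e.t for e in events if e.kind == "up"]
    met_ms = sum(u - d for d, u in zip(downs, ups))
    gt["tst_expected"] = (last_up_t - downs[0]) / 1000.0
    gt["met_expected"] = met_ms / 1000.0
    gt["mpt_expected"] = gt["tst_expected"] - gt["met_expected"]
    gt["pauses_in_tst"] = pauses_in_tst
    gt["pause_total"] = float(sum(gt["pauses"]))
    return events, snapshots, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def sample_profile(archetype: GroupArchetype, rng: np.random.Generator,
                   spread: float = 0.12) -> PlayerProfile:
    """Draw an individual profile around a group archetype."""
    p = archetype.profile
    jig = lambda v: v * float(rng.lognormal(0.0, spread)) if v > 0 else 0.0
    return replace(
        p,
        drag_speed=jig(p.drag_speed),
        plan_pause_mean=jig(p.plan_pause_mean),
        jitter_sd=jig(p.jitter_sd),
        reversal_rate=jig(p.reversal_rate),
        error_prob=min(1.0, jig(p.error_prob)),
    )


def sample_covariates(archetype: GroupArchetype, rng: np.random.Generator) -> dict:
    lo, hi = archetype.age_range
    truncnorm = lambda m, s, a, b: float(np.clip(rng.normal(m, s), a, b))
    return {
        "age": int(rng.integers(lo, hi + 1)),
        "moca": round(truncnorm(*archetype.moca, 0, 30), 1),
        "tmt_a": round(truncnorm(*archetype.tmt_a, 5, 400), 1),
        "tmt_b": round(truncnorm(*archetype.tmt_b, 10, 400), 1),
        "smt": round(truncnorm(*archetype.smt, 3, 300), 1),
    }


def simulate_session(
    puzzles: list[Puzzle],
    profile: PlayerProfile,
    geometry: BoardGeometry | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[list[TouchEvent], list[BoardSnapshot], dict]]:
    """Play a list of puzzles in order with one profile (in memory)."""
    rng = rng or np.random.default_rng()
    return [simulate_level(pz, profile, geometry, rng) for pz in puzzles]


def simulate_cohort(
    levels: list[DifficultyLevel],
    archetypes: list[GroupArchetype],
    n_per_group: int | dict[str, int],
    seed: int,
    out_dir: str | Path,
    cell_size: float = 100.0,
    generation: GenerationConfig | None = None,
) -> Path:
    """Simulate a full cohort and write a session directory tree.

    Layout: ``<out>/covariates.csv``, ``<out>/manifest.json``, and per
    participant ``<out>/sessions/<pid>/<level_dir>/{touch.csv,
    snapshots.txt, puzzle.json, ground_truth.json}``. Byte-identical
    for identical seeds.
    """
    out = Path(out_dir)
    (out / "sessions").mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(seed)
    gen_cfg = generation or GenerationConfig(seed=seed)

    ranked = {lv: rank for lv, rank in rank_difficulty(levels)}
    puzzles: list[Puzzle] = []
    for i, lv in enumerate(levels):
        puzzles.append(generate_puzzle(lv, replace(gen_cfg, seed=(gen_cfg.seed or 0) + i)))

    manifest = {
        "cell_size": cell_size,
        "levels": [
            {
                "dir": _level_dirname(i, lv),
                "level": list(lv.as_tuple()),
                "rank": ranked[lv],
                "order": i,
            }
            for i, lv in enumerate(levels)
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")

    counts = (
        n_per_group if isinstance(n_per_group, dict)
        else {a.name: n_per_group for a in archetypes}
    )
    rows = []
    for arch in archetypes:
        for i in range(counts[arch.name]):
            pid = f"{arch.name}{i + 1:02d}"
            prng = np.random.default_rng(root_rng.integers(2**63))
            profile = sample_profile(arch, prng)
            cov = sample_covariates(arch, prng)
            rows.append({"participant": pid, "group": arch.name, **cov})
            pdir = out / "sessions" / pid
            pdir.mkdir(parents=True, exist_ok=True)
            for j, (lv, pz) in enumerate(zip(levels, puzzles)):
                geometry = default_geometry(pz, cell_size)
                events, snaps, gt = simulate_level(pz, profile, geometry, prng)
                ldir = pdir / _level_dirname(j, lv)
                ldir.mkdir(exist_ok=True)
                (ldir / "touch.csv").write_text(write_touch_log(events))
                (ldir / "snapshots.txt").write_text(write_snapshots(snaps))
                (ldir / "puzzle.json").write_text(
                    json.dumps(to_record(pz), indent=1) + "\n"
                )
                (ldir / "geometry.json").write_text(
                    json.dumps(geometry.to_dict(), indent=1) + "\n"
                )
                (ldir / "ground_truth.json").write_text(json.dumps(gt, indent=1) + "\n")
    with open(out / "covariates.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["participant", "group", "age", "moca", "tmt_a", "tmt_b", "smt"]
        )
        writer.writeheader()
        writer.writerows(rows)
    return out


def _level_dirname(index: int, lv: DifficultyLevel) -> str:
    w, h, p, t = lv.as_tuple()
    return f"{index:02d}_w{w}h{h}p{p}t{t}"
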
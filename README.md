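# gridlink

A toolkit for assessing cognitive and motor performance with grid
link puzzles (connect pairs of identical dots with non-crossing
orthogonal paths that jointly cover the whole board). It bundles:

* **`gridlink.puzzle`** — the puzzle data model, rule validation, path
  geometry (turn counts, city-block distance), an exhaustive
  backtracking solver used as a testing oracle, and plain-text formats.
* **`gridlink.levels`** — random full-cover puzzle generation for an
  exact `(width, height, paths, turns)` tuple, the graded 4..8
  difficulty space, parallel sets A/B, short/medium/long versions, the
  practice block, screening-based version assignment, and difficulty
  ranking.
* **`gridlink.session`** — the two per-level session files (touch-event
  stream, board-state snapshots), pixel-to-cell mapping, and
  segmentation of raw events into drag moves.
* **`gridlink.metrics`** — per-level performance measures: total
  solving time (TST), motor execution time (MET), mental planning time
  (MPT), false and excess moves, hints, mean drag velocity (MVE) and
  movement direction changes (MDC) over RDP-detected sub-paths, plus
  session-level aggregation (median/IQR/SD).
* **`gridlink.simulate`** — a seeded synthetic-player engine with
  controllable speed, planning pauses, jitter, axis reversals and error
  moves, group archetype presets (YA/OA/OOA/PD/HD), and full cohort
  simulation writing session directories plus a covariate table.
* **`gridlink.stats`** — tie-corrected Kruskal–Wallis with a mean-rank
  multiple-comparison post hoc, Spearman and age-controlled partial
  Spearman correlations, and the pooled difficulty-vs-solving-time
  correlation.

## CLI

```sh
# one puzzle for a difficulty tuple (grid text to stdout, record to JSON)
gridlink generate --width 5 --height 5 --paths 5 --turns 5 --seed 1 --out puzzle.json

# a graded level set (manifest + one puzzle record per level)
gridlink levels --version short --set A --seed 0 --out levels/

# a synthetic cohort over those levels
gridlink simulate --levels levels/ --group YA --group HD --n 5 --seed 7 --out cohort/

# per-level metric table for one participant's session directory
gridlink score --session cohort/sessions/YA01 --out metrics.csv

# group comparison / correlations / difficulty analysis on a pooled table
gridlink stats --metrics pooled.csv --analysis groups --out report.csv
```

`score` expects one directory per level containing `touch.csv`,
`snapshots.txt`, `puzzle.json` and `geometry.json` (exactly what
`simulate` writes). The `stats` command consumes a pooled CSV with
`participant`, `group`, `level_rank` and the metric columns
(`tst_s, met_s, mpt_s, false_moves, excess_moves, hints, mve_px_s, mdc`).

## Notes

* Generation is exact in `(paths, turns)`: a rejection-sampled random
  frontier growth supplies variety, and a snake-cut construction
  (boustrophedon cover cut at turn-removing sites) guarantees
  termination for every reachable turn total.
  `gridlink.levels.feasible_turns` reports, per board and path count,
  the turn totals the generator supports; a handful of extreme tuples
  (e.g. an 8×8 board with 4 paths and fewer than 8 turns) admit no
  known full cover and raise `GenerationError`.
* Simulator archetype parameters are illustrative presets ordered like
  the group contrasts they emulate, not fits to any dataset.
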
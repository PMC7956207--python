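"""Two-level game-interactive stimulation paradigm.

The 15 x 15 board is partitioned into 25 labelled 3 x 3 regions; a move is
selected in two sub-trials: first the region (25 flashing buttons), then the
position within it (digits 1-9 plus a regret button 'R').  The second-level
flashing sequence is dynamically shortened by dropping digits whose board
cells are already occupied, clamped to a minimum length so the target stays
rare enough for a reliable P300 (too-rapid repeats of the same stimulus cause
repetition blindness).
"""

from __future__ import annotations

import dataclasses
import json
import string
from typing import Iterator

import numpy as np

from .gomoku import BOARD_SIZE, Board

#: Stimulation timing (ms) and repetition count.
FLASH_MS = 100
ISI_MS = 40
SOA_MS = FLASH_MS + ISI_MS  # onset-to-onset spacing
N_ROUNDS = 10
#: Minimum length of the (shortened) second-level flashing sequence.
MIN_SEQUENCE_LEN = 6
#: Breaks (seconds): between the two sub-trials, and between trials.
INTER_SUBTRIAL_S = 2.5
INTER_TRIAL_S = 5.0

REGION_GRID = 5  # regions per board side
REGION_SPAN = 3  # board cells per region side
REGION_LABELS = string.ascii_uppercase[: REGION_GRID * REGION_GRID]  # 'A'..'Y'
DIGIT_BUTTONS = tuple(str(d) for d in range(1, 10))
REGRET_BUTTON = "R"


@dataclasses.dataclass(frozen=True)
class RegionMap:
    """Bijection between (region label, digit) pairs and board intersections.

    Labels run 'A'..'Y' row-major over the 5 x 5 region grid (so 'M' is the
    centre region); digits run 1..9 row-major within each 3 x 3 block.
    """

    labels: str = REGION_LABELS

    def region_origin(self, label: str) -> tuple[int, int]:
        idx = self.labels.index(label)
        return (idx // REGION_GRID) * REGION_SPAN, (idx % REGION_GRID) * REGION_SPAN

    def cells(self, label: str) -> list[tuple[int, int]]:
        """The 9 board coordinates of a region, digit order 1..9."""
        r0, c0 = self.region_origin(label)
        return [(r0 + d // 3, c0 + d % 3) for d in range(9)]

    def to_coordinate(self, label: str, digit: int) -> tuple[int, int]:
        if not 1 <= digit <= 9:
            raise ValueError(f"digit must be in 1..9, got {digit}")
        r0, c0 = self.region_origin(label)
        return r0 + (digit - 1) // 3, c0 + (digit - 1) % 3

    def from_coordinate(self, row: int, col: int) -> tuple[str, int]:
        if not (0 <= row < BOARD_SIZE and 0 <= col < BOARD_SIZE):
            raise IndexError(f"coordinate {(row, col)} off the board")
        label = self.labels[(row // REGION_SPAN) * REGION_GRID + col // REGION_SPAN]
        digit = (row % REGION_SPAN) * REGION_SPAN + col % REGION_SPAN + 1
        return label, digit


def build_region_map() -> RegionMap:
    """The fixed 25-region partition of the 15 x 15 board."""
    return RegionMap()


def map_selection(region_label: str, digit: int,
                  region_map: RegionMap | None = None) -> tuple[int, int]:
    """(region, digit) -> 0-based board coordinate (row, col)."""
    rm = region_map or build_region_map()
    return rm.to_coordinate(region_label, digit)


@dataclasses.dataclass(frozen=True)
class FlashSchedule:
    """Ordered flash events of one sub-trial.

    Every button flashes exactly once per round in a seeded random order;
    onsets are spaced by flash + ISI with no gap between rounds.
    """

    level: int
    buttons: tuple[str, ...]
    order: tuple[tuple[str, ...], ...]  # per-round permutations
    flash_ms: float = FLASH_MS
    isi_ms: float = ISI_MS

    @property
    def rounds(self) -> int:
        return len(self.order)

    @property
    def n_flashes(self) -> int:
        return sum(len(r) for r in self.order)

    @property
    def soa_ms(self) -> float:
        return self.flash_ms + self.isi_ms

    @property
    def flashes(self) -> Iterator[tuple[float, str, int]]:
        """Yield (onset_ms, button, round) in temporal order."""
        k = 0
        for rnd, perm in enumerate(self.order, start=1):
            for button in perm:
                yield k * self.soa_ms, button, rnd
                k += 1

    @property
    def duration_s(self) -> float:
        return self.n_flashes * self.soa_ms / 1000.0


def _schedule(level: int, buttons: tuple[str, ...], seed: int,
              rounds: int = N_ROUNDS) -> FlashSchedule:
    rng = np.random.default_rng(seed)
    order: list[tuple[str, ...]] = []
    prev_last: str | None = None
    for _ in range(rounds):
        perm = [buttons[i] for i in rng.permutation(len(buttons))]
        # rounds abut with no gap: avoid an immediate repeat of the last
        # flashed button across the boundary (double-flash blindness)
        if len(perm) > 1 and perm[0] == prev_last:
            perm[0], perm[1] = perm[1], perm[0]
        order.append(tuple(perm))
        prev_last = perm[-1]
    return FlashSchedule(level=level, buttons=buttons, order=tuple(order))


def first_level_sequence(seed: int, rounds: int = N_ROUNDS) -> FlashSchedule:
    """All 25 region buttons, flashed in random order each round."""
    return _schedule(1, tuple(REGION_LABELS), seed, rounds)


def gi_ss_sequence(region_label: str, board: Board, seed: int,
                   rounds: int = N_ROUNDS,
                   min_len: int = MIN_SEQUENCE_LEN) -> FlashSchedule:
    """Second-level dynamic sequence with game-interactive shortening.

    Start from the 9 digits plus 'R'; drop digits whose board cell is
    occupied; if fewer than ``min_len`` buttons remain, re-add dropped digits
    in ascending order until the length is ``min_len``.  'R' is a control
    button and is never dropped.
    """
    rm = build_region_map()
    cells = rm.cells(region_label)
    kept = [d for d, cell in zip(DIGIT_BUTTONS, cells) if board.is_empty(*cell)]
    removed = [d for d in DIGIT_BUTTONS if d not in kept]
    buttons = kept + [REGRET_BUTTON]
    for d in removed:
        if len(buttons) >= min_len:
            break
        buttons.insert(len(buttons) - 1, d)  # keep 'R' last in display order
    buttons.sort(key=lambda b: (b == REGRET_BUTTON, b))
    return _schedule(2, tuple(buttons), seed, rounds)


@dataclasses.dataclass
class TrialState:
    """State machine for one trial (two selections -> one coordinate)."""

    board: Board
    phase: str = "level-1"  # level-1 | level-2 | done
    level1_selection: str | None = None
    level2_selection: str | None = None
    coordinate: tuple[int, int] | None = None
    valid: bool = True
    schedule: FlashSchedule | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schedule is None:
            self.schedule = first_level_sequence(self.seed)


class InvalidMoveError(ValueError):
    """The selected digit points at an occupied cell."""


def advance_trial(state: TrialState, selection: str) -> TrialState:
    """Feed one recognized selection into the trial state machine.

    A level-1 selection switches to level-2 and (re)builds that region's
    shortened flashing sequence; a level-2 digit completes the trial with a board
    coordinate; 'R' at level-2 returns to level-1 and marks the trial
    invalid (the regret mechanic).
    """
    if state.phase == "done":
        raise ValueError("trial already complete")
    if state.schedule is None or selection not in state.schedule.buttons:
        raise ValueError(f"selection {selection!r} not in the current sequence")
    if state.phase == "level-1":
        state.level1_selection = selection
        state.phase = "level-2"
        state.schedule = gi_ss_sequence(selection, state.board,
                                        seed=state.seed + 1)
        return state
    # level-2
    state.level2_selection = selection
    if selection == REGRET_BUTTON:
        state.phase = "level-1"
        state.valid = False
        state.level1_selection = None
        state.schedule = first_level_sequence(state.seed + 2)
        return state
    coord = map_selection(state.level1_selection, int(selection))
    if not state.board.is_empty(*coord):
        raise InvalidMoveError(f"cell {coord} is occupied")
    state.coordinate = coord
    state.phase = "done"
    return state


def nominal_trial_seconds(
    schedules: tuple[FlashSchedule, ...],
    include_breaks: bool = True,
) -> float:
    """Stimulation time of a trial's sub-trials from the timing constants,
    plus the inter-sub-trial break and, optionally, the inter-trial break."""
    total = sum(s.duration_s for s in schedules)
    if include_breaks and len(schedules) > 0:
        total += INTER_SUBTRIAL_S * max(len(schedules) - 1, 0)
        total += INTER_TRIAL_S
    return total


def write_schedule_jsonl(path, schedule: FlashSchedule) -> None:
    """One flash per line: timestamp_ms, level, button, round."""
    with open(path, "w") as fh:
        for onset_ms, button, rnd in schedule.flashes:
            fh.write(json.dumps({
                "timestamp_ms": onset_ms, "level": schedule.level,
                "button": button, "round": rnd,
            }) + "\n")
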
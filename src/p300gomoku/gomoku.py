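"""Gomoku (five-in-a-row) on a 15 x 15 board, with a rule-based opponent.

Plain Gomoku: players alternate starting with black, a stone goes on any
empty intersection, and the first side with five or more contiguous stones in
a line wins (overlines count).  No swap/renju opening restrictions.
"""

from __future__ import annotations

import dataclasses
import json
from enum import Enum

import numpy as np

BOARD_SIZE = 15

EMPTY, BLACK, WHITE = 0, 1, 2

_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


class Status(Enum):
    ONGOING = "ongoing"
    BLACK_WINS = "black-wins"
    WHITE_WINS = "white-wins"
    DRAW = "draw"


@dataclasses.dataclass(frozen=True)
class GameResult:
    status: Status

    @property
    def terminal(self) -> bool:
        return self.status is not Status.ONGOING


@dataclasses.dataclass
class Board:
    """Immutable-by-convention game state; ``apply_move`` returns a copy."""

    grid: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros((BOARD_SIZE, BOARD_SIZE), dtype=np.int8)
    )
    history: list[tuple[int, int, int]] = dataclasses.field(default_factory=list)

    @property
    def side_to_move(self) -> int:
        return BLACK if len(self.history) % 2 == 0 else WHITE

    def is_empty(self, row: int, col: int) -> bool:
        return self.grid[row, col] == EMPTY

    def is_full(self) -> bool:
        return not np.any(self.grid == EMPTY)

    def copy(self) -> "Board":
        return Board(grid=self.grid.copy(), history=list(self.history))

    def to_diagram(self) -> str:
        """15-line text diagram: '.' empty, 'X' black, 'O' white."""
        chars = {EMPTY: ".", BLACK: "X", WHITE: "O"}
        return "\n".join(
            "".join(chars[int(v)] for v in row) for row in self.grid
        )

    @classmethod
    def from_diagram(cls, text: str) -> "Board":
        """Rebuild a grid from a diagram (history is synthesized row-major)."""
        rows = [ln for ln in text.strip().splitlines()]
        grid = np.zeros((BOARD_SIZE, BOARD_SIZE), dtype=np.int8)
        for r, ln in enumerate(rows):
            for c, ch in enumerate(ln):
                grid[r, c] = {".": EMPTY, "X": BLACK, "O": WHITE}[ch]
        history = [
            (int(r), int(c), int(grid[r, c]))
            for r, c in np.argwhere(grid != EMPTY)
        ]
        # interleave so the colour counts stay legal in replay checks
        history.sort(key=lambda m: (m[2], m[:2]))
        return cls(grid=grid, history=history)


def apply_move(board: Board, coordinate: tuple[int, int], color: int) -> Board:
    """Place a stone; validates bounds, emptiness, and side to move."""
    row, col = coordinate
    if not (0 <= row < BOARD_SIZE and 0 <= col < BOARD_SIZE):
        raise IndexError(f"coordinate {coordinate} is off the board")
    if board.grid[row, col] != EMPTY:
        raise ValueError(f"cell {coordinate} is already occupied")
    if color != board.side_to_move:
        raise ValueError(
            f"wrong side to move: expected {board.side_to_move}, got {color}"
        )
    new = board.copy()
    new.grid[row, col] = color
    new.history.append((row, col, color))
    return new


def check_win(board: Board, last_move: tuple[int, int]) -> GameResult:
    """Scan the 4 line directions through the last move for a run of >= 5."""
    row, col = last_move
    color = int(board.grid[row, col])
    if color == EMPTY:
        return GameResult(Status.ONGOING)
    for dr, dc in _DIRECTIONS:
        run = 1
        for sign in (1, -1):
            r, c = row + sign * dr, col + sign * dc
            while (
                0 <= r < BOARD_SIZE
                and 0 <= c < BOARD_SIZE
                and board.grid[r, c] == color
            ):
                run += 1
                r += sign * dr
                c += sign * dc
        if run >= 5:
            status = Status.BLACK_WINS if color == BLACK else Status.WHITE_WINS
            return GameResult(status)
    if board.is_full():
        return GameResult(Status.DRAW)
    return GameResult(Status.ONGOING)


def _line_run(board: Board, row: int, col: int, dr: int, dc: int,
              color: int) -> tuple[int, int]:
    """Run length through (row, col) if ``color`` played there, and the
    number of open ends (0-2)."""
    run = 1
    open_ends = 0
    for sign in (1, -1):
        r, c = row + sign * dr, col + sign * dc
        while (
            0 <= r < BOARD_SIZE and 0 <= c < BOARD_SIZE
            and board.grid[r, c] == color
        ):
            run += 1
            r += sign * dr
            c += sign * dc
        if 0 <= r < BOARD_SIZE and 0 <= c < BOARD_SIZE and board.grid[r, c] == EMPTY:
            open_ends += 1
    return run, open_ends

# pattern score per (capped run length, open ends): open runs dominate
_PATTERN = {
    (2, 2): 10, (2, 1): 3, (2, 0): 0,
    (3, 2): 100, (3, 1): 25, (3, 0): 0,
    (4, 2): 5000, (4, 1): 1000, (4, 0): 0,
}


def _cell_score(board: Board, row: int, col: int, color: int) -> float:
    score = 0.0
    for dr, dc in _DIRECTIONS:
        run, ends = _line_run(board, row, col, dr, dc, color)
        if run >= 5:
            score += 10 ** 6
        elif run >= 2:
            score += _PATTERN[(min(run, 4), ends)]
        elif ends == 2:
            score += 1  # lone stone with room to grow
    return score


def _winning_cells(board: Board, color: int) -> list[tuple[int, int]]:
    cells = []
    for row, col in np.argwhere(board.grid == EMPTY):
        for dr, dc in _DIRECTIONS:
            run, _ = _line_run(board, int(row), int(col), dr, dc, color)
            if run >= 5:
                cells.append((int(row), int(col)))
                break
    return cells


def ai_move(board: Board, seed: int = 0) -> tuple[int, int]:
    """Rule-cascade opponent: win now, else block, else best pattern score.

    Deterministic for a given board: ties are broken by the lowest (row, col)
    coordinate.  Strength is deliberately modest (1-ply lookahead plus a
    pattern heuristic over open/closed runs of 2-4).
    """
    if board.is_full():
        raise ValueError("board is full")
    me = board.side_to_move
    opp = BLACK if me == WHITE else WHITE

    wins = _winning_cells(board, me)
    if wins:
        return min(wins)
    threats = _winning_cells(board, opp)
    if threats:
        return min(threats)

    best: tuple[int, int] | None = None
    best_score = -np.inf
    for row, col in np.argwhere(board.grid == EMPTY):
        row, col = int(row), int(col)
        # offense outweighs defense (0.3): two copies of this heuristic
        # reach a decisive result instead of blocking each other to a draw
        score = _cell_score(board, row, col, me) + 0.3 * _cell_score(
            board, row, col, opp
        )
        # gentle centre bias keeps the opening sensible
        score += 0.01 * (14 - abs(row - 7) - abs(col - 7))
        if score > best_score:
            best_score = score
            best = (row, col)
    assert best is not None
    return best


def replay(history: list[tuple[int, int, int]]) -> Board:
    """Rebuild a board by replaying a move history from scratch."""
    board = Board()
    for row, col, color in history:
        board = apply_move(board, (row, col), color)
    return board


def write_game_log(path, history, statuses) -> None:
    """JSON-lines game log: move index, color, row, col, status after move."""
    with open(path, "w") as fh:
        for i, ((row, col, color), status) in enumerate(zip(history, statuses)):
            fh.write(json.dumps({
                "move": i, "color": "black" if color == BLACK else "white",
                "row": row, "col": col, "status": status.value,
            }) + "\n")
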
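"""Dynamic second-level sequence shortening as the board fills up.

The second-level interface flashes the 9 position digits plus the regret
button 'R'.  Digits whose board cells are occupied are dropped from the
flashing sequence — but never below 6 buttons, because too-rapid re-flashes
of the same stimulus cause repetition blindness and degrade the P300.
"""

from p300gomoku import Board, apply_move, build_region_map, gi_ss_sequence
from p300gomoku.gomoku import BLACK, WHITE
from p300gomoku.paradigm import nominal_trial_seconds

rm = build_region_map()
board = Board()
cells = rm.cells("M")

for n_occupied in (0, 3, 8):
    while len(board.history) < n_occupied:
        i = len(board.history)
        board = apply_move(board, cells[i], BLACK if i % 2 == 0 else WHITE)
    sched = gi_ss_sequence("M", board, seed=1)
    secs = nominal_trial_seconds((sched,), include_breaks=False)
    print(f"{n_occupied} occupied cells -> {len(sched.buttons)} buttons "
          f"{sched.buttons}, {secs:.1f} s of stimulation")

print("shortening saves stimulation time; the floor of 6 keeps the "
      "attended digit rare enough to evoke a reliable P300.")
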
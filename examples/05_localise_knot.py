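"""Knot localisation: oracle ground truth and the LSTM's P_k(x).

Builds a ring with a tight trefoil spliced into beads 10-40, shows the
oracle's knotted-arc mask, then trains the sequence-to-sequence
localiser on a small thermal dataset and prints its per-bead accuracy.
"""
import numpy as np

from writhenet.experiments import FIVE_KNOTS, localisation_experiment
from writhenet.fixtures import tight_trefoil_in_loop
from writhenet.oracle import localise_knot

fix = tight_trefoil_in_loop(100, 10, 40)
mask = localise_knot(fix, method="shrink", rng=np.random.default_rng(0),
                     full_label=(3, 7))
run = np.flatnonzero(mask.bits)
print(f"spliced trefoil fixture: oracle mask beads {run.min()}..{run.max()} "
      f"({mask.run_length()} of 100)")

rep = localisation_experiment(FIVE_KNOTS, n_per_class=120, seed=44)
print(f"\nLSTM localiser on thermal 5-knot data: "
      f"per-bead binary accuracy {rep.accuracy:.3f}")
print()
print("The oracle finds the shortest arc whose minimally-interfering")
print("closure still carries the ring's knot type; the recurrent network")
print("recovers that mask from the StA profile alone, bead by bead.")
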
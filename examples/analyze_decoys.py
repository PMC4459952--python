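"""Decoy analysis: CAPRI-style metrics and search-efficiency curves.

Runs a short WTE-REMC refinement, then reports per-decoy quality against the
bound reference and the two efficiency curves used to compare protocols: the
running mean of the 10 lowest interaction scores relative to the overall
minimum, and the running minimum ligand RMSD.
"""

import numpy as np

from remcdock.analysis import best_lrmsd_curve, convergence_curve, evaluate_trajectory
from remcdock.energy import EnergyParams
from remcdock.sampling import ProtocolConfig, run_protocol
from remcdock.toys import generate_start, make_toy_complex

native, _, library = make_toy_complex()
start = generate_start(native, rng=np.random.default_rng(42))
cfg = ProtocolConfig(protocol="WTE-REMC", steps=15_000, seed=42)
traj = run_protocol(cfg, start, EnergyParams(), library, native=native)

metrics = evaluate_trajectory(traj, native)
frac = float((metrics["capri_class"] != "none").mean())
print(metrics.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nfraction of CAPRI medium+high decoys: {frac:.3f}")

steps = metrics["step"].tolist()
conv = convergence_curve(traj.table, steps)
best = best_lrmsd_curve(metrics, steps)
print("\nstep   mean(10 lowest I_sc) − min I_sc   best L_rmsd so far")
for (s, c), (_, b) in zip(conv, best):
    print(f"{s:5d}   {c:>30.3f}   {b:18.3f}")
print(
    "\nThe best-L_rmsd curve is a running minimum; the score curve is"
    "\nnon-increasing once ten decoys have accumulated (earlier points average"
    "\nover fewer scores).  The faster they fall, the more efficiently the"
    "\nprotocol optimizes the docking score and approaches the bound geometry."
)

if traj.exchange_attempts:
    rates = traj.exchange_rates()
    print(f"\nexchange-rate median across neighbour pairs: {np.median(list(rates.values())):.2f}")
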
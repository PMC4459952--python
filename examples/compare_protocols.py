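"""Search-efficiency comparison: plain MC vs. the 2-D replica-exchange protocol.

The toy complex carries a decoy trap — a laterally displaced, shallower
binding patch — next to the true funnel.  Plain MC at the base temperature
diffuses slowly (0.1 Å / 1° steps) and tends to stall; WTE-H-REMC couples 25
replicas across 5 temperatures and 5 repulsive-softness levels, each with a
well-tempered energy bias, and finds the funnel orders of magnitude faster.
Hits are the first per-replica step at which any replica comes within 2 Å
ligand-RMSD of the bound pose; runs that never hit report the full budget.
"""

import numpy as np

from remcdock.energy import EnergyParams
from remcdock.sampling import ProtocolConfig, run_protocol
from remcdock.toys import ToyComplexSpec, generate_start, make_toy_complex

spec = ToyComplexSpec(decoy_trap=(12.0, 1.0))
native, _, library = make_toy_complex(spec)
params = EnergyParams()
budget = 10_000

print(f"per-replica budget: {budget} steps, hit threshold: L_rmsd <= 2 Å\n")
for seed in range(3):
    start = generate_start(native, rng=np.random.default_rng(100 + seed))
    row = [f"start {seed}:"]
    for protocol in ("MC", "WTE-H-REMC"):
        cfg = ProtocolConfig(protocol=protocol, steps=budget, seed=seed, stop_on_hit=True)
        traj = run_protocol(cfg, start, params, library, native=native)
        hit = traj.first_hit_step
        row.append(f"{protocol} first hit: {hit if hit else f'none in {budget}'}")
    print("  " + "  |  ".join(row))
print(
    "\nLower is better: fewer per-replica steps to the first near-native pose."
    "\nThe enhanced-sampling protocol pays 25x the compute per step but"
    "\nconverts it into a far larger per-step chance of crossing the barrier."
)
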
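"""Well-tempered ensemble bias: geometrically decaying deposition heights.

Each visit to an energy bin deposits a Gaussian of height
W = ω·exp(−V/ΔT) with ΔT = (γ−1)T, where V is the bias already accumulated
in that bin.  Heights therefore shrink geometrically and the bias converges,
while energy fluctuations are boosted by roughly a factor γ — which is what
keeps replica-exchange acceptance rates high with only a handful of
replicas.
"""

from remcdock.sampling import WTEBias

bias = WTEBias(temperature=0.15, gamma=5.0, omega=1.0, bin_width=2.0)
print(f"ΔT = (γ−1)·T = {bias.delta_t:.2f} (γ = {bias.gamma}, T = {bias.temperature})\n")
print("visit   deposited height W     accumulated bias V")
v = 0.0
for k in range(1, 11):
    w = bias.deposit(1.0)  # repeated visits to the bin holding E = 1.0
    v += w
    print(f"{k:5d}   {w:18.6f}   {v:18.6f}")
print(
    "\nEvery height is ω·exp(−V_old/ΔT): the first deposit is the full ω, and"
    "\nrepeat visits add geometrically less, so the well fills without ever"
    "\novershooting — the tempered analogue of flattening the landscape."
)
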
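"""Grand canonical sampling of an ideal gas against the exact answer.

For non-interacting particles the Adams-formulation chain has a Poisson
stationary occupancy with mean e^B.  Both the instantaneous and the
nonequilibrium (NCMC) move methods are run and compared with that closed
form — the standard correctness oracle for the acceptance machinery.
"""

import math

import numpy as np

from gcncmc import (AdamsParameters, GCRegion, IntegratorSettings,
                    NCMCProtocol, attempt_instantaneous_move,
                    attempt_ncmc_move, make_ideal_gas)

B = -1.0
n_moves, burn = 30_000, 3_000
region = GCRegion(mode="whole-box", species="gas")
adams = AdamsParameters(B=B)

# instantaneous GCMC
sys = make_ideal_gas(1, seed=1)
rng = np.random.default_rng(2)
occ = []
for k in range(n_moves):
    attempt_instantaneous_move(sys, region, adams, rng)
    if k >= burn:
        occ.append(len(sys.real_molecule_ids("gas")))
print(f"instantaneous GCMC: mean N = {np.mean(occ):.3f}")

# GCNCMC (work is identically zero for an ideal gas, so the chain must
# coincide with the instantaneous one in distribution)
sys = make_ideal_gas(1, seed=3)
rng = np.random.default_rng(4)
md_rng = np.random.default_rng(5)
proto = NCMCProtocol(n_pert=2, n_prop=1)
occ = []
for k in range(n_moves):
    attempt_ncmc_move(sys, region, adams, proto, IntegratorSettings(),
                      rng, md_rng=md_rng)
    if k >= burn:
        occ.append(len(sys.real_molecule_ids("gas")))
print(f"GCNCMC:             mean N = {np.mean(occ):.3f}")
print(f"exact Poisson mean: e^B    = {math.exp(B):.3f}")
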
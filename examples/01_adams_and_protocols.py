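"""Adams parameters and NCMC protocol arithmetic.

Computes the equilibrium Adams parameter B for a bulk water box and for a
6 Å spherical move region, then builds two switching protocols from their
switching times.  B folds the excess chemical potential and region volume
into one dimensionless constant: exp(B) sets the insertion pressure of the
grand canonical chain.
"""

import math

from gcncmc import (adams_equilibrium, gcmc_deletion_acceptance,
                    gcmc_insertion_acceptance, protocol_from_time)

# bulk water: mu_ex = -6.09 kcal/mol (hydration free energy of one water),
# V_std = 30.345 A^3, T = 298 K, box volume 64.02 nm^3
B_bulk = adams_equilibrium(-6.09, 64020.0, 30.345, 298.0)
print(f"B_equil (64.02 nm^3 water box)  = {B_bulk:.3f}")

V_sphere = (4.0 / 3.0) * math.pi * 6.0**3
B_sphere = adams_equilibrium(-6.09, V_sphere, 30.345, 298.0)
print(f"B_equil (6 A sphere, {V_sphere:.1f} A^3) = {B_sphere:.3f}")

# acceptance probabilities at those parameters
p_ins = gcmc_insertion_acceptance(0.0, B_bulk, N=0)
p_del = gcmc_deletion_acceptance(4.0, B_bulk, N=3)
print(f"insertion acceptance (dU=0, N=0)   = {p_ins:.4f}")
print(f"deletion acceptance (dU=+4, N=3)   = {p_del:.4f}")

# switching-time relation tau = (n_pert + 1) * n_prop * dt
for tau, n_prop in ((10.0, 10), (15.0, 50)):
    proto = protocol_from_time(tau, n_prop, timestep=0.002)
    print(f"tau = {tau:4.0f} ps, n_prop = {n_prop:2d} -> n_pert = {proto.n_pert}")

print("\nB < 0 means insertions into bulk are rare; the perturbation count "
      "sets how gradually a molecule is coupled during one NCMC move.")
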
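"""Physical constants in the package's internal unit system.

Internal units: length Å, time ps, mass amu, energy kcal/mol, temperature K,
charge e.  Velocities are Å/ps and forces kcal/mol/Å.
"""

#: Boltzmann constant, kcal/(mol K).
KB = 0.0019872041

#: Coulomb constant, kcal Å / (mol e²).
COULOMB = 332.0637

#: Conversion of kcal/mol into amu Å²/ps² (the "AKMA" energy unit);
#: acceleration [Å/ps²] = force [kcal/mol/Å] * KCAL_MOL_TO_AKMA / mass [amu].
KCAL_MOL_TO_AKMA = 418.4

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: 1 bar expressed in kcal/(mol Å³), for Monte Carlo volume moves.
BAR_TO_KCAL_MOL_A3 = 1.0e5 * 1.0e-30 * AVOGADRO / 4184.0
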
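# Rigid 3-site water parameters (TIP3P, as published in the force-field
# literature).  Format version 1 — see docs/formats.md.
#
# site columns: label  mass(amu)  charge(e)  epsilon(kcal/mol)  sigma(A)  x  y  z (A)
version 1
template water
resname HOH WAT TIP3
primary O
site O   15.9994  -0.834  0.1521  3.15061   0.000000  0.000000  0.000000
site H1   1.008    0.417  0.0     0.0       0.957200  0.000000  0.000000
site H2   1.008    0.417  0.0     0.0      -0.239987  0.926627  0.000000
end
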
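"""Physical constants and pipeline-wide defaults.

Units throughout the package: lengths in nm, energies in kJ/mol, charges in
units of the elementary charge e, forces in kJ mol^-1 nm^-1, times in ps.
"""

#: Electric conversion factor 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_CONSTANT = 138.935458

#: Short-range nonbonded cutoff (nm). Coulomb is truncated here; the
#: Lennard-Jones force is switched to zero between R_SWITCH and R_CUT.
R_CUT = 1.2

#: Inner radius of the Lennard-Jones force-switching window (nm).
R_SWITCH = 1.0

#: Default time between analysed trajectory frames (ps).
STRIDE_PS = 40.0

#: Default difference-vector threshold separating down (<=) from up (>).
STATE_THRESHOLD = 0.0
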
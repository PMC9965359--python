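"""Physical constants and unit conversions.

Internal unit system follows the GROMACS convention: lengths in nm, times in
ps, masses in amu (g/mol), energies in kJ/mol.  Stress/pressure is expressed
in bar at I/O boundaries; kJ·mol⁻¹·nm⁻³ converts to bar by ``BAR_PER_KJ_MOL_NM3``.
"""

# Boltzmann constant, kJ mol^-1 K^-1 (molar energies)
KB_KJ_MOL = 0.0083144621

# 1 kJ mol^-1 nm^-3 in bar
BAR_PER_KJ_MOL_NM3 = 16.6054

# Boltzmann constant in bar nm^3 K^-1 (per molecule, for Green-Kubo prefactors
# with stresses in bar and volumes in nm^3)
KB_BAR_NM3 = KB_KJ_MOL * BAR_PER_KJ_MOL_NM3

# amu nm^-3 -> g cm^-3
G_CM3_PER_AMU_NM3 = 1.66053906660

# Standard atomic masses, g/mol
ATOMIC_MASSES = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "Si": 28.085,
}
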
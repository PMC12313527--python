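"""Internal unit system and conversions.

Everything inside the package is expressed in nm, kJ/mol, ps and K.
Angstrom and kcal/mol appear only at I/O boundaries (PDB files, reported
free energies) and are converted explicitly with the helpers below.
"""

# Boltzmann constant, kJ/(mol K)
KB = 0.00831446261815324

ANGSTROM_PER_NM = 10.0
KJ_PER_KCAL = 4.184


def kbt(temperature: float) -> float:
    """Thermal energy k_B T in kJ/mol at ``temperature`` (K)."""
    return KB * temperature


def nm_to_angstrom(x):
    return x * ANGSTROM_PER_NM


def angstrom_to_nm(x):
    return x / ANGSTROM_PER_NM


def kj_to_kcal(x):
    return x / KJ_PER_KCAL


def kcal_to_kj(x):
    return x * KJ_PER_KCAL
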
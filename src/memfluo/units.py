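"""Unit conventions and conversions used package-wide.

Lengths are µm, times s, diffusion coefficients µm²/s, surface
concentrations nmol/m², intensities counts/s.  All conversions between
these conventions live here so they can be unit-tested in one place.
"""

AVOGADRO = 6.02214076e23  # 1/mol

# 1 molecule/µm² = 1e12 molecules/m²; /N_A -> mol/m²; *1e9 -> nmol/m²
_MOLEC_PER_UM2_TO_NMOL_PER_M2 = 1.0e21 / AVOGADRO


def molecules_per_um2_to_nmol_per_m2(density: float) -> float:
    """Convert a surface density in molecules/µm² to nmol/m²."""
    return density * _MOLEC_PER_UM2_TO_NMOL_PER_M2


def nmol_per_m2_to_molecules_per_um2(conc: float) -> float:
    """Convert a surface concentration in nmol/m² to molecules/µm²."""
    return conc / _MOLEC_PER_UM2_TO_NMOL_PER_M2


def nm_to_um(x: float) -> float:
    return x * 1.0e-3
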
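"""Physical constants and unit conversions used across the package.

All masses are in daltons (Da), m/z in Da per elementary charge (Th),
collision cross sections in nm^2, atomic coordinates in angstroms,
drift times in milliseconds and concentrations in nM internally.
"""

#: Mass of a proton in Da; native electrospray in positive mode charges
#: by protonation, so peak centres sit at (M + z * PROTON_MASS) / z.
PROTON_MASS = 1.00728

#: Mass of a helium atom in Da. Reference CCS values for protein
#: calibrants are conventionally reported in helium, so the reduced mass
#: entering the calibration uses the helium mass by default.
HELIUM_MASS = 4.0026

#: Mass of molecular nitrogen in Da (alternative drift-gas choice).
NITROGEN_MASS = 28.0134

#: Mass shift of a single phosphorylation (+HPO3) in Da.
PHOSPHO_SHIFT = 79.966

#: Square angstroms per square nanometre.
A2_PER_NM2 = 100.0


def um_to_nm(value_um: float) -> float:
    """Convert a concentration from micromolar to nanomolar."""
    return value_um * 1000.0


def nm_to_um(value_nm: float) -> float:
    """Convert a concentration from nanomolar to micromolar."""
    return value_nm / 1000.0


def mz_for(neutral_mass: float, charge: int) -> float:
    """m/z of a protonated ion of a given neutral mass and charge."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge
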
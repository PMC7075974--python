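"""Physical constants shared by every module.

All energies are kcal mol^-1, distances Å, temperatures K. Pinning the
constants in one table prevents cross-module drift between the
free-energy, rate and electrostatics layers.
"""

#: Boltzmann constant, J K^-1 (CODATA 2018, exact by SI definition)
K_B = 1.380649e-23

#: Planck constant, J s (CODATA 2018, exact by SI definition)
PLANCK_H = 6.62607015e-34

#: thermochemical calorie, J (exact)
CAL_TO_J = 4.184

#: gas constant in kcal mol^-1 K^-1
R_KCAL = 1.987204e-3

#: Coulomb constant in kcal Å mol^-1 e^-2
COULOMB_KCAL = 332.06

#: default simulation/assay temperature, K
DEFAULT_TEMPERATURE = 310.0


def rt(temperature: float) -> float:
    """Thermal energy R*T in kcal mol^-1."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return R_KCAL * temperature
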
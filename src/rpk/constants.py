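"""Physical constants shared across the package.

Units follow the analysis conventions used throughout: lengths in Å,
times in ps, energies in kcal mol⁻¹, charges in elementary-charge units.
"""

#: Gas constant, kcal mol⁻¹ K⁻¹ (CODATA 2018).
R_KCAL = 1.987204e-3

#: Boltzmann constant, J K⁻¹ (exact, SI 2019).
K_B = 1.380649e-23

#: Planck constant, J s (exact, SI 2019).
H_PLANCK = 6.62607015e-34

#: Default analysis temperature, K (matches the simulation thermostat).
T_DEFAULT = 310.15

#: Coulomb constant for point charges, kcal Å mol⁻¹ e⁻².
COULOMB_K = 332.0637


def rt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy R·T in kcal mol⁻¹."""
    return R_KCAL * temperature


def attempt_frequency(temperature: float = T_DEFAULT) -> float:
    """Transition-state-theory prefactor k_B·T/h in s⁻¹ (~6.46e12 at 310.15 K)."""
    return K_B * temperature / H_PLANCK
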
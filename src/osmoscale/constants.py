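"""Physical constants and unit conversions.

Unit conventions used throughout the package:

* concentrations in mOsm (osmolar milli-units; 1 mOsm == 1 mol/m^3 of
  osmotically active particles),
* volumes in um^3,
* membrane tensions in N/m,
* temperature in K,
* osmolyte *amounts* as concentration x volume (mOsm.um^3), convertible
  to particle counts via :data:`PARTICLES_PER_MOSM_UM3`.

With these choices the Van't Hoff pressure is Pi = C * R_GAS * T (Pa when C
is expressed in mol/m^3) and the zero-tension osmometer law V - b = N / C
is exact arithmetic, with no hidden unit factors.
"""

R_GAS = 8.31446261815324
"""Molar gas constant, J/(mol K)."""

K_BOLTZMANN = 1.380649e-23
"""Boltzmann constant, J/K."""

AVOGADRO = 6.02214076e23
"""Avogadro constant, 1/mol."""

PARTICLES_PER_MOSM_UM3 = 6.02214076e5
"""Particles per um^3 in a 1 mOsm (= 1 mol/m^3 = 1e-18 mol/um^3) solution."""

DEFAULT_TEMPERATURE_K = 303.15
"""Default absolute temperature (30 degrees C, the culture temperature)."""

WATER_VISCOSITY_30C = 7.97e-4
"""Dynamic viscosity of water at 30 degrees C, Pa s."""

UM_TO_M = 1e-6
M2_PER_S_TO_UM2_PER_S = 1e12


def particles_per_um3_to_mosm(n_per_um3: float) -> float:
    """Convert a particle number density (1/um^3) to osmolarity (mOsm)."""
    if n_per_um3 < 0:
        raise ValueError(f"particle density must be non-negative, got {n_per_um3}")
    return n_per_um3 / PARTICLES_PER_MOSM_UM3


def mosm_um3_to_particles(amount_mosm_um3: float) -> float:
    """Convert an osmolyte amount (mOsm um^3) to an absolute particle count."""
    return amount_mosm_um3 * PARTICLES_PER_MOSM_UM3
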
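"""Physical constants and unit conversions.

Internal unit system: lengths in nm, time in ns, energy in kBT (at the
configured temperature), voltage in V, concentration in ions/nm^3, rates in
ns^-1.  Conversion helpers to and from SI live here so the rest of the
package never multiplies by 1e-9 by hand.
"""

import math

# CODATA 2018 exact values
KB = 1.380649e-23  # Boltzmann constant, J/K
E_CHARGE = 1.602176634e-19  # elementary charge, C
N_AVOGADRO = 6.02214076e23  # 1/mol
EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

DEFAULT_TEMPERATURE = 298.0  # K, room temperature

# unit factors
NM = 1e-9  # m per nm
NS = 1e-9  # s per ns


def kbt_joules(temperature: float) -> float:
    """Thermal energy kB*T in joules."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature


def thermal_voltage(temperature: float) -> float:
    """kB*T/e in volts (~25.7 mV at 298 K)."""
    return kbt_joules(temperature) / E_CHARGE


def molar_to_per_nm3(c_molar: float) -> float:
    """Convert mol/L to ions per nm^3 (1 mol/L = 0.6022 nm^-3; 1 L = 1e24 nm^3)."""
    return c_molar * N_AVOGADRO * 1e-24


def per_nm3_to_molar(c_nm3: float) -> float:
    """Convert ions per nm^3 to mol/L."""
    return c_nm3 / (N_AVOGADRO * 1e-24)


def mobility_si_to_nm2_per_vns(mu: float) -> float:
    """m^2/(V s) -> nm^2/(V ns)."""
    return mu * 1e18 / 1e9


def diffusion_si_to_nm2_per_ns(d: float) -> float:
    """m^2/s -> nm^2/ns."""
    return d * 1e18 / 1e9


def coulomb_kbt_nm(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """e^2/(4 pi eps0) expressed in kBT*nm (~56 kBT nm at 298 K).

    The Coulomb energy between unit charges a distance r nm apart in a
    medium of relative permittivity eps is then ``coulomb_kbt_nm(T)/(eps*r)``.
    """
    return E_CHARGE**2 / (4.0 * math.pi * EPS0 * kbt_joules(temperature) * NM)
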
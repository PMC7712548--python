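"""Back-of-the-envelope physical estimators for the kinetic parameters.

Each estimator maps directly onto one of the standard expressions for
transport through a small pore -- diffusive capture by an absorbing disc,
drift feeding against the pore resistance, Arrhenius-suppressed barrier
crossing, Hille-style pore-plus-access resistance, and the continuum
conductance/permeability pair.  Estimators return a
:class:`TransportEstimate` that echoes its inputs so fitted and estimated
rates can be compared side by side in reports.

Sign conventions: concentrations in ions/nm^3, lengths in nm, resistivities
in ohm*m (SI, since they multiply SI geometry inside), rates in ns^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import constants as K
from .core import Conditions, IonSpecies, PoreGeometry

#: capture solid-angle conventions: a circular absorbing disc gives 4,
#: a hemispherical pore mouth 2*pi, a sphere in free solution 4*pi.
THETA_DISC = 4.0
THETA_HEMISPHERE = 2.0 * math.pi
THETA_SPHERE = 4.0 * math.pi


@dataclass
class TransportEstimate:
    value: float
    units: str
    formula: str
    inputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.value < 0:
            raise ValueError(f"estimate {self.formula} is negative: {self.value}")

    def __float__(self) -> float:
        return self.value


def capture_rate(theta: float, D: float, c: float, ap: float) -> TransportEstimate:
    """Diffusion-limited capture rate kb0 = Theta*D*c*ap.

    Parameters: capture solid angle Theta (4 for a disc), D in nm^2/ns,
    c in ions/nm^3, ap in nm.  For K+ at 1 mol/L and ap = 0.1 nm this is
    about 0.5 ns^-1.  Exactly linear in every argument.
    """
    if min(theta, D, c, ap) < 0:
        raise ValueError("capture_rate inputs must be >= 0")
    return TransportEstimate(theta * D * c * ap, "ns^-1", "capture_rate",
                             dict(theta=theta, D=D, c=c, ap=ap))


def drift_feed_coefficient(ap: float, gamma_p: float, hp: float,
                           valence: int = 1) -> TransportEstimate:
    """Drift-fed supply coefficient kappa_b = pi*ap^2/(q*gamma_p*hp).

    The pore resistance dominates, so the current a voltage V can push,
    V/(gamma_p*hp/(pi*ap^2)), must be supplied by bulk drift.  Returned in
    ions/(V*ns); multiply by 1e9 for ions/(V*s).
    """
    if gamma_p <= 0 or hp <= 0:
        raise ValueError("gamma_p and hp must be > 0")
    per_vs = math.pi * (ap * K.NM) ** 2 / (abs(valence) * K.E_CHARGE * gamma_p * hp * K.NM)
    return TransportEstimate(per_vs * 1e-9, "ions/(V*ns)", "drift_feed_coefficient",
                             dict(ap=ap, gamma_p=gamma_p, hp=hp, valence=valence))


def dissociation_rate(ion: IonSpecies, Ud: float, voltage: float,
                      hp: float, delta_p: float) -> TransportEstimate:
    """Field-driven escape from the internal site: kd = mu*e^{-Ud}*(V/hp)/delta_p.

    The drift velocity mu*Ep (with Ep = V/hp the field across the effective
    membrane) divided by the site length delta_p, suppressed by the exit
    barrier Ud (kBT).  Equals q*Pp*Ep/kBT with Pp the pore permeability.
    Barrierless K+ at 1 V gives ~76 ns^-1 for delta_p = hp = 1 nm and
    ~190 ns^-1 for delta_p = 0.4 nm.
    """
    if hp <= 0 or delta_p <= 0:
        raise ValueError("hp and delta_p must be > 0")
    if voltage < 0:
        raise ValueError("voltage must be >= 0")
    mu = ion.mobility_nm2_per_vns  # nm^2/(V ns)
    val = mu * math.exp(-Ud) * (voltage / hp) / delta_p
    return TransportEstimate(val, "ns^-1", "dissociation_rate",
                             dict(Ud=Ud, voltage=voltage, hp=hp, delta_p=delta_p,
                                  mobility=ion.mobility))


def arrhenius_rate(k0: float, U: float) -> TransportEstimate:
    """k = k0 * exp(-U) with the barrier U in kBT."""
    if k0 < 0:
        raise ValueError("k0 must be >= 0")
    return TransportEstimate(k0 * math.exp(-U), "ns^-1", "arrhenius_rate",
                             dict(k0=k0, U=U))


def pore_plus_access_resistance(gamma: float, ap: float, hp: float) -> TransportEstimate:
    """Series resistance of a cylindrical pore and its two access regions:
    R = gamma*(1/(2*ap) + hp/(pi*ap^2)), in ohms (gamma in ohm*m, lengths nm).
    hp = 0 leaves the pure (two-sided) access resistance gamma/(2*ap)."""
    if gamma <= 0 or ap <= 0 or hp < 0:
        raise ValueError("gamma, ap must be > 0 and hp >= 0")
    val = gamma * (1.0 / (2.0 * ap * K.NM) + hp * K.NM / (math.pi * (ap * K.NM) ** 2))
    return TransportEstimate(val, "ohm", "pore_plus_access_resistance",
                             dict(gamma=gamma, ap=ap, hp=hp))


def access_resistance_one_sided(gamma: float, ap: float) -> TransportEstimate:
    """Ra = gamma/(4*ap): converging-field resistance on one side of a disc."""
    if gamma <= 0 or ap <= 0:
        raise ValueError("gamma and ap must be > 0")
    return TransportEstimate(gamma / (4.0 * ap * K.NM), "ohm",
                             "access_resistance_one_sided", dict(gamma=gamma, ap=ap))


def continuum_pore_conductance(c_p: float, mu_p: float, Ap: float,
                               hp: float, valence: int = 1) -> TransportEstimate:
    """Gp = q*cp*mu_p*Ap/hp in siemens (cp in ions/nm^3, mu_p in m^2/(V s),
    Ap in nm^2, hp in nm)."""
    if hp <= 0:
        raise ValueError("hp must be > 0")
    cp_si = c_p / K.NM**3  # ions/m^3
    val = abs(valence) * K.E_CHARGE * cp_si * mu_p * (Ap * K.NM**2) / (hp * K.NM)
    return TransportEstimate(val, "S", "continuum_pore_conductance",
                             dict(c_p=c_p, mu_p=mu_p, Ap=Ap, hp=hp))


def continuum_permeability(D_p: float, hp: float) -> TransportEstimate:
    """Pp = Dp/hp in nm/ns (Dp in nm^2/ns, hp in nm)."""
    if hp <= 0:
        raise ValueError("hp must be > 0")
    return TransportEstimate(D_p / hp, "nm/ns", "continuum_permeability",
                             dict(D_p=D_p, hp=hp))


def bulk_voltage_drop(voltage: float, ap: float, gamma_b: float, gamma_p: float,
                      hp: float,
                      temperature: float = K.DEFAULT_TEMPERATURE) -> tuple[float, float]:
    """One-sided access voltage drop Vb = pi*ap*gamma_b*V/(4*gamma_p*hp).

    This is I*Ra with the current limited by the pore resistance.  Returns
    (Vb in volts, Vb in units of kBT/q); about 1.5 kBT at 1 V for the
    default crown-ether parameters.  Vb/Ra reproduces the drift feeding
    rate kappa_b*V of :func:`drift_feed_coefficient` identically.
    """
    if gamma_p <= 0 or hp <= 0:
        raise ValueError("gamma_p and hp must be > 0")
    vb = math.pi * ap * gamma_b * voltage / (4.0 * gamma_p * hp)
    return vb, vb / K.thermal_voltage(temperature)


# ---------------------------------------------------------------------------
# the full estimate table


def estimate_table(conditions: Conditions, ion: IonSpecies,
                   geometry: PoreGeometry, theta: float = THETA_DISC,
                   gamma_p: float | None = None,
                   voltage: float = 1.0) -> list[TransportEstimate]:
    """All analytic estimates for one configuration, at the given voltage.

    ``gamma_p`` defaults to twice the bulk resistivity (only the cation
    carries current in the pore).
    """
    gp = 2.0 * conditions.bulk_resistivity if gamma_p is None else gamma_p
    gb = conditions.bulk_resistivity
    ap, hp, dp = geometry.effective_radius, geometry.effective_length, \
        geometry.internal_site_length
    c = conditions.concentration_per_nm3
    D = ion.diffusion_nm2_per_ns
    out = [
        capture_rate(theta, D, c, ap),
        drift_feed_coefficient(ap, gp, hp, ion.valence),
        drift_feed_coefficient(ap, gb, hp, ion.valence),
        dissociation_rate(ion, 0.0, voltage, hp, hp),
        dissociation_rate(ion, 0.0, voltage, hp, dp),
        pore_plus_access_resistance(gb, ap, hp),
        access_resistance_one_sided(gb, ap),
        continuum_pore_conductance(c, ion.mobility, math.pi * ap**2, hp, ion.valence),
        continuum_permeability(D, hp),
    ]
    vb, vb_kbt = bulk_voltage_drop(voltage, ap, gb, gp, hp, conditions.temperature)
    out.append(TransportEstimate(vb_kbt, "kBT", "bulk_voltage_drop_kBT",
                                 dict(voltage=voltage, ap=ap, gamma_b=gb,
                                      gamma_p=gp, hp=hp)))
    return out
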
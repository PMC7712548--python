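"""Shared domain types: solution conditions, ion species, pore geometry and
pore charges, plus configuration-file loading.

All types are frozen-by-convention dataclasses validated on construction.
Validation errors always name the offending field so that malformed
configuration files produce actionable messages.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import constants as K


class ConfigError(ValueError):
    """Raised when a configuration value violates a physical invariant."""


@dataclass
class Conditions:
    """Bulk electrolyte conditions.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.
    concentration : float
        Salt concentration in mol/L (1:1 electrolyte assumed).
    bulk_resistivity : float
        Bulk resistivity gamma_b in ohm*m (0.071 ohm*m for 1 mol/L KCl in
        rigid TIP3P water).
    relative_permittivity : float
        Bulk relative permittivity of the solvent.
    """

    temperature: float = K.DEFAULT_TEMPERATURE
    concentration: float = 1.0
    bulk_resistivity: float = 0.071
    relative_permittivity: float = 78.4

    def __post_init__(self):
        if self.temperature <= 0:
            raise ConfigError(f"temperature must be > 0 K, got {self.temperature}")
        if self.concentration < 0:
            raise ConfigError(f"concentration must be >= 0 mol/L, got {self.concentration}")
        if self.bulk_resistivity <= 0:
            raise ConfigError(
                f"bulk_resistivity must be > 0 ohm*m, got {self.bulk_resistivity}"
            )
        if self.relative_permittivity <= 0:
            raise ConfigError(
                f"relative_permittivity must be > 0, got {self.relative_permittivity}"
            )

    @property
    def kbt_joules(self) -> float:
        return K.kbt_joules(self.temperature)

    @property
    def thermal_voltage(self) -> float:
        """kB*T/e in volts."""
        return K.thermal_voltage(self.temperature)

    @property
    def concentration_per_nm3(self) -> float:
        """Cation number density in ions/nm^3."""
        return K.molar_to_per_nm3(self.concentration)

    def debye_length(self) -> float:
        """Debye screening length in nm for a 1:1 electrolyte.

        lambda_D = sqrt(eps0*eps_r*kBT / (2*NA*e^2*c)); approximately
        0.30 nm at 1 mol/L and room temperature.  Scales as 1/sqrt(c).
        """
        if self.concentration <= 0:
            raise ConfigError(
                "concentration must be > 0 for a finite Debye length "
                f"(got {self.concentration} mol/L; screening length diverges)"
            )
        n_per_m3 = self.concentration * 1e3 * K.N_AVOGADRO  # ions/m^3 per species
        lam = math.sqrt(
            K.EPS0 * self.relative_permittivity * self.kbt_joules
            / (2.0 * n_per_m3 * K.E_CHARGE**2)
        )
        return lam / K.NM


@dataclass
class HydrationLayer:
    """One hydration shell: radius (nm), energy (kBT) and the O(1) non-linear
    response factor eta."""

    radius: float
    energy: float
    eta: float = 1.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigError(f"hydration layer radius must be > 0 nm, got {self.radius}")


@dataclass
class IonSpecies:
    """A permeant ion.

    Mobility and diffusion coefficient are tied by the Einstein relation
    D = mu*kBT/q; supply either one (the other is derived) or both
    (checked to 1e-10 relative).
    """

    name: str = "K+"
    valence: int = 1
    mobility: Optional[float] = None  # m^2/(V s)
    diffusion: Optional[float] = None  # m^2/s
    vdw_radius: float = 0.138  # nm
    hydration_layers: list[HydrationLayer] = field(default_factory=list)
    temperature: float = K.DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.valence == 0:
            raise ConfigError("valence must be non-zero")
        vt = K.thermal_voltage(self.temperature) / abs(self.valence)
        if self.mobility is None and self.diffusion is None:
            raise ConfigError("one of mobility or diffusion must be supplied")
        if self.diffusion is None:
            self.diffusion = self.mobility * vt
        elif self.mobility is None:
            self.mobility = self.diffusion / vt
        else:
            expected = self.mobility * vt
            if abs(expected - self.diffusion) > 1e-10 * max(abs(self.diffusion), 1e-300):
                raise ConfigError(
                    "mobility and diffusion violate the Einstein relation: "
                    f"mu*kBT/q = {expected:g} m^2/s but diffusion = {self.diffusion:g} m^2/s"
                )
        radii = [h.radius for h in self.hydration_layers]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ConfigError(
                f"hydration_layers radii must be strictly increasing, got {radii}"
            )

    @property
    def diffusion_nm2_per_ns(self) -> float:
        return K.diffusion_si_to_nm2_per_ns(self.diffusion)

    @property
    def mobility_nm2_per_vns(self) -> float:
        return K.mobility_si_to_nm2_per_vns(self.mobility)

    @classmethod
    def potassium(cls, temperature: float = K.DEFAULT_TEMPERATURE) -> "IonSpecies":
        """K+ with the TIP3P-water mobility 7.62e-8 m^2/(V s).

        The two hydration shells sit near 0.33 nm and 0.55 nm; the shell
        energies are order-of-magnitude defaults for the landscape model
        (the dehydration barrier of a sub-nanometre pore is a few kBT to
        ~10 kBT) and are meant to be overridden from a configuration file
        when better values are known.
        """
        return cls(
            name="K+",
            valence=1,
            mobility=7.62e-8,
            vdw_radius=0.138,
            hydration_layers=[
                HydrationLayer(radius=0.33, energy=6.0, eta=1.0),
                HydrationLayer(radius=0.55, energy=2.0, eta=1.0),
            ],
            temperature=temperature,
        )


@dataclass
class PoreGeometry:
    """Crown-ether pore geometry and its linear strain response.

    Lengths in nm; strain in percent.  ``nominal_radius_0`` is measured from
    the pore centre to the oxygen centres at 0% strain and grows by
    ``strain_coefficient`` per percent strain (7.5 pm/% by default).
    """

    nominal_radius_0: float = 0.29
    strain_coefficient: float = 0.0075  # nm per % strain
    oxygen_vdw_radius: float = 0.152
    effective_radius: float = 0.1  # a_p
    effective_length: float = 1.0  # h_p
    internal_site_length: float = 0.4  # Delta_p
    staging_spread: float = 0.1  # r_s
    crossing_spread: float = 0.02  # r_c
    abf_radius: float = 0.28  # r_ABF
    carbon_vdw_radius: float = 0.17  # membrane slab half-thickness

    def __post_init__(self):
        for name in ("nominal_radius_0", "oxygen_vdw_radius", "effective_radius",
                     "effective_length", "internal_site_length", "staging_spread",
                     "crossing_spread", "abf_radius", "carbon_vdw_radius"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for s in (0.0, 10.0):
            if self.geometric_radius(s) <= 0:
                raise ConfigError(
                    "geometric_radius must stay positive over 0-10% strain; "
                    f"at {s}% it is {self.geometric_radius(s):g} nm "
                    "(check nominal_radius_0 vs oxygen_vdw_radius)"
                )
        if not (self.crossing_spread <= self.staging_spread <= self.effective_radius):
            warnings.warn(
                "expected ordering crossing_spread <= staging_spread <= "
                f"effective_radius, got {self.crossing_spread}, "
                f"{self.staging_spread}, {self.effective_radius}",
                stacklevel=2,
            )

    def nominal_radius(self, strain_percent: float) -> float:
        """Pore-centre-to-oxygen-centre radius at the given % strain.

        Linear in strain: 0.29 nm unstrained, about 0.37 nm at 10%.
        """
        if strain_percent < 0:
            raise ValueError(f"strain must be >= 0 %, got {strain_percent}")
        return self.nominal_radius_0 + strain_percent * self.strain_coefficient

    def geometric_radius(self, strain_percent: float = 0.0) -> float:
        """Nominal radius minus the oxygen van der Waals radius (0.137 nm
        unstrained)."""
        return self.nominal_radius(strain_percent) - self.oxygen_vdw_radius


@dataclass
class ChargeGroup:
    """A ring of ``count`` identical point charges at fixed radial and axial
    position (nm), charge in units of e."""

    charge: float
    count: int
    radial_position: float
    axial_position: float = 0.0

    def __post_init__(self):
        if self.count < 1:
            raise ConfigError(f"charge group count must be >= 1, got {self.count}")
        if self.radial_position < 0:
            raise ConfigError(
                f"radial_position must be >= 0 nm, got {self.radial_position}"
            )


@dataclass
class PoreChargeSet:
    """The set of partial charges decorating the pore rim."""

    groups: list[ChargeGroup] = field(default_factory=list)

    @property
    def total_charge(self) -> float:
        """Net charge in units of e."""
        return sum(g.charge * g.count for g in self.groups)

    @classmethod
    def crown_ether(cls, q_oxygen: float = -0.54,
                    oxygen_radius: float = 0.29,
                    carbon_radius: float = 0.42) -> "PoreChargeSet":
        """The 18-crown-6 rim: 6 oxygens at charge qO and the 12 adjacent
        carbons at -qO/2, so the rim is net neutral."""
        return cls(groups=[
            ChargeGroup(charge=q_oxygen, count=6, radial_position=oxygen_radius),
            ChargeGroup(charge=-q_oxygen / 2.0, count=12, radial_position=carbon_radius),
        ])


# ---------------------------------------------------------------------------
# configuration files


@dataclass
class SystemConfig:
    """Everything needed to run the analysis pipeline on one pore system."""

    conditions: Conditions = field(default_factory=Conditions)
    ion: IonSpecies = field(default_factory=IonSpecies.potassium)
    geometry: PoreGeometry = field(default_factory=PoreGeometry)
    charges: PoreChargeSet = field(default_factory=PoreChargeSet.crown_ether)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTION_TYPES = {
    "conditions": Conditions,
    "geometry": PoreGeometry,
}


def _build_ion(d: dict) -> IonSpecies:
    d = dict(d)
    layers = [HydrationLayer(**h) for h in d.pop("hydration_layers", [])]
    try:
        return IonSpecies(hydration_layers=layers, **d)
    except TypeError as exc:
        raise ConfigError(f"ion: {exc}") from None


def _build_charges(d: dict) -> PoreChargeSet:
    try:
        return PoreChargeSet(groups=[ChargeGroup(**g) for g in d.get("groups", [])])
    except TypeError as exc:
        raise ConfigError(f"charges: {exc}") from None


def config_from_dict(data: dict) -> SystemConfig:
    """Build a :class:`SystemConfig` from a nested dict, using defaults for
    missing sections and raising :class:`ConfigError` naming unknown fields."""
    known = {"conditions", "ion", "geometry", "charges"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration section(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            try:
                kwargs[name] = cls(**data[name])
            except TypeError as exc:
                raise ConfigError(f"{name}: {exc}") from None
    if "ion" in data:
        kwargs["ion"] = _build_ion(data["ion"])
    if "charges" in data:
        kwargs["charges"] = _build_charges(data["charges"])
    return SystemConfig(**kwargs)


def load_config(path: str | Path) -> SystemConfig:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def save_config(config: SystemConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
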
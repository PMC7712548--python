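"""Construction and analysis of 1D free-energy profiles along the pore axis.

A profile F(z) (in kBT, z in nm) for an ion crossing an atomically thin pore
is shaped by two competing contributions: the dehydration penalty of
stripping water shells inside the constriction, and the electrostatic
interaction with the partial charges on the pore rim.  This module provides

* a geometric dehydration + screened-Coulomb model of the profile,
* voltage tilting (the applied bias drops over a ~1 nm slab around the pore),
* discrete-gradient feature analysis that pairs each local minimum with the
  next maximum in the transport direction and asks whether the applied field
  can wash the barrier out, and
* closed-form entropic penalties for confining an ion from bulk into a
  sampling cylinder, the crossing region, or a binding well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .core import Conditions, IonSpecies, PoreGeometry, PoreChargeSet
from . import constants as K


@dataclass
class FreeEnergyProfile:
    """1D free-energy profile: grid z (nm, strictly increasing), F (kBT) and
    optional per-point standard error (kBT)."""

    z: np.ndarray
    F: np.ndarray
    se: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.z.ndim != 1 or self.F.shape != self.z.shape:
            raise ValueError("z and F must be 1D arrays of equal length")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("F must be finite")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.z.shape:
                raise ValueError("se must match the z grid")

    def __len__(self) -> int:
        return len(self.z)

    def interp(self, z: np.ndarray) -> np.ndarray:
        return np.interp(z, self.z, self.F)


@dataclass
class LandscapeFeature:
    """A (minimum, next maximum) pair in the positive-z direction."""

    min_position: float
    min_value: float
    max_position: float
    max_value: float

    def __post_init__(self):
        if self.max_position <= self.min_position:
            raise ValueError("feature must run in the positive-z direction")

    @property
    def gradient(self) -> float:
        """(F_max - F_min)/(z_max - z_min) in kBT/nm; >= 0 for a true
        min->max pair."""
        return (self.max_value - self.min_value) / (self.max_position - self.min_position)

    @property
    def mean_position(self) -> float:
        return 0.5 * (self.min_position + self.max_position)


# ---------------------------------------------------------------------------
# dehydration + electrostatics model


def dehydration_fraction(z: float, layer_radius: float,
                         geometry: PoreGeometry,
                         pore_radius: Optional[float] = None) -> float:
    """Fraction of a hydration shell excluded by the membrane.

    The membrane is modelled as a slab of half-thickness equal to the carbon
    van der Waals radius, pierced by a cylindrical opening of the geometric
    pore radius.  The hydration shell is the thin sphere of radius
    ``layer_radius`` centred on the ion at axial position ``z``; the excluded
    fraction is the part of that sphere inside the slab but outside the
    opening.  Because the area of a spherical zone depends only on its
    height, the fraction has the closed form of an interval-length ratio.
    """
    if layer_radius <= 0:
        raise ValueError(f"layer_radius must be > 0, got {layer_radius}")
    rp = geometry.geometric_radius() if pore_radius is None else pore_radius
    half = geometry.carbon_vdw_radius
    R = layer_radius
    lo = max(-half, z - R)
    hi = min(half, z + R)
    if hi <= lo:
        return 0.0
    if R <= rp:
        return 0.0  # shell fits entirely through the opening
    d = math.sqrt(R * R - rp * rp)  # |z'-z| < d means outside the cylinder
    lo = max(lo, z - d)
    hi = min(hi, z + d)
    if hi <= lo:
        return 0.0
    return (hi - lo) / (2.0 * R)


def _effective_permittivity(r: np.ndarray, eps_pore: float, eps_bulk: float,
                            r_inner: float, r_outer: float) -> np.ndarray:
    """Distance-dependent permittivity: eps_pore at contact (no intervening
    water, r <= r_inner), bulk beyond full hydration (r >= r_outer), linear
    in between.  The true form is not known; only the endpoints are."""
    t = np.clip((r - r_inner) / max(r_outer - r_inner, 1e-12), 0.0, 1.0)
    return eps_pore + (eps_bulk - eps_pore) * t


def model_free_energy(z, ion: IonSpecies, pore_charges: PoreChargeSet,
                      geometry: PoreGeometry,
                      eps_pore: float = 4.0,
                      conditions: Optional[Conditions] = None,
                      strain_percent: float = 0.0) -> np.ndarray:
    """Dehydration + electrostatics estimate of the free energy, in kBT.

    F(z) = sum_i eta_i * f_i(z) * E_i  +  sum_groups q*q'*n' / (4 pi eps0 eps(r) r)

    with f_i the geometric shell-exclusion fraction and eps(r) switching from
    ``eps_pore`` (around 4 inside the dry pore) to the bulk value once the
    ion-charge distance exceeds the second hydration shell.  Far from the
    membrane both terms vanish within screening, so |F| < 1 kBT beyond ~1 nm.
    """
    if eps_pore <= 0:
        raise ValueError(f"eps_pore must be > 0, got {eps_pore}")
    cond = conditions or Conditions(temperature=ion.temperature)
    z = np.atleast_1d(np.asarray(z, dtype=float))
    rp = geometry.geometric_radius(strain_percent)

    out = np.zeros_like(z)
    for layer in ion.hydration_layers:
        frac = np.array([dehydration_fraction(zi, layer.radius, geometry, rp)
                         for zi in z])
        out += layer.eta * frac * layer.energy

    radii = [h.radius for h in ion.hydration_layers]
    r_inner = radii[0] if radii else 0.3
    r_outer = radii[-1] if len(radii) > 1 else 2 * r_inner
    coul = K.coulomb_kbt_nm(cond.temperature)
    for g in pore_charges.groups:
        r = np.sqrt((z - g.axial_position) ** 2 + g.radial_position ** 2)
        if np.any(r == 0):
            raise ValueError(
                f"ion coincides with charge group at radial_position="
                f"{g.radial_position}, axial_position={g.axial_position}"
            )
        eps = _effective_permittivity(r, eps_pore, cond.relative_permittivity,
                                      r_inner, r_outer)
        out += coul * ion.valence * g.charge * g.count / (eps * r)
    return out


# ---------------------------------------------------------------------------
# voltage tilt


def tilt_profile(profile: FreeEnergyProfile, v_ext: float,
                 drop_halfwidth: float = 0.5,
                 valence: int = 1,
                 temperature: float = K.DEFAULT_TEMPERATURE) -> FreeEnergyProfile:
    """Apply an external bias to a profile.

    The potential drop is localized: lambda(z) ramps linearly from 0 at
    z <= -w to 1 at z >= +w (w = ``drop_halfwidth``, default 0.5 nm, over
    which the applied field is ideally ~10 kBT/nm at 0.25 V).  For a cation
    driven toward +z the energy q*V*lambda(z) is subtracted, so the total
    drop across the profile is exactly q*V.
    """
    if drop_halfwidth <= 0:
        raise ValueError(f"drop_halfwidth must be > 0, got {drop_halfwidth}")
    lam = np.clip((profile.z + drop_halfwidth) / (2.0 * drop_halfwidth), 0.0, 1.0)
    vt = K.thermal_voltage(temperature)
    F = profile.F - valence * v_ext / vt * lam
    meta = dict(profile.metadata)
    meta["applied_voltage"] = meta.get("applied_voltage", 0.0) + v_ext
    return FreeEnergyProfile(z=profile.z.copy(), F=F, se=None if profile.se is None
                             else profile.se.copy(), metadata=meta)


# ---------------------------------------------------------------------------
# discrete-gradient feature analysis


def _smooth(F: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return F
    kernel = np.ones(window) / window
    pad = window // 2
    Fp = np.pad(F, pad, mode="edge")
    out = np.convolve(Fp, kernel, mode="same")
    return out[pad:len(Fp) - pad] if pad else out


def discrete_gradients(profile: FreeEnergyProfile,
                       smooth_window: int = 3,
                       min_prominence: float = 0.5) -> list[LandscapeFeature]:
    """Pair every local minimum with the next local maximum at larger z.

    Gradients in the negative-z direction (max before min) assist rather
    than hinder a +z-moving ion and are not reported; minima with no
    subsequent maximum are dropped.  Profiles are lightly smoothed
    (moving average, default 3 points) and extrema below 0.5 kBT prominence
    discarded, since sampled profiles carry per-point noise of that order.
    A monotone profile yields an empty list.
    """
    if len(profile) < 3:
        raise ValueError("profile needs at least 3 points")
    F = _smooth(profile.F, smooth_window)
    z = profile.z
    maxima, _ = find_peaks(F, prominence=min_prominence)
    minima, _ = find_peaks(-F, prominence=min_prominence)
    # endpoints can act as minima for features climbing out of the edges
    features: list[LandscapeFeature] = []
    for i in minima:
        later = maxima[maxima > i]
        if len(later) == 0:
            continue
        j = later[0]
        features.append(LandscapeFeature(
            min_position=z[i], min_value=F[i],
            max_position=z[j], max_value=F[j]))
    return features


@dataclass
class FeatureLabel:
    feature: LandscapeFeature
    label: str  # washed_out | reduced | irrelevant | unmatched
    matched: Optional[LandscapeFeature] = None


def classify_feature_relevance(features_eq: Sequence[LandscapeFeature],
                               features_biased: Sequence[LandscapeFeature],
                               v_ext: float,
                               drop_halfwidth: float = 0.5,
                               valence: int = 1,
                               temperature: float = K.DEFAULT_TEMPERATURE,
                               match_tolerance: float = 0.1,
                               change_tolerance: float = 0.1) -> list[FeatureLabel]:
    """Label equilibrium features by how the applied bias changed them.

    A feature is *washed_out* if it disappears (or its gradient is driven
    to <= 0) under bias; *reduced* if its gradient dropped by more than the
    fraction the ideal field q*V/(2w) would account for; *irrelevant* if its
    gradient is essentially unchanged (within ``change_tolerance``) even
    though the ideal field should have mattered -- such features are not
    rate limiting, so no self-consistent potential drop develops across
    them.  Features larger than the ideal field (e.g. ~40 kBT/nm against
    ~10 kBT/nm at 0.25 V) survive and stay labelled *reduced*.
    """
    vt = K.thermal_voltage(temperature)
    ideal_field = abs(valence) * abs(v_ext) / vt / (2.0 * drop_halfwidth)  # kBT/nm
    out: list[FeatureLabel] = []
    biased = list(features_biased)
    for feq in features_eq:
        match = None
        if biased:
            dists = [abs(fb.mean_position - feq.mean_position) for fb in biased]
            k = int(np.argmin(dists))
            if dists[k] <= match_tolerance:
                match = biased[k]
        if match is None or match.gradient <= 0:
            out.append(FeatureLabel(feq, "washed_out", match))
            continue
        g0, g1 = feq.gradient, match.gradient
        rel_change = (g0 - g1) / g0 if g0 > 0 else 0.0
        expected_rel = min(ideal_field / g0, 1.0) if g0 > 0 else 0.0
        if abs(rel_change) < change_tolerance and expected_rel > change_tolerance:
            out.append(FeatureLabel(feq, "irrelevant", match))
        elif rel_change > change_tolerance:
            out.append(FeatureLabel(feq, "reduced", match))
        else:
            out.append(FeatureLabel(feq, "unchanged", match))
    return out


# ---------------------------------------------------------------------------
# entropic penalties


def constriction_entropy(r_abf: float, l: float) -> float:
    """Free-energy cost (kBT) of confining an ion from a bulk cell of side l
    (the typical inter-ion spacing, ~1.2 nm at 1 mol/L) into a sampling
    cylinder of radius r_abf: -ln(pi r^2 l / l^3) ~ 1.7 kBT for the
    defaults."""
    if r_abf <= 0 or l <= 0:
        raise ValueError("lengths must be positive")
    return -math.log(math.pi * r_abf**2 * l / l**3)


def crossing_entropy(r_c: float, r_abf: float) -> float:
    """Penalty (kBT) to squeeze from the sampling cylinder (radius r_abf)
    into the narrow crossing region (radius r_c): -ln(r_c^2/r_abf^2)."""
    if r_c <= 0 or r_abf <= 0:
        raise ValueError("lengths must be positive")
    return -math.log(r_c**2 / r_abf**2)


def well_entropy(l_well: float, l: float) -> float:
    """Penalty (kBT) for localization into a binding well of axial size
    l_well out of a bulk spacing l: -ln(l_well/l)."""
    if l_well <= 0 or l <= 0:
        raise ValueError("lengths must be positive")
    return -math.log(l_well / l)
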
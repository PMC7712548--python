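"""Synthetic measurement tables and free-energy profiles.

MD observables for this system are (i) ion-counting currents with standard
errors from a handful of parallel runs, (ii) pore-site occupancies P2 that
decay with strain and voltage, and (iii) 1D free-energy profiles with a
central well or barrier plus satellite features.  This module generates all
three from a ground-truth :class:`~crownpore.kinetics.RateSet`, so the whole
fitting pipeline can be exercised end to end with known answers.

Counting noise is produced by an event-driven two-state occupancy process
(pore filled/empty) whose stationary occupancy and emptying-event rate equal
the model's deterministic values at each design point -- currents really are
event counts over finite runs, and the occupancy estimate is a time average
over the same event train, so the two observables carry correlated,
realistically sized errors.  A fast Gaussian mode is retained as an option.  Default truth parameters are the fitted values for the
strongly-charged (qO = -0.54e) pore: kb0 = 0.5/ns, kappa_b = 2.2/(V ns),
ktilde_a = 12/ns and the combined dissociation law
kd = 3.2 * V * exp(0.043*qV/kBT + 0.22*s) ns^-1, which reproduces the
characteristic current plateau versus strain and the occupancy collapse.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import constants as K
from .core import Conditions
from .kinetics import RateSet, steady_state_chain
from .landscape import FreeEnergyProfile, tilt_profile
from .fitting import MeasurementTable


@dataclass
class KdLaw:
    """Dissociation-rate law of the internal site, ns^-1:

        kd(s, V) = B * V * exp(b*V/VT + c*s) * exp(-Uw(s, V))

    The first factor is the plateau law (the field drives ions across the
    site, with small barrier shifts linear in voltage and strain).  Uw is
    the residual exit-well depth of the unstrained, weakly biased pore,

        Uw(s, V) = well_depth * max(0, 1 - s/well_strain_scale)
                               * max(0, 1 - V/well_voltage_scale),

    which produces the blocked-pore regime (occupancy ~ 1, current limited
    by dissociation) at small strain and voltage and fades on the plateau.
    The default depth and scales are set so the effective open-pore rate is
    ~0.012/ns at (0%, 0.1 V) and ~0.25/ns at (0%, 0.25 V), the magnitudes
    characteristic of an electrostatically stabilized well; set
    well_depth = 0 for the bare plateau law.
    """

    B: float = 3.2  # 1/(V ns)
    b: float = 0.043  # per unit qV/kBT
    c: float = 0.22  # per % strain
    well_depth: float = 4.0  # kBT
    well_strain_scale: float = 4.0  # %
    well_voltage_scale: float = 0.6  # V
    thermal_voltage: float = K.thermal_voltage(K.DEFAULT_TEMPERATURE)  # V

    def __call__(self, strain: float, voltage: float) -> float:
        plateau = self.B * voltage * math.exp(self.b * voltage / self.thermal_voltage
                                              + self.c * strain)
        uw = self.well_depth * max(0.0, 1.0 - strain / self.well_strain_scale) \
            * max(0.0, 1.0 - voltage / self.well_voltage_scale)
        return plateau * math.exp(-uw)

    @classmethod
    def exponential_in_strain(cls, prefactor: float, exponent: float,
                              voltage: float) -> "KdLaw":
        """A per-voltage law kd = prefactor*exp(exponent*s) pinned at one
        voltage (e.g. 20 ns^-1 and 0.20/% at 1 V); no well term."""
        return cls(B=prefactor / voltage, b=0.0, c=exponent, well_depth=0.0)


@dataclass
class GeneratorSpec:
    """Study design for a synthetic measurement campaign.

    Defaults mirror the simulated campaign the model was built for: strains
    0-10% in 2% steps, voltages {0.1, 0.25, 0.5, 1.0} V, five parallel runs
    per point with 50-100 ns each (250-500 ns total).
    """

    truth: RateSet = field(default_factory=lambda: RateSet(
        kb0=0.5, kappa_b=2.2, ktilde_a=12.0))
    kd_law: KdLaw = field(default_factory=KdLaw)
    strains: tuple = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    voltages: tuple = (0.1, 0.25, 0.5, 1.0)
    n_runs: int = 5
    run_length: float = 100.0  # ns per replica
    q_oxygen: float = -0.54
    noise: str = "counting"  # counting | gaussian | none
    gaussian_rel_se: float = 0.1  # only for the gaussian mode

    def __post_init__(self):
        if not self.strains or not self.voltages:
            raise ValueError("strain and voltage grids must be non-empty")
        if self.n_runs < 2 and self.noise == "counting":
            raise ValueError("counting noise needs >= 2 runs for an SE")
        if self.run_length <= 0:
            raise ValueError("run_length must be > 0 ns")


def _chain_for_point(spec: GeneratorSpec, strain: float, voltage: float) -> RateSet:
    """Materialize a concrete 3-site chain whose reduced parameters equal
    the truth: no staging back-flow (so ktilde_a = ka) and a fast exit side
    (site 3 practically empty)."""
    kd = spec.kd_law(strain, voltage)
    return RateSet(kb=spec.truth.kb_at(voltage), kb_out=0.0,
                   ka=spec.truth.effective_association(voltage),
                   kd=kd, kexit_in=0.0, kexit_out=1000.0 * kd if kd > 0 else 1.0)


def expected_point(spec: GeneratorSpec, strain: float, voltage: float):
    """Noise-free model current and occupancy at one design point."""
    state = steady_state_chain(_chain_for_point(spec, strain, voltage))
    return state.current, state.P2


def _occupancy_event_train(current: float, p2: float, t_end: float, rng):
    """One replica of the filled/empty renewal process.

    The pore alternates between occupied (emptying at koff = I/P2, each
    emptying being one counted translocation) and empty (refilling at
    kon = I/(1-P2)); the stationary occupancy is then exactly ``p2`` and
    the event rate exactly ``current``.  Returns (measured current,
    time-averaged occupancy) over a window of ``t_end`` ns.
    """
    kon = current / (1.0 - p2)
    koff = current / p2
    occupied = bool(rng.random() < p2)
    t = on_time = 0.0
    count = 0
    while True:
        tau = rng.exponential(1.0 / (koff if occupied else kon))
        if t + tau >= t_end:
            if occupied:
                on_time += t_end - t
            break
        if occupied:
            on_time += tau
            count += 1
        occupied = not occupied
        t += tau
    return count / t_end, on_time / t_end


def generate_measurements(spec: GeneratorSpec, seed: int) -> MeasurementTable:
    """Simulate the measurement campaign.

    Each (strain, voltage) point runs ``n_runs`` independent replicas of the
    event-driven occupancy process for ``run_length`` ns; the reported
    current is the mean translocation count rate and the occupancy the mean
    time-averaged P2, each with SE = sqrt(var/n_runs).  ``noise='none'`` returns the
    deterministic steady-state values with zero SEs; ``noise='gaussian'``
    perturbs them with a fixed relative SE instead of running the chain.

    Output tables are byte-for-byte reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    min_expected = math.inf
    for s in spec.strains:
        for v in spec.voltages:
            chain = _chain_for_point(spec, s, v)
            if spec.noise == "none":
                cur, p2 = expected_point(spec, s, v)
                cur_se = p2_se = 0.0
            elif spec.noise == "gaussian":
                cur0, p20 = expected_point(spec, s, v)
                cur_se = spec.gaussian_rel_se * cur0
                p2_se = spec.gaussian_rel_se * max(p20, 1e-3)
                cur = max(rng.normal(cur0, cur_se), 1e-12)
                p2 = float(np.clip(rng.normal(p20, p2_se), 1e-6, 1.0))
            else:
                cur0, p20 = expected_point(spec, s, v)
                reps = np.array([_occupancy_event_train(cur0, p20,
                                                        spec.run_length, rng)
                                 for _ in range(spec.n_runs)])
                cur = float(reps[:, 0].mean())
                cur_se = float(reps[:, 0].std(ddof=1) / math.sqrt(spec.n_runs))
                p2 = float(reps[:, 1].mean())
                p2_se = float(reps[:, 1].std(ddof=1) / math.sqrt(spec.n_runs))
                min_expected = min(min_expected, cur0 * spec.run_length)
            rows.append(dict(strain=s, voltage=v, current=cur,
                             current_se=cur_se, p2=p2, p2_se=p2_se,
                             qo=spec.q_oxygen, n_runs=spec.n_runs))
    if spec.noise == "counting" and min_expected < 1.0:
        warnings.warn(
            f"fewest expected translocations per replica is {min_expected:.2f}; "
            "currents at that point are dominated by counting noise",
            stacklevel=2)
    return MeasurementTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# free-energy profiles


@dataclass
class ProfileSpec:
    """Parameterized landscape: a central Gaussian feature whose amplitude
    responds to strain, satellite features near |z| ~ 0.35 nm, and optional
    per-point noise at the sampled-SE level.

    For a strongly charged rim (qO ~ -0.54e) the centre is a well that
    flattens with strain while a dehydration barrier grows; a weakly
    charged rim (qO ~ -0.24e) starts out barrier-dominated.
    """

    central_well_depth: float = 6.0  # kBT at 0% strain (well if rim charge strong)
    well_flattening_strain: float = 8.0  # % strain at which the well is gone
    central_barrier_0: float = 0.5  # kBT dehydration barrier at 0% strain
    central_barrier_slope: float = 0.25  # kBT per % strain
    central_width: float = 0.1  # nm
    satellite_positions: tuple = (-0.35, 0.35)  # nm
    satellite_amplitudes: tuple = (2.5, 2.0)  # kBT barriers
    satellite_width: float = 0.08  # nm
    se_level: float = 0.3  # kBT per point
    z_range: tuple = (-1.5, 1.5)
    n_points: int = 121


def _central_amplitude(spec: ProfileSpec, strain: float, q_oxygen: float) -> float:
    barrier = spec.central_barrier_0 + spec.central_barrier_slope * strain
    if q_oxygen <= -0.4:  # electrostatics beats dehydration: a well
        well = -spec.central_well_depth * max(0.0, 1.0 - strain / spec.well_flattening_strain)
        return well + barrier
    return spec.central_well_depth * 0.5 + barrier  # barrier-dominated pore


def generate_profile(spec: ProfileSpec, strain: float, q_oxygen: float,
                     v_ext: float = 0.0, seed: Optional[int] = None,
                     conditions: Optional[Conditions] = None) -> FreeEnergyProfile:
    """Sum-of-Gaussians landscape with strain- and charge-dependent centre,
    optional voltage tilt and seeded Gaussian noise at the SE level."""
    cond = conditions or Conditions()
    z = np.linspace(*spec.z_range, spec.n_points)
    F = np.zeros_like(z)
    amp = _central_amplitude(spec, strain, q_oxygen)
    F += amp * np.exp(-z**2 / (2 * spec.central_width**2))
    for pos, a in zip(spec.satellite_positions, spec.satellite_amplitudes):
        F += a * np.exp(-(z - pos) ** 2 / (2 * spec.satellite_width**2))
    se = np.full_like(z, spec.se_level)
    if seed is not None and spec.se_level > 0:
        F = F + np.random.default_rng(seed).normal(0.0, spec.se_level, z.shape)
    prof = FreeEnergyProfile(z=z, F=F, se=se,
                             metadata={"strain": strain, "q_oxygen": q_oxygen,
                                       "applied_voltage": 0.0})
    if v_ext:
        prof = tilt_profile(prof, v_ext, temperature=cond.temperature)
    return prof
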
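"""Transport-regime classification: when is the current limited by the
barrier landscape, by bulk diffusion, or dominated by drift feeding?

Diffusion-limited currents need ions to spend little time in the pore and
bulk drift to be a minor supply channel.  In rate language that is the chain
of inequalities  kb << ktilde_a << kd  plus the access-drop condition
q*Vb << kBT, which together bound the usable voltage to a window

    Theta*kBT*c*ap*hp^2/q  <<  qV  <<  Theta*kBT*hp/(pi*ap*q)

-- roughly 6 mV to 300 mV for the default crown-ether pore.  "Much less
than" is operationalized as a configurable margin factor (default 3x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import constants as K
from .core import Conditions, PoreGeometry
from .kinetics import RateSet
from .rates import capture_rate, drift_feed_coefficient, bulk_voltage_drop

DEFAULT_MARGIN = 1.0 / 3.0


@dataclass
class VoltageWindow:
    v_min: float  # volts
    v_max: float
    has_window: bool


def diffusion_window(theta: float, conditions: Conditions,
                     geometry: PoreGeometry) -> VoltageWindow:
    """Voltage window for diffusion-limited transport.

    Lower bound: the barrierless exit rate must beat diffusive feeding
    (ions removed fast enough to sustain a concentration gradient).  Upper
    bound: drift feeding must stay below diffusive feeding (little voltage
    drop in bulk).  Theta cancels in the ratio v_max/v_min =
    1/(pi*c*ap^2*hp).
    """
    kbt = conditions.kbt_joules
    c_si = conditions.concentration_per_nm3 / K.NM**3
    ap, hp = geometry.effective_radius * K.NM, geometry.effective_length * K.NM
    v_min = theta * kbt * c_si * ap * hp**2 / K.E_CHARGE
    v_max = theta * kbt * hp / (math.pi * ap * K.E_CHARGE)
    return VoltageWindow(v_min=v_min, v_max=v_max, has_window=v_min < v_max)


@dataclass
class InequalityMargins:
    kb_over_ka: float
    ka_over_kd: float
    diffusion_limited: bool
    degenerate: bool = False


def chain_inequality_margins(kb: float, ktilde_a: float, kd: float,
                             margin: float = DEFAULT_MARGIN) -> InequalityMargins:
    """Margins of kb << ktilde_a << kd.

    Both ratios below ``margin`` flags the point diffusion-limited.  Zero
    denominators give +inf margins and a degenerate flag; kb = 0 satisfies
    the chain trivially but is also flagged degenerate.
    """
    if min(kb, ktilde_a, kd) < 0:
        raise ValueError("rates must be >= 0")
    m1 = kb / ktilde_a if ktilde_a > 0 else math.inf
    m2 = ktilde_a / kd if kd > 0 else math.inf
    degenerate = (kb == 0) or math.isinf(m1) or math.isinf(m2)
    return InequalityMargins(m1, m2, bool(m1 < margin and m2 < margin), degenerate)


@dataclass
class DriftDiffusionBalance:
    drift_rate: float  # kappa_b * V, ns^-1
    diffusive_rate: float  # kb0, ns^-1
    ratio: float  # drift / diffusion
    vb_over_kbt: float  # q*Vb/kBT
    diffusion_dominant: bool


def drift_vs_diffusion(voltage: float, conditions: Conditions,
                       geometry: PoreGeometry, D: float,
                       theta: float = 4.0, gamma_p: float | None = None,
                       kb0: float | None = None, kappa_b: float | None = None,
                       margin: float = DEFAULT_MARGIN) -> DriftDiffusionBalance:
    """Compare the drift-fed and diffusive supply rates at a voltage.

    ``kb0`` and ``kappa_b`` (ns^-1 and 1/(V ns)) default to the geometric
    estimates but can be overridden with fitted values.  With the fitted
    feed parameters of the crown-ether pore, diffusion (0.5/ns) beats drift
    (~0.22/ns) by more than 2x at 0.1 V, and the two are comparable near
    0.25 V.  The crossover voltage (ratio = 1) is kb0/kappa_b exactly.
    """
    gp = 2.0 * conditions.bulk_resistivity if gamma_p is None else gamma_p
    ap, hp = geometry.effective_radius, geometry.effective_length
    if kb0 is None:
        kb0 = capture_rate(theta, D, conditions.concentration_per_nm3, ap).value
    kappa = (drift_feed_coefficient(ap, gp, hp).value
             if kappa_b is None else kappa_b)
    drift = kappa * voltage
    _, vb_kbt = bulk_voltage_drop(voltage, ap, conditions.bulk_resistivity,
                                  gp, hp, conditions.temperature)
    ratio = drift / kb0 if kb0 > 0 else math.inf
    return DriftDiffusionBalance(drift, kb0, ratio, vb_kbt,
                                 bool(ratio < margin and vb_kbt < 1.0))


def crossover_voltage(kb0: float, kappa_b: float) -> float:
    """Voltage at which drift feeding equals diffusive feeding: kb0/kappa_b."""
    if kappa_b <= 0:
        raise ValueError("kappa_b must be > 0")
    return kb0 / kappa_b


# ---------------------------------------------------------------------------
# data-driven classification


def conductance_linearity(group: pd.DataFrame, z_crit: float = 1.96) -> str:
    """Classify conductance vs voltage for one strain as superlinear
    (G grows with V: barrier-limited), sublinear (G falls with V:
    diffusion-limited) or ohmic (slope indistinguishable from zero).

    Fits G = I/V against V by weighted least squares with weights from the
    per-point measurement SEs.  Because those SEs are replica-derived
    (known-variance), the slope uncertainty is taken from the propagated
    measurement error, cov = (X^T W X)^{-1}, not from the line's residuals
    -- voltage series this short are curved, and residual-based intervals
    would swamp a clear monotone trend.
    """
    if group["voltage"].nunique() < 2:
        raise ValueError("need at least two voltages per strain to classify")
    V = group["voltage"].to_numpy(dtype=float)
    G = group["current"].to_numpy(dtype=float) / V
    se = group.get("current_se")
    if se is not None and np.all(np.asarray(se) > 0):
        sigma_g = np.asarray(se, dtype=float) / V
    else:
        sigma_g = np.full_like(G, max(np.std(G), 1e-12))
    w = 1.0 / sigma_g**2
    X = sm.add_constant(V)
    fit = sm.WLS(G, X, weights=w).fit()
    slope = fit.params[1]
    cov = np.linalg.inv(X.T @ (w[:, None] * X))  # absolute-sigma covariance
    slope_se = float(np.sqrt(cov[1, 1]))
    if slope > z_crit * slope_se:
        return "superlinear"
    if slope < -z_crit * slope_se:
        return "sublinear"
    return "ohmic"


@dataclass
class RegimePoint:
    strain: float
    voltage: float
    label: str  # diffusion_limited | barrier_limited | intermediate
    kb: float
    open_association: float  # ktilde_a * (1 - P2)
    margins: InequalityMargins = None


@dataclass
class RegimeReport:
    points: list[RegimePoint]
    window: VoltageWindow
    linearity: dict  # strain -> classification

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "strain": p.strain, "voltage": p.voltage, "label": p.label,
            "kb": p.kb, "open_association": p.open_association,
        } for p in self.points])


def classify_regimes(table: pd.DataFrame, rates: RateSet,
                     conditions: Conditions, geometry: PoreGeometry,
                     margin: float = DEFAULT_MARGIN,
                     theta: float = 4.0) -> RegimeReport:
    """Per-(strain, voltage) regime labels from measured occupancies.

    A point is *diffusion_limited* when the bulk feeding rate kb(V) is the
    bottleneck against the open-pore association rate ktilde_a*(1-P2); it
    is *barrier_limited* when the pore term is the bottleneck instead
    (e.g. a blocked pore, P2 -> 1, at small strain and voltage).
    """
    pts = []
    for _, row in table.iterrows():
        kb = rates.kb_at(row["voltage"])
        ktilde = rates.effective_association(row["voltage"])
        open_assoc = ktilde * (1.0 - float(row["p2"]))
        if kb < margin * open_assoc:
            label = "diffusion_limited"
        elif open_assoc < margin * kb:
            label = "barrier_limited"
        else:
            label = "intermediate"
        pts.append(RegimePoint(strain=float(row["strain"]),
                               voltage=float(row["voltage"]), label=label,
                               kb=kb, open_association=open_assoc))
    linearity = {}
    for strain, grp in table.groupby("strain"):
        if grp["voltage"].nunique() >= 2:
            linearity[float(strain)] = conductance_linearity(grp)
    return RegimeReport(points=pts,
                        window=diffusion_window(theta, conditions, geometry),
                        linearity=linearity)
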
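"""Fitting the closed-form chain current to (strain, voltage, current, P2)
measurement tables, and extracting the dissociation rate from occupancy.

The model current is I/q = [1/kb(V) + 1/(ktilde_a*(1-P2))]^{-1} with the
measured pore occupancy P2 inserted directly (this removes the dissociation
side of the chain from the fit entirely).  Three forms of the bulk feeding
rate are supported:

* ``drift_fed``:  kb = kb0 + kappa_b*V     -- diffusion plus drift supply,
* ``activated``:  kb = kb0*exp(beta*V)     -- a weakly activated entrance,
  beta being the barrier reduction in kBT per volt,
* ``drift_only``: kb = kappa_b*V           -- no diffusive component.

On the current plateau the occupancy balance gives kd*P2 = I/q, so kd can
be read off point by point and summarized by exponential-in-strain fits,
kd = A*exp(c*s), and a combined voltage-strain law kd = B*V*exp(b*qV/kBT + c*s).

All least squares are inverse-variance weighted by the per-point standard
errors; rate parameters are fitted in log space to enforce positivity.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from . import constants as K
from .core import Conditions

MODEL_FORMS = ("drift_fed", "activated", "drift_only")

REQUIRED_COLUMNS = ("strain", "voltage", "current", "current_se", "p2", "p2_se")
OPTIONAL_COLUMNS = ("qo", "n_runs")


class TableError(ValueError):
    pass


@dataclass
class MeasurementTable:
    """Rows of (strain %, voltage V, current ions/ns, SE, P2, SE[, qO, n_runs]).

    A thin validated wrapper around a DataFrame; ``data`` is the raw frame.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise TableError(f"measurement table is missing column(s): {missing}")
        if ((df["p2"] < 0) | (df["p2"] > 1)).any():
            raise TableError("p2 values must lie in [0, 1]")
        if (df[["current_se", "p2_se"]] < 0).any().any():
            raise TableError("standard errors must be >= 0")
        keycols = ["strain", "voltage"] + (["qo"] if "qo" in df.columns else [])
        if df.duplicated(subset=keycols).any():
            raise TableError(f"duplicate {tuple(keycols)} keys in measurement table")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path, metadata: Optional[dict] = None) -> None:
        with open(path, "w") as fh:
            for k, v in (metadata or {}).items():
                fh.write(f"# {k}: {v}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementTable":
        lines, meta = [], {}
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                if ":" in line:
                    k, v = line[1:].split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                lines.append(line)
        df = pd.read_csv(io.StringIO("\n".join(lines)))
        table = cls(df)
        table.metadata = meta
        return table

    def interpolate_p2(self, strain: np.ndarray, voltage: float) -> np.ndarray:
        """P2 at intermediate strains by linear interpolation within one
        voltage (the continuous model curve between measured strains)."""
        sub = self.data[self.data["voltage"] == voltage].sort_values("strain")
        if len(sub) < 2:
            raise TableError(f"need >= 2 strains at voltage {voltage} to interpolate")
        return np.interp(strain, sub["strain"], sub["p2"])


@dataclass
class FitResult:
    model: str
    params: dict  # name -> value (rates in ns^-1, kappa_b in 1/(V ns), beta 1/V)
    se: dict  # name -> standard error
    r_squared: float
    r_squared_adj: float
    residuals: np.ndarray  # weighted residuals
    n_obs: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(s < 0 for s in self.se.values()):
            raise ValueError("parameter standard errors must be >= 0")


def _kb_of_voltage(model: str, p: dict, V: np.ndarray) -> np.ndarray:
    if model == "drift_fed":
        return p["kb0"] + p["kappa_b"] * V
    if model == "activated":
        return p["kb0"] * np.exp(p["beta"] * V)
    if model == "drift_only":
        return p["kappa_b"] * V
    raise ValueError(f"unknown model form {model!r}; choose from {MODEL_FORMS}")


def predict_current(model: str, params: dict, voltage: np.ndarray,
                    p2: np.ndarray) -> np.ndarray:
    """Model current (ions/ns) for given voltages and measured occupancies."""
    V = np.asarray(voltage, dtype=float)
    P2 = np.asarray(p2, dtype=float)
    kb = _kb_of_voltage(model, params, V)
    open_assoc = params["ktilde_a"] * (1.0 - P2)
    out = np.zeros_like(V)
    ok = (kb > 0) & (open_assoc > 0)
    out[ok] = 1.0 / (1.0 / kb[ok] + 1.0 / open_assoc[ok])
    return out


_PARAM_NAMES = {
    "drift_fed": ("kb0", "kappa_b", "ktilde_a"),
    "activated": ("kb0", "beta", "ktilde_a"),
    "drift_only": ("kappa_b", "ktilde_a"),
}
_LOG_PARAMS = {"kb0", "kappa_b", "ktilde_a"}  # positive rates -> log space


def fit_bulk_model(table: MeasurementTable, model_form: str = "drift_fed",
                   x0: Optional[dict] = None,
                   weighting: str = "moderated") -> FitResult:
    """Weighted least-squares fit of the chain current to a table.

    Requires at least four rows spanning at least two voltages and uses the
    measured P2 per row.

    Weighting.  Per-point variance estimates from a handful of replicas are
    themselves ~50% uncertain, and plugging them straight into
    inverse-variance weights is known to bias weighted least squares.  The
    default ``moderated`` weighting therefore pools them through the
    physically expected variance laws -- currents are event counts
    (var proportional to the mean) and occupancies are time-averaged binary
    signals (var proportional to P2*(1-P2)) -- fitting one scale constant
    per law across the table.  ``pointwise`` uses the raw per-point SEs.
    In both cases the occupancy, which enters the model as a regressor, has
    its uncertainty propagated into the weight (effective-variance method),
    sigma_eff^2 = SE_I^2 + (dI/dP2)^2*SE_P2^2, iterated once.  Parameter
    standard errors come from the fit covariance scaled by the reduced
    chi-square.  Raises on non-convergence.
    """
    if model_form not in MODEL_FORMS:
        raise ValueError(f"unknown model form {model_form!r}; choose from {MODEL_FORMS}")
    df = table.data
    if len(df) < 4 or df["voltage"].nunique() < 2:
        raise TableError("need >= 4 rows spanning >= 2 voltages to fit")
    V = df["voltage"].to_numpy(dtype=float)
    I = df["current"].to_numpy(dtype=float)
    P2 = df["p2"].to_numpy(dtype=float)
    se = df["current_se"].to_numpy(dtype=float)
    p2_se_raw = df["p2_se"].to_numpy(dtype=float)
    if weighting == "moderated" and (se > 0).any():
        c_i = float(np.mean(se**2 / np.clip(I, 1e-12, None)))
        sigma_i = np.sqrt(c_i * np.clip(I, 1e-12, None))
        bern = np.clip(P2 * (1.0 - P2), 1e-9, None)
        c_p = float(np.mean(p2_se_raw**2 / bern))
        p2_se = np.sqrt(c_p * bern)
    elif weighting == "pointwise" or not (se > 0).any():
        floor = max(np.min(se[se > 0]) if (se > 0).any() else 1.0, 1e-12)
        sigma_i = np.where(se > 0, se, floor)
        p2_se = p2_se_raw
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    names = _PARAM_NAMES[model_form]
    defaults = {"kb0": 1.0, "kappa_b": 1.0, "ktilde_a": 10.0, "beta": 1.0}
    start = {**defaults, **(x0 or {})}

    def pack(p: dict) -> np.ndarray:
        return np.array([math.log(p[n]) if n in _LOG_PARAMS else p[n] for n in names])

    def unpack(theta: np.ndarray) -> dict:
        return {n: (math.exp(t) if n in _LOG_PARAMS else float(t))
                for n, t in zip(names, theta)}

    sigma = sigma_i.copy()
    sol = None
    for _round in range(2):
        def resid(theta):
            return (predict_current(model_form, unpack(theta), V, P2) - I) / sigma

        x_start = pack(start) if sol is None else sol.x
        sol = least_squares(resid, x_start, method="lm", xtol=1e-14, ftol=1e-14)
        if not sol.success:
            raise RuntimeError(f"fit did not converge: {sol.message}")
        if np.all(p2_se == 0):
            break
        p = unpack(sol.x)
        pred = predict_current(model_form, p, V, P2)
        u = np.clip(1.0 - P2, 1e-12, None)
        dI_dP2 = pred**2 / (p["ktilde_a"] * u**2)
        sigma = np.sqrt(sigma_i**2 + (dI_dP2 * p2_se) ** 2)
    params = unpack(sol.x)

    n, p = len(I), len(names)
    dof = max(n - p, 1)
    chi2_red = 2.0 * sol.cost / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov_theta = np.linalg.inv(JTJ) * chi2_red
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(JTJ) * chi2_red
    se_theta = np.sqrt(np.clip(np.diag(cov_theta), 0, None))
    ses = {nme: (params[nme] * s if nme in _LOG_PARAMS else s)
           for nme, s in zip(names, se_theta)}

    w = 1.0 / sigma**2
    ybar = np.average(I, weights=w)
    ss_res = float(np.sum(w * (predict_current(model_form, params, V, P2) - I) ** 2))
    ss_tot = float(np.sum(w * (I - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - p - 1, 1)
    return FitResult(model=model_form, params=params, se=ses,
                     r_squared=r2, r_squared_adj=r2_adj,
                     residuals=sol.fun, n_obs=n,
                     metadata={
                         "weighting": weighting,
                         "positivity": "rates fitted in log space",
                         "voltages": sorted(set(V.tolist())),
                         "row_voltages": V.tolist(),
                         "data_keys": _data_keys(df),
                     })


def _data_keys(df: pd.DataFrame) -> tuple:
    """Identity of the fitted dataset: design keys plus the observed values."""
    return tuple(sorted(zip(df["strain"].tolist(), df["voltage"].tolist(),
                            df["current"].tolist(), df["p2"].tolist())))


def bootstrap_se(table: MeasurementTable, model_form: str, seed: int,
                 n_boot: int = 1000) -> dict:
    """Seeded residual-free parametric bootstrap: resample each current from
    N(I, SE) and refit; returns the std of each parameter across resamples.
    A cross-check on the covariance-based standard errors."""
    rng = np.random.default_rng(seed)
    base = table.data
    out: dict[str, list] = {}
    for _ in range(n_boot):
        df = base.copy()
        df["current"] = rng.normal(base["current"], base["current_se"].clip(lower=1e-12))
        try:
            res = fit_bulk_model(MeasurementTable(df), model_form)
        except RuntimeError:
            continue
        for k, v in res.params.items():
            out.setdefault(k, []).append(v)
    return {k: float(np.std(v, ddof=1)) for k, v in out.items()}


# ---------------------------------------------------------------------------
# dissociation-rate extraction


@dataclass
class ExponentialFit:
    """kd = prefactor * exp(exponent * s), s in percent strain."""

    prefactor: float
    prefactor_se: float
    prefactor_ci: tuple  # 95% interval
    exponent: float
    exponent_se: float


@dataclass
class CombinedKdFit:
    """kd = B * V * exp(b * qV/kBT + c * s)."""

    B: float
    B_se: float
    B_ci: tuple
    b: float
    b_se: float
    c: float
    c_se: float


@dataclass
class KdExtraction:
    points: pd.DataFrame  # strain, voltage, kd, kd_se
    per_voltage: dict  # voltage -> ExponentialFit
    combined: Optional[CombinedKdFit]
    n_excluded: int


def extract_kd(table: MeasurementTable,
               conditions: Optional[Conditions] = None) -> KdExtraction:
    """Point-by-point kd = (I/q)/P2 on the plateau, plus exponential fits.

    Rows with P2 = 0 are excluded with a warning (a vanishing occupancy
    carries no kd information).  Log-space errors are propagated from both
    the current and occupancy SEs; fits are weighted by their inverse
    variance.
    """
    cond = conditions or Conditions()
    df = table.data
    bad = df["p2"] <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} row(s) with P2 = 0 from kd "
                      "extraction", stacklevel=2)
    d = df[~bad].copy()
    d["kd"] = d["current"] / d["p2"]
    rel_var = (d["current_se"] / d["current"]) ** 2 + (d["p2_se"] / d["p2"]) ** 2
    d["kd_se"] = d["kd"] * np.sqrt(rel_var)
    log_sigma = np.sqrt(rel_var).replace(0, np.nan)
    fallback = float(np.nanmin(log_sigma)) if np.isfinite(log_sigma).any() else 1.0
    d["_logsig"] = log_sigma.fillna(fallback if fallback > 0 else 1.0)

    per_voltage: dict[float, ExponentialFit] = {}
    for v, grp in d.groupby("voltage"):
        if grp["strain"].nunique() < 2:
            continue
        y = np.log(grp["kd"].to_numpy())
        X = sm.add_constant(grp["strain"].to_numpy(dtype=float))
        w = 1.0 / grp["_logsig"].to_numpy() ** 2
        fit = sm.WLS(y, X, weights=w).fit()
        ci = fit.conf_int(alpha=0.05)
        per_voltage[float(v)] = ExponentialFit(
            prefactor=float(np.exp(fit.params[0])),
            prefactor_se=float(np.exp(fit.params[0]) * fit.bse[0]),
            prefactor_ci=(float(np.exp(ci[0][0])), float(np.exp(ci[0][1]))),
            exponent=float(fit.params[1]),
            exponent_se=float(fit.bse[1]),
        )

    combined = None
    if d["voltage"].nunique() >= 2 and d["strain"].nunique() >= 2:
        vt = cond.thermal_voltage
        y = np.log(d["kd"].to_numpy() / d["voltage"].to_numpy())
        X = np.column_stack([
            np.ones(len(d)),
            d["voltage"].to_numpy(dtype=float) / vt,
            d["strain"].to_numpy(dtype=float),
        ])
        w = 1.0 / d["_logsig"].to_numpy() ** 2
        fit = sm.WLS(y, X, weights=w).fit()
        ci = fit.conf_int(alpha=0.05)
        combined = CombinedKdFit(
            B=float(np.exp(fit.params[0])),
            B_se=float(np.exp(fit.params[0]) * fit.bse[0]),
            B_ci=(float(np.exp(ci[0][0])), float(np.exp(ci[0][1]))),
            b=float(fit.params[1]), b_se=float(fit.bse[1]),
            c=float(fit.params[2]), c_se=float(fit.bse[2]),
        )
    pts = d[["strain", "voltage", "kd", "kd_se"]].reset_index(drop=True)
    return KdExtraction(points=pts, per_voltage=per_voltage, combined=combined,
                        n_excluded=int(bad.sum()))


# ---------------------------------------------------------------------------
# model comparison


def compare_models(results: Sequence[FitResult],
                   reject_margin: float = 0.005) -> pd.DataFrame:
    """Rank fits of the same data by adjusted R^2 (plus the residual scale
    at the lowest voltage, where the model forms differ most).

    All results must have been fitted to identical (strain, voltage) keys.
    A model is flagged rejected when its adjusted R^2 trails the best by
    more than ``reject_margin``.
    """
    if len(results) < 2:
        raise ValueError("need at least two fit results to compare")
    keys = {r.metadata.get("data_keys") for r in results}
    if len(keys) != 1:
        raise ValueError("fit results were not obtained on identical data")
    rows = []
    for r in results:
        vmin = min(r.metadata["voltages"])
        mask = np.array(r.metadata["row_voltages"]) == vmin
        rows.append({
            "model": r.model,
            "r_squared": r.r_squared,
            "r_squared_adj": r.r_squared_adj,
            "lowest_voltage_rms": float(np.sqrt(np.mean(r.residuals[mask] ** 2)))
            if mask.any() else np.nan,
            **{f"{k}": v for k, v in r.params.items()},
            **{f"{k}_se": v for k, v in r.se.items()},
        })
    out = pd.DataFrame(rows).sort_values("r_squared_adj", ascending=False)
    best = out["r_squared_adj"].iloc[0]
    out["rejected"] = out["r_squared_adj"] < best - reject_margin
    return out.reset_index(drop=True)
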
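"""Single-site and three-site one-way rate models of pore permeation.

An atomically thin pore that holds at most one ion is described as a chain
of three sites: a staging site on the association side (1), the internal
pore binding site (2), and an exit-side site (3).  With one-way transitions
at the internal site (valid once the bias is large enough that back-steps
up the potential gradient are rare) the occupancies obey

    dP1/dt = kb*(1-P1) - kb_out*P1 - ka*P1*(1-P2)
    dP2/dt = ka*P1*(1-P2) - kd*P2*(1-P3)
    dP3/dt = kd*P2*(1-P3) - kexit_out*P3 + kexit_in*(1-P3)

and the steady-state particle current collapses to the closed form

    I/q = [ 1/kb + 1/(ktilde_a*(1-P2)) ]^{-1},   ktilde_a = ka*P1eq,

with P1eq = kb/(kb + kb_out) the staging occupancy decoupled from the pore.
The (1-P2) factor carries the many-body blocking effect: a localized ion in
the pore shuts off the current until it dissociates.

Deterministic solvers (steady state, transient ODE) and an exact
event-driven (Gillespie) simulator of the same {0,1}^3 Markov chain are
provided; the two routes agree within Monte-Carlo error and are used as
mutual cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import constants as K


@dataclass
class RateSet:
    """Kinetic parameters of the site chain, all in ns^-1 (rates) or their
    natural per-volt companions.

    The bulk feeding rate may be given directly (``kb``) or through one of
    two voltage laws evaluated by :meth:`kb_at`:

    * drift-fed:  kb(V) = kb0 + kappa_b*V        (kappa_b in 1/(V*ns))
    * activated:  kb(V) = kb0*exp(beta*V)        (beta in 1/V,
      i.e. the barrier drops by beta*V*kBT per volt of applied bias)
    """

    kb: Optional[float] = None
    kb0: Optional[float] = None
    kappa_b: Optional[float] = None
    beta: Optional[float] = None
    kb_out: float = 0.0  # staging -> bulk
    ka: Optional[float] = None  # staging -> pore
    ktilde_a: Optional[float] = None  # effective association ka*P1eq
    kd: float = 0.0  # pore -> exit site
    kexit_in: float = 0.0  # bulk -> exit site
    kexit_out: float = 0.0  # exit site -> bulk
    ka_back: float = 0.0  # optional backward rates, default one-way
    kd_back: float = 0.0

    def __post_init__(self):
        for name in ("kb", "kb0", "kappa_b", "ka", "ktilde_a"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("kb_out", "kd", "kexit_in", "kexit_out", "ka_back", "kd_back"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.ka is not None and self.ktilde_a is not None \
                and self.ktilde_a > self.ka * (1 + 1e-12):
            raise ValueError(
                f"ktilde_a={self.ktilde_a} cannot exceed ka={self.ka} "
                "(ktilde_a = ka * P1eq with P1eq <= 1)"
            )

    def kb_at(self, voltage: float = 0.0) -> float:
        """Bulk feeding rate at the given applied voltage."""
        if self.kb is not None:
            return self.kb
        if self.kb0 is None:
            raise ValueError("neither kb nor kb0 is set")
        if self.kappa_b is not None:
            return self.kb0 + self.kappa_b * voltage
        if self.beta is not None:
            return self.kb0 * math.exp(self.beta * voltage)
        return self.kb0

    def p1_equilibrium(self, voltage: float = 0.0) -> float:
        kb = self.kb_at(voltage)
        if kb + self.kb_out == 0:
            return 0.0
        return kb / (kb + self.kb_out)

    def effective_association(self, voltage: float = 0.0) -> float:
        if self.ktilde_a is not None:
            return self.ktilde_a
        if self.ka is None:
            raise ValueError("neither ktilde_a nor ka is set")
        return self.ka * self.p1_equilibrium(voltage)

    def resolved(self, voltage: float = 0.0) -> "RateSet":
        """A copy with kb fixed at the given voltage and ka populated."""
        ka = self.ka
        if ka is None:
            p1 = self.p1_equilibrium(voltage)
            ka = (self.ktilde_a / p1) if (self.ktilde_a and p1 > 0) else (self.ktilde_a or 0.0)
        return replace(self, kb=self.kb_at(voltage), kb0=None, kappa_b=None,
                       beta=None, ka=ka)


@dataclass
class ChainState:
    P1: float
    P2: float
    P3: float
    current: float  # ions/ns (particle current I/q)

    def occupancies(self) -> np.ndarray:
        return np.array([self.P1, self.P2, self.P3])


# ---------------------------------------------------------------------------
# closed forms


def single_site_current(ka: float, kd: float) -> tuple[float, float]:
    """Single-site one-way model: I/q = (1/ka + 1/kd)^-1, P = ka/(ka+kd).

    The identities I/q = kd*P = ka*(1-P) hold; for ka << kd the current is
    association limited, I/q -> ka.
    """
    if ka < 0 or kd < 0:
        raise ValueError("rates must be >= 0")
    if ka + kd == 0:
        raise ValueError("ka and kd cannot both be zero")
    if ka == 0 or kd == 0:
        return 0.0, (1.0 if kd == 0 else 0.0)
    current = 1.0 / (1.0 / ka + 1.0 / kd)
    return current, ka / (ka + kd)


def current_from_occupancy(kb: float, ktilde_a: float, P2: float) -> float:
    """Closed-form chain current given the pore occupancy:
    I/q = [1/kb + 1/(ktilde_a*(1-P2))]^-1.  A blocked pore (P2=1) carries
    zero current; the strongly asymmetric limits give min(kb, ktilde_a*(1-P2)).
    """
    if kb < 0 or ktilde_a < 0:
        raise ValueError("rates must be >= 0")
    if not (0.0 <= P2 <= 1.0):
        raise ValueError(f"P2 must be in [0,1], got {P2}")
    open_rate = ktilde_a * (1.0 - P2)
    if kb == 0 or open_rate == 0:
        return 0.0
    return 1.0 / (1.0 / kb + 1.0 / open_rate)


# ---------------------------------------------------------------------------
# deterministic chain


def _chain_rhs(rates: RateSet, voltage: float = 0.0) -> Callable:
    kb = rates.kb_at(voltage)
    kbo, ka = rates.kb_out, (rates.ka or 0.0)
    kd, kei, keo = rates.kd, rates.kexit_in, rates.kexit_out
    kab, kdb = rates.ka_back, rates.kd_back

    def rhs(_t, P):
        P1, P2, P3 = P
        a12 = ka * P1 * (1 - P2) - kab * P2 * (1 - P1)
        a23 = kd * P2 * (1 - P3) - kdb * P3 * (1 - P2)
        return [kb * (1 - P1) - kbo * P1 - a12,
                a12 - a23,
                a23 - keo * P3 + kei * (1 - P3)]

    return rhs


def steady_state_chain(rates: RateSet, voltage: float = 0.0,
                       tol: float = 1e-13, max_iter: int = 500) -> ChainState:
    """Solve the chain's steady state.

    P1 and P3 are eliminated analytically in terms of P2 and the remaining
    scalar balance  ka*P1(P2)*(1-P2) = kd*P2*(1-P3(P2))  is solved by
    bracketed root finding (one-way chain only; with backward rates a
    fixed-point iteration on the full system is used).  At the solution the
    three stage currents agree to the solver tolerance.
    """
    r = rates.resolved(voltage)
    kb, kbo, ka = r.kb, r.kb_out, (r.ka or 0.0)
    kd, kei, keo = r.kd, r.kexit_in, r.kexit_out
    if r.ka_back or r.kd_back:
        return _steady_state_iterate(r, tol, max_iter)
    if kb == 0:
        p3 = kei / (kei + keo) if (kei + keo) > 0 else 0.0
        return ChainState(0.0, 0.0, p3, 0.0)

    def p1_of(P2):
        den = kb + kbo + ka * (1 - P2)
        return kb / den if den > 0 else 0.0

    def p3_of(P2):
        den = kd * P2 + kei + keo
        return (kd * P2 + kei) / den if den > 0 else 0.0

    def balance(P2):
        return ka * p1_of(P2) * (1 - P2) - kd * P2 * (1 - p3_of(P2))

    if ka == 0:
        P2 = 0.0
    elif kd == 0 or keo == 0:
        # pore (or exit) is absorbing: fills up completely
        P2 = 1.0
    else:
        lo, hi = 0.0, 1.0
        if balance(lo) <= 0:
            P2 = 0.0
        else:
            P2 = brentq(balance, lo, hi, xtol=tol, rtol=8.9e-16)
    P1, P3 = p1_of(P2), p3_of(P2)
    current = ka * P1 * (1 - P2)
    state = ChainState(P1, P2, P3, current)
    _check_residual(r, state, tol=1e-10)
    return state


def _steady_state_iterate(r: RateSet, tol: float, max_iter: int) -> ChainState:
    rhs = _chain_rhs(r)
    P = np.array([0.5, 0.5, 0.5])
    # damped fixed-point on the stationarity conditions
    for _ in range(max_iter):
        denom1 = r.kb + r.kb_out + (r.ka or 0.0) * (1 - P[1])
        P1 = (r.kb + r.ka_back * P[1]) / (denom1 + r.ka_back * P[1]) \
            if denom1 > 0 else 0.0
        num = (r.ka or 0.0) * P1 + r.kd_back * P[2]
        den = num + r.kd * (1 - P[2]) + r.ka_back * (1 - P1)
        P2 = num / den if den > 0 else 0.0
        den3 = r.kd * P2 + r.kexit_in + r.kexit_out + r.kd_back * (1 - P2)
        P3 = (r.kd * P2 + r.kexit_in) / den3 if den3 > 0 else 0.0
        new = np.array([P1, P2, P3])
        if np.max(np.abs(new - P)) < tol:
            P = new
            break
        P = 0.5 * P + 0.5 * new
    else:
        res = np.max(np.abs(rhs(0, P)))
        raise RuntimeError(f"steady state did not converge; residual {res:.3g}")
    current = (r.ka or 0.0) * P[0] * (1 - P[1]) - r.ka_back * P[1] * (1 - P[0])
    return ChainState(P[0], P[1], P[2], current)


def _check_residual(rates: RateSet, state: ChainState, tol: float) -> None:
    rhs = _chain_rhs(rates)
    res = np.max(np.abs(rhs(0.0, state.occupancies())))
    scale = max(rates.kb or 0.0, rates.ka or 0.0, rates.kd, 1e-30)
    if res > tol * scale:
        raise RuntimeError(
            f"steady-state residual {res:.3g} exceeds tolerance {tol * scale:.3g}"
        )


def transient_chain(rates: RateSet, P_init, t_grid, voltage: float = 0.0):
    """Integrate the occupancy ODEs on ``t_grid`` (ns).

    Returns an array of shape (len(t_grid), 3) plus the particle current
    time series.  Converges to :func:`steady_state_chain` as t -> inf.
    """
    P_init = np.asarray(P_init, dtype=float)
    if P_init.shape != (3,) or np.any(P_init < 0) or np.any(P_init > 1):
        raise ValueError(f"P_init must be three occupancies in [0,1], got {P_init}")
    t_grid = np.asarray(t_grid, dtype=float)
    rhs = _chain_rhs(rates, voltage)
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), P_init, t_eval=t_grid,
                    method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    P = np.clip(sol.y.T, 0.0, 1.0)
    r = rates.resolved(voltage)
    current = (r.ka or 0.0) * P[:, 0] * (1 - P[:, 1])
    return P, current


def stationary_distribution(rates: RateSet, voltage: float = 0.0):
    """Exact stationary state of the {0,1}^3 occupancy Markov chain.

    Solves the 8-state master equation directly (no factorization), so the
    result matches :func:`gillespie_chain` to Monte-Carlo precision for any
    rate set.  The deterministic :func:`steady_state_chain` treats the site
    occupancies as independent (it closes products like <n1(1-n2)> as
    P1*(1-P2)); that approximation is accurate when each boundary site
    exchanges with its reservoir faster than with the pore and can deviate
    by several percent otherwise.

    Returns (ChainState, p) where p is the probability vector over states
    ordered as binary tuples (n1, n2, n3).
    """
    import itertools

    r = rates.resolved(voltage)
    states = list(itertools.product([0, 1], repeat=3))
    index = {s: i for i, s in enumerate(states)}
    Q = np.zeros((8, 8))
    for s in states:
        n1, n2, n3 = s
        if n1 == 0:
            Q[index[s], index[(1, n2, n3)]] += r.kb or 0.0
        if n1 == 1:
            Q[index[s], index[(0, n2, n3)]] += r.kb_out
        if n1 == 1 and n2 == 0:
            Q[index[s], index[(0, 1, n3)]] += r.ka or 0.0
        if n2 == 1 and n3 == 0:
            Q[index[s], index[(n1, 0, 1)]] += r.kd
        if n3 == 1:
            Q[index[s], index[(n1, n2, 0)]] += r.kexit_out
        if n3 == 0:
            Q[index[s], index[(n1, n2, 1)]] += r.kexit_in
        if n2 == 1 and n1 == 0:
            Q[index[s], index[(1, 0, n3)]] += r.ka_back
        if n3 == 1 and n2 == 0:
            Q[index[s], index[(n1, 1, 0)]] += r.kd_back
    A = Q.T - np.diag(Q.sum(axis=1))
    A[-1, :] = 1.0
    b = np.zeros(8)
    b[-1] = 1.0
    p = np.linalg.solve(A, b)
    P = np.zeros(3)
    current = 0.0
    for s, pi in zip(states, p):
        P += np.array(s) * pi
        if s[1] == 1 and s[2] == 0:
            current += r.kd * pi
        if s[2] == 1 and s[1] == 0:
            current -= r.kd_back * pi
    return ChainState(P[0], P[1], P[2], current), p


# ---------------------------------------------------------------------------
# stochastic chain


@dataclass
class GillespieResult:
    """One or several replicas of the exact occupancy Markov chain."""

    t_end: float
    seed: int
    occupancy: np.ndarray  # time-averaged (P1, P2, P3), mean over replicas
    occupancy_se: np.ndarray
    current: float  # translocations (site2 -> site3) / t_end, mean
    current_se: float
    translocations: np.ndarray  # per replica
    events: Optional[list[tuple[float, str]]] = None  # first replica's train


_TRANSITIONS = (
    # name, rate attr, condition(n1,n2,n3), delta
    ("bulk_in", "kb", lambda n: n[0] == 0, (1, 0, 0)),
    ("bulk_out", "kb_out", lambda n: n[0] == 1, (-1, 0, 0)),
    ("associate", "ka", lambda n: n[0] == 1 and n[1] == 0, (-1, 1, 0)),
    ("dissociate", "kd", lambda n: n[1] == 1 and n[2] == 0, (0, -1, 1)),
    ("exit_out", "kexit_out", lambda n: n[2] == 1, (0, 0, -1)),
    ("exit_in", "kexit_in", lambda n: n[2] == 0, (0, 0, 1)),
    ("associate_back", "ka_back", lambda n: n[1] == 1 and n[0] == 0, (1, -1, 0)),
    ("dissociate_back", "kd_back", lambda n: n[2] == 1 and n[1] == 0, (0, 1, -1)),
)


def gillespie_chain(rates: RateSet, t_end: float, seed: int,
                    n_replicas: int = 1, voltage: float = 0.0,
                    record_events: bool = False,
                    initial=(0, 0, 0)) -> GillespieResult:
    """Exact event-driven simulation of the {0,1}^3 occupancy chain.

    Time-averaged occupancies and the translocation count divided by
    ``t_end`` reproduce the deterministic steady state within Monte-Carlo
    error.  The standard error across replicas is sqrt(var/n).  Runs are
    bit-reproducible for a fixed seed.
    """
    r = rates.resolved(voltage)
    occ = np.zeros((n_replicas, 3))
    trans = np.zeros(n_replicas)
    events_first: Optional[list] = [] if record_events else None
    root = np.random.default_rng(seed)
    for rep, child in enumerate(root.spawn(n_replicas)):
        n = list(initial)
        t = 0.0
        dwell = np.zeros(3)
        count = 0
        while True:
            props = []
            for name, attr, cond, delta in _TRANSITIONS:
                k = getattr(r, attr) or 0.0
                if k > 0 and cond(n):
                    props.append((k, name, delta))
            total = sum(p[0] for p in props)
            if total == 0:
                dwell += np.array(n) * (t_end - t)
                break
            tau = child.exponential(1.0 / total)
            if t + tau >= t_end:
                dwell += np.array(n) * (t_end - t)
                break
            dwell += np.array(n) * tau
            t += tau
            u = child.uniform(0, total)
            acc = 0.0
            for k, name, delta in props:
                acc += k
                if u <= acc:
                    n = [a + d for a, d in zip(n, delta)]
                    if name == "dissociate":
                        count += 1
                    if record_events and rep == 0:
                        events_first.append((t, name))
                    break
        occ[rep] = dwell / t_end
        trans[rep] = count
    current = trans / t_end
    occ_se = (occ.std(axis=0, ddof=1) / np.sqrt(n_replicas)
              if n_replicas > 1 else np.full(3, np.nan))
    cur_se = (float(current.std(ddof=1) / np.sqrt(n_replicas))
              if n_replicas > 1 else float("nan"))
    return GillespieResult(t_end=t_end, seed=seed,
                           occupancy=occ.mean(axis=0), occupancy_se=occ_se,
                           current=float(current.mean()), current_se=cur_se,
                           translocations=trans, events=events_first)
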
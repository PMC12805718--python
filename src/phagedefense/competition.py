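"""Stochastic altruist/cheater competition in a single shared chemostat.

The altruist genotype is PCD-competent (strategy ``(a, r)``); the cheater
carries the same immunity investment but never commits PCD (``(0, r)``).
Both experience the same nutrient and virion pools, so any fitness
difference is mediated by the *public* consequences of PCD — destroyed
virions and freed nutrient — which a well-mixed population shares equally.
PCD is individually costly only insofar as the dying cell forgoes expected
future progeny; when cells trigger PCD only at viral loads from which they
could never recover (e.g. when immunity is too weak to clear the infection),
the trait is selectively neutral even without population structure.

Demographic noise is realised by tau-leaping: every deterministic flux of
the chemostat step becomes a draw with matching expectation (sequential
conditioned binomials, so a state's channels never overdraw it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels as K
from .chemostat_core import EXIT_PROB_CAP, RateTables, run_to_equilibrium
from .params import EcologyParams, StrategyParams

__all__ = [
    "DuoState",
    "CompetitionTrace",
    "step_stochastic",
    "run_competition",
    "classify_neutrality",
    "mixed_equilibrium_state",
]


@dataclass
class DuoState:
    """Two genotypes sharing one chemostat."""

    n_alt: np.ndarray  # int64, shape (P0, Q+1)
    n_cheat: np.ndarray
    phi: float
    psi: float
    t: float = 0.0

    @property
    def N_alt(self) -> int:
        return int(self.n_alt.sum())

    @property
    def N_cheat(self) -> int:
        return int(self.n_cheat.sum())

    @property
    def altruist_fraction(self) -> float:
        tot = self.N_alt + self.N_cheat
        return self.N_alt / tot if tot > 0 else float("nan")

    def copy(self) -> "DuoState":
        return DuoState(self.n_alt.copy(), self.n_cheat.copy(),
                        self.phi, self.psi, self.t)


@dataclass
class CompetitionTrace:
    times: np.ndarray
    altruist_fraction: np.ndarray
    N_alt: np.ndarray
    N_cheat: np.ndarray
    outcome: str = "ongoing"  # ongoing | fixation | extinct | collapse | neutral | advantage

    @property
    def N_total(self) -> np.ndarray:
        return self.N_alt + self.N_cheat


def _duo_tables(eco: EcologyParams, strat_alt: StrategyParams,
                strat_cheat: StrategyParams):
    ta = RateTables(eco, strat_alt)
    tc = RateTables(eco, strat_cheat)
    return ta, tc


def mixed_equilibrium_state(
    eco: EcologyParams,
    strat_alt: StrategyParams,
    init_fraction: float = 0.5,
    tol: float = 1e-4,
    t_max: float = 500.0,
) -> DuoState:
    """Equilibrate the altruist alone, then relabel a share of every (p, q)
    class as cheaters.

    Competition thus starts at ecological steady state, and because the
    cheater inherits the altruist's standing distribution there is no
    initial transient that favours either genotype.  ``init_fraction`` is
    the altruist share retained.
    """
    if not 0 < init_fraction <= 1:
        raise ValueError("init_fraction must lie in (0, 1]")
    res = run_to_equilibrium(eco, strat_alt, tol=tol, t_max=t_max)
    n = np.rint(res.final_state.n).astype(np.int64)
    n_alt = np.rint(n * init_fraction).astype(np.int64)
    n_cheat = n - n_alt
    return DuoState(n_alt=n_alt, n_cheat=n_cheat,
                    phi=res.final_state.phi, psi=res.final_state.psi, t=0.0)


def step_stochastic(
    state: DuoState,
    eco: EcologyParams,
    strat_alt: StrategyParams,
    strat_cheat: StrategyParams,
    dt: float,
    rng: np.random.Generator,
) -> DuoState:
    """Advance the two-genotype chemostat by ``dt`` with tau-leaping.

    The leap condition (per-state exit probability below the configured cap)
    is enforced internally by subdividing ``dt`` when necessary; the
    expectation of the update equals the deterministic step.
    """
    if strat_cheat.a != 0.0:
        warnings.warn("cheater genotype normally has a=0", stacklevel=2)
    ta, tc = _duo_tables(eco, strat_alt, strat_cheat)
    rec = np.empty(2)
    rec_fa = np.empty(2)
    rec_na = np.empty(2)
    rec_nc = np.empty(2)
    seed = int(rng.integers(1, 2**31 - 1))
    n_a, n_c, phi, psi, t, _nrec, _steps = K.integrate_tau(
        np.ascontiguousarray(state.n_alt, dtype=np.int64),
        np.ascontiguousarray(state.n_cheat, dtype=np.int64),
        state.phi, state.psi,
        ta.A_eff, strat_alt.r, tc.A_eff, strat_cheat.r,
        eco.B, eco.C, eco.F, eco.phi0, eco.psi0,
        ta.pvec, ta.lam, ta.det, ta.pcd, tc.pcd, eco.Q,
        EXIT_PROB_CAP, ta.lam_ctrl_cap,
        state.t, dt, seed, 2 * dt, rec, rec_fa, rec_na, rec_nc)
    return DuoState(n_alt=n_a, n_cheat=n_c, phi=phi, psi=psi, t=t)


def run_competition(
    eco: EcologyParams,
    strat_alt: StrategyParams,
    init_fraction: float = 0.5,
    t_max: float = 200.0,
    replicates: int = 20,
    rng: "np.random.Generator | int | None" = None,
    rec_dt: float = 1.0,
    strat_cheat: Optional[StrategyParams] = None,
    classify: bool = True,
) -> list[CompetitionTrace]:
    """Replicate stochastic competition runs from an equilibrated mixed start.

    Each replicate starts from the same deterministic mixed equilibrium
    (altruist share ``init_fraction``) and runs for ``t_max`` time units,
    sampling the altruist fraction every ``rec_dt``.  Outcomes are labelled
    per trace (fixation/extinct) and, across replicates, by
    :func:`classify_neutrality`.
    """
    rng = np.random.default_rng(rng)
    if strat_cheat is None:
        strat_cheat = StrategyParams(a=0.0, r=strat_alt.r)
    ta, tc = _duo_tables(eco, strat_alt, strat_cheat)
    if init_fraction == 1.0:
        res = run_to_equilibrium(eco, strat_alt)
        base = DuoState(
            n_alt=np.rint(res.final_state.n).astype(np.int64),
            n_cheat=np.zeros_like(res.final_state.n, dtype=np.int64),
            phi=res.final_state.phi, psi=res.final_state.psi)
    else:
        base = mixed_equilibrium_state(eco, strat_alt, init_fraction)
    nbuf = int(t_max / rec_dt) + 3
    traces = []
    for _rep in range(replicates):
        rec_t = np.empty(nbuf)
        rec_fa = np.empty(nbuf)
        rec_na = np.empty(nbuf)
        rec_nc = np.empty(nbuf)
        seed = int(rng.integers(1, 2**31 - 1))
        n_a, n_c, phi, psi, t, nrec, _steps = K.integrate_tau(
            base.n_alt.copy(), base.n_cheat.copy(), base.phi, base.psi,
            ta.A_eff, strat_alt.r, tc.A_eff, strat_cheat.r,
            eco.B, eco.C, eco.F, eco.phi0, eco.psi0,
            ta.pvec, ta.lam, ta.det, ta.pcd, tc.pcd, eco.Q,
            EXIT_PROB_CAP, ta.lam_ctrl_cap,
            0.0, t_max, seed, rec_dt, rec_t, rec_fa, rec_na, rec_nc)
        tr = CompetitionTrace(
            times=rec_t[:nrec].copy(),
            altruist_fraction=rec_fa[:nrec].copy(),
            N_alt=rec_na[:nrec].copy(),
            N_cheat=rec_nc[:nrec].copy())
        tot = tr.N_alt[-1] + tr.N_cheat[-1]
        if tot == 0:
            tr.outcome = "extinct"
        elif tr.N_alt[-1] == 0 or tr.N_cheat[-1] == 0:
            tr.outcome = "fixation"
        traces.append(tr)
    if classify and len(traces) >= 5:
        label = classify_neutrality(traces)
        for tr in traces:
            if tr.outcome == "ongoing":
                tr.outcome = label
    return traces


def _logit_slope(tr: CompetitionTrace) -> Optional[float]:
    """OLS slope of logit(altruist fraction) against time for one trace.

    Points at or beyond fixation/extinction are right-censored: the series
    is truncated at the first boundary hit.  Returns None when fewer than
    three usable points remain.
    """
    f = tr.altruist_fraction
    t = tr.times
    good = np.isfinite(f)
    boundary = np.where((f <= 0.0) | (f >= 1.0) | ~good)[0]
    stop = boundary[0] if len(boundary) else len(f)
    f = f[:stop]
    t = t[:stop]
    if len(f) < 3:
        return None
    y = np.log(f / (1.0 - f))
    return float(np.polyfit(t, y, 1)[0])


def classify_neutrality(traces: Sequence[CompetitionTrace],
                        z_threshold: float = 2.0) -> str:
    """Label an ensemble of competition traces.

    Fits a per-replicate slope of logit(altruist fraction) versus time and
    tests the across-replicate mean slope against zero: ``neutral`` within
    ``z_threshold`` standard errors, ``collapse`` when significantly
    negative, ``advantage`` when significantly positive.  Traces that hit a
    boundary are right-censored before fitting; an ensemble whose traces all
    hit boundaries immediately cannot be classified and raises.
    """
    if len(traces) < 5:
        raise ValueError("need at least 5 replicate traces of equal duration")
    slopes = [s for s in (_logit_slope(tr) for tr in traces) if s is not None]
    if len(slopes) < 2:
        raise ValueError("too few informative traces to classify")
    slopes = np.asarray(slopes)
    se = slopes.std(ddof=1) / np.sqrt(len(slopes))
    if se == 0:
        z = np.inf * np.sign(slopes.mean()) if slopes.mean() != 0 else 0.0
    else:
        z = slopes.mean() / se
    if z < -z_threshold:
        return "collapse"
    if z > z_threshold:
        return "advantage"
    return "neutral"
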
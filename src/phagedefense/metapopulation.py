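"""Structured (Simpson's paradox) metapopulation of two-genotype chemostats.

A fully connected ensemble of up to ``K`` chemostats undergoes a birth-death
process — empty vessels appear at rate ``b*(K-k)/K`` and random vessels are
removed at rate ``d`` — and is coupled by stochastic migration: at
exponentially distributed epochs (mean interval ``m``) a source vessel is
drawn with probability proportional to its population size, a destination
uniformly among the others, and ``Binomial(N_i, f)`` individuals move,
their altruist share drawn binomially from the source composition.  Because
larger (altruist-richer) vessels both persist longer and export more
migrants, a locally disfavoured PCD genotype can still fix globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels as K
from .chemostat_core import EXIT_PROB_CAP, RateTables, run_to_equilibrium
from .competition import DuoState, mixed_equilibrium_state
from .params import EcologyParams, StrategyParams

__all__ = [
    "MetapopParams",
    "MetapopState",
    "MetapopTrace",
    "migrate",
    "step_metapop",
    "run_metapopulation",
]


@dataclass
class MetapopParams:
    eco: EcologyParams
    strat_alt: StrategyParams
    b: float  # chemostat birth-rate scale
    d: float  # chemostat death rate (ensemble-level, a uniform vessel dies)
    K: int  # carrying capacity of the ensemble
    m: float  # mean time between migration events
    f: float  # per-individual migration probability at a migration event
    strat_cheat: Optional[StrategyParams] = None
    init_k: Optional[int] = None  # initial number of vessels (default K//2)
    init_fraction: float = 0.5  # altruist share of the seeding equilibrium

    def __post_init__(self):
        if self.strat_cheat is None:
            self.strat_cheat = StrategyParams(a=0.0, r=self.strat_alt.r)
        if min(self.b, self.d, self.m) <= 0 or self.f <= 0:
            raise ValueError("b, d, m, f must be positive")
        if int(self.K) != self.K or self.K < 1:
            raise ValueError("K must be an integer >= 1")


@dataclass
class MetapopState:
    subpops: list  # list[DuoState]
    t: float = 0.0
    event_log: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.subpops)

    @property
    def N_alt(self) -> int:
        return int(sum(s.N_alt for s in self.subpops))

    @property
    def N_cheat(self) -> int:
        return int(sum(s.N_cheat for s in self.subpops))

    @property
    def global_altruist_fraction(self) -> float:
        tot = self.N_alt + self.N_cheat
        return self.N_alt / tot if tot > 0 else float("nan")


@dataclass
class MetapopTrace:
    times: np.ndarray
    altruist_fraction: np.ndarray
    N_alt: np.ndarray
    N_cheat: np.ndarray
    k: np.ndarray
    subpop_sizes: list  # per sample, array of N_i
    subpop_fractions: list
    outcome: str = "ongoing"  # altruist_fixation | cheater_fixation | extinct | ongoing


def _sample_migrants(n: np.ndarray, count: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw ``count`` individuals without replacement from the occupancy
    matrix ``n``, returned as a matrix of the same shape."""
    flat = n.ravel()
    take = rng.multivariate_hypergeometric(flat, count)
    return take.reshape(n.shape)


def migrate(state: MetapopState, params: MetapopParams,
            rng: np.random.Generator) -> None:
    """Execute one migration event in place.

    Source vessel i is drawn with probability ``N_i / sum N_j`` (integer
    sizes), the destination uniformly among the other vessels; ``n_m ~
    Binomial(N_i, f)`` individuals migrate, of which ``n_ma ~ Binomial(n_m,
    N_ia/N_i)`` are altruists; the (p, q) classes of the migrants are
    sampled proportionally to the source's occupancy within each genotype.
    Totals of both genotypes are conserved.
    """
    if state.k < 2:
        return
    sizes = np.array([s.N_alt + s.N_cheat for s in state.subpops], dtype=float)
    tot = sizes.sum()
    if tot <= 0:
        state.event_log.append((state.t, "migration_noop", -1, -1, 0, 0))
        return
    src = int(rng.choice(state.k, p=sizes / tot))
    others = [j for j in range(state.k) if j != src]
    dst = int(rng.choice(others))
    s = state.subpops[src]
    Ni = s.N_alt + s.N_cheat
    n_m = int(rng.binomial(Ni, params.f))
    if n_m == 0:
        state.event_log.append((state.t, "migration", src, dst, 0, 0))
        return
    n_ma = int(rng.binomial(n_m, s.N_alt / Ni))
    n_mc = n_m - n_ma
    d = state.subpops[dst]
    if n_ma > 0:
        take = _sample_migrants(s.n_alt, n_ma, rng)
        s.n_alt -= take
        d.n_alt += take
    if n_mc > 0:
        take = _sample_migrants(s.n_cheat, n_mc, rng)
        s.n_cheat -= take
        d.n_cheat += take
    state.event_log.append((state.t, "migration", src, dst, n_m, n_ma))


def _advance_subpops(state: MetapopState, params: MetapopParams, dt: float,
                     tables, rng: np.random.Generator) -> None:
    eco = params.eco
    ta, tc = tables
    rec = np.empty(2)
    rec2 = np.empty(2)
    rec3 = np.empty(2)
    rec4 = np.empty(2)
    for s in state.subpops:
        if s.N_alt + s.N_cheat == 0:
            # an empty vessel only exchanges media with the influent
            s.phi = eco.phi0 + (s.phi - eco.phi0) * np.exp(-eco.B * dt)
            s.psi = eco.psi0 + (s.psi - eco.psi0) * np.exp(-eco.B * dt)
            s.t += dt
            continue
        seed = int(rng.integers(1, 2**31 - 1))
        n_a, n_c, phi, psi, t, _nr, _st = K.integrate_tau(
            s.n_alt, s.n_cheat, s.phi, s.psi,
            ta.A_eff, params.strat_alt.r, tc.A_eff, params.strat_cheat.r,
            eco.B, eco.C, eco.F, eco.phi0, eco.psi0,
            ta.pvec, ta.lam, ta.det, ta.pcd, tc.pcd, eco.Q,
            EXIT_PROB_CAP, ta.lam_ctrl_cap,
            s.t, dt, seed, 2 * dt, rec, rec2, rec3, rec4)
        s.n_alt = n_a
        s.n_cheat = n_c
        s.phi = phi
        s.psi = psi
        s.t = t


def step_metapop(state: MetapopState, params: MetapopParams, dt: float,
                 rng: np.random.Generator,
                 tables=None) -> None:
    """Advance the whole ensemble by ``dt`` in place.

    Every subpopulation advances with the stochastic chemostat kernel;
    migration, vessel birth (an empty chemostat with influent media) and
    vessel death (a uniformly chosen chemostat disappears) each fire with
    probability ``rate * dt``, so ``dt`` must resolve the event rates
    (``dt <= min(m, 1/b, 1/d)/10`` is recommended).
    """
    eco = params.eco
    if tables is None:
        tables = (RateTables(eco, params.strat_alt),
                  RateTables(eco, params.strat_cheat))
    _advance_subpops(state, params, dt, tables, rng)
    state.t += dt
    if rng.random() < dt / params.m:
        migrate(state, params, rng)
    birth_rate = params.b * (params.K - state.k) / params.K
    if birth_rate > 0 and rng.random() < birth_rate * dt:
        empty = DuoState(
            n_alt=np.zeros((eco.P0, eco.Q + 1), dtype=np.int64),
            n_cheat=np.zeros((eco.P0, eco.Q + 1), dtype=np.int64),
            phi=eco.phi0, psi=eco.psi0, t=state.t)
        state.subpops.append(empty)
        state.event_log.append((state.t, "birth", -1, state.k - 1, 0, 0))
    if state.k > 0 and rng.random() < params.d * dt:
        victim = int(rng.integers(state.k))
        state.subpops.pop(victim)
        state.event_log.append((state.t, "death", victim, -1, 0, 0))


def run_metapopulation(
    params: MetapopParams,
    t_max: float,
    rng: "np.random.Generator | int | None" = None,
    rec_dt: float = 2.0,
) -> MetapopTrace:
    """Simulate the structured population until fixation, extinction or t_max.

    Initially ``init_k`` (default K//2) vessels are seeded from the same
    deterministic mixed equilibrium (altruist share ``init_fraction``).
    Between the discrete ensemble events — migration at rate 1/m, vessel
    birth at ``b*(K-k)/K``, vessel death at ``d`` — all subpopulations
    advance in parallel with the stochastic chemostat kernel; the event type
    is then drawn from the competing exponential clocks.
    """
    rng = np.random.default_rng(rng)
    eco = params.eco
    tables = (RateTables(eco, params.strat_alt),
              RateTables(eco, params.strat_cheat))
    init_k = params.init_k if params.init_k is not None else max(params.K // 2, 1)
    base = mixed_equilibrium_state(eco, params.strat_alt, params.init_fraction)
    state = MetapopState(subpops=[base.copy() for _ in range(init_k)])
    times = [0.0]
    fr = [state.global_altruist_fraction]
    na = [state.N_alt]
    nc = [state.N_cheat]
    kk = [state.k]
    sizes = [np.array([s.N_alt + s.N_cheat for s in state.subpops])]
    fracs = [np.array([s.altruist_fraction for s in state.subpops])]
    next_rec = rec_dt
    outcome = "ongoing"
    while state.t < t_max:
        birth_rate = params.b * (params.K - state.k) / params.K
        total_rate = 1.0 / params.m + birth_rate + (params.d if state.k else 0.0)
        tau = rng.exponential(1.0 / total_rate)
        tau = min(tau, t_max - state.t, max(rec_dt, 1e-9))
        _advance_subpops(state, params, tau, tables, rng)
        state.t += tau
        u = rng.random() * total_rate
        if u < 1.0 / params.m:
            migrate(state, params, rng)
        elif u < 1.0 / params.m + birth_rate:
            if state.k < params.K:
                empty = DuoState(
                    n_alt=np.zeros((eco.P0, eco.Q + 1), dtype=np.int64),
                    n_cheat=np.zeros((eco.P0, eco.Q + 1), dtype=np.int64),
                    phi=eco.phi0, psi=eco.psi0, t=state.t)
                state.subpops.append(empty)
                state.event_log.append((state.t, "birth", -1, state.k - 1, 0, 0))
        else:
            if state.k > 0:
                victim = int(rng.integers(state.k))
                state.subpops.pop(victim)
                state.event_log.append((state.t, "death", victim, -1, 0, 0))
        if state.t >= next_rec or state.t >= t_max:
            times.append(state.t)
            fr.append(state.global_altruist_fraction)
            na.append(state.N_alt)
            nc.append(state.N_cheat)
            kk.append(state.k)
            sizes.append(np.array([s.N_alt + s.N_cheat for s in state.subpops]))
            fracs.append(np.array([s.altruist_fraction for s in state.subpops]))
            next_rec = state.t + rec_dt
        Na, Nc = state.N_alt, state.N_cheat
        if Na == 0 and Nc == 0:
            outcome = "extinct"
            break
        if Nc == 0:
            outcome = "altruist_fixation"
            break
        if Na == 0:
            outcome = "cheater_fixation"
            break
    trace = MetapopTrace(
        times=np.asarray(times), altruist_fraction=np.asarray(fr),
        N_alt=np.asarray(na), N_cheat=np.asarray(nc), k=np.asarray(kk),
        subpop_sizes=sizes, subpop_fractions=fracs, outcome=outcome)
    return trace
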
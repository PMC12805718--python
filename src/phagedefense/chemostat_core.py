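"""Well-mixed chemostat model of a prokaryote population under lytic phage.

Cells are tracked on a two-dimensional grid of volume ``p`` (from the newborn
size ``P0`` to the division size ``2*P0 - 1``) and intracellular virion count
``q`` (0 to ``Q``).  The intracellular virus *concentration*

    rho(p, q) = (q / Q) * (P0 / p)

is normalised so that a newborn cell holding the maximum ``Q`` virions has
concentration one.  Cells grow on the nutrient, divide from the top volume
bin when uninfected, are infected by free virions (superinfection excluded),
replicate internal virus, clear it by immunity, lyse — stochastically below
the lethal threshold ``T`` and certainly at or above it — and are washed out
by dilution.  A PCD-competent genotype additionally self-destructs, without
releasing virions, as soon as ``rho`` exceeds ``1 - a``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels as K
from .params import EcologyParams, StrategyParams

__all__ = [
    "ChemostatState",
    "EquilibriumResult",
    "StepSizeError",
    "virus_concentration",
    "lysis_rate",
    "step",
    "run_to_equilibrium",
    "burst_size_distribution",
    "burst_modes",
    "expected_progeny",
    "RateTables",
]

#: Populations below this total count are reported as extinct.
EXTINCTION_FLOOR = 1e-6

#: Default cap on the per-state exit probability per Euler step.
EXIT_PROB_CAP = 0.05


class StepSizeError(RuntimeError):
    """Raised when a single Euler step of the requested dt would produce
    negative cell counts; reduce dt (the adaptive integrator does so
    automatically)."""


def virus_concentration(p: int, q: int, eco: EcologyParams) -> float:
    """Intracellular virus concentration ``rho = (q/Q) * (P0/p)``.

    Strictly increasing in the virion count and decreasing in cell volume;
    equals one for a newborn cell at the intracellular cap.
    """
    if not eco.P0 <= p <= 2 * eco.P0 - 1:
        raise ValueError(f"volume index p={p} outside [{eco.P0}, {2 * eco.P0 - 1}]")
    if not 0 <= q <= eco.Q:
        raise ValueError(f"virion count q={q} outside [0, {eco.Q}]")
    return (q / eco.Q) * (eco.P0 / p)


def lysis_rate(rho: float, eco: EcologyParams, dt: float) -> float:
    """Per-cell lysis rate at concentration ``rho``.

    Below the lethal threshold the rate is ``(rho/(T-rho))**G``; at or above
    it the cell lyses within one step with probability one, i.e. the rate is
    capped at ``1/dt``.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rho >= eco.T:
        return 1.0 / dt
    if rho == 0.0:
        return 0.0
    return (rho / (eco.T - rho)) ** eco.G


class RateTables:
    """Precomputed per-state quantities for one (ecology, strategy) pair."""

    def __init__(self, eco: EcologyParams, strat: StrategyParams):
        strat.validate_against(eco)
        self.eco = eco
        self.strat = strat
        P0, Q = eco.P0, eco.Q
        self.pvec = np.arange(P0, 2 * P0, dtype=np.float64)
        qv = np.arange(Q + 1, dtype=np.float64)
        self.rho = (qv[None, :] / Q) * (P0 / self.pvec[:, None])
        self.det = self.rho >= eco.T
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            lam = np.where(self.det, 0.0, (self.rho / (eco.T - self.rho)) ** eco.G)
        lam[:, 0] = 0.0
        self.lam = np.ascontiguousarray(lam)
        self.pcd = self.rho > 1.0 - strat.a
        self.A_eff = eco.A * (1.0 - strat.r / eco.E)
        # retained for kernel call-site stability; lysis no longer enters
        # the step controller (its per-step probability saturates at one)
        self.lam_ctrl_cap = max(eco.F * Q, 1.0)


@dataclass
class ChemostatState:
    """Cell-count matrix plus the shared nutrient and virion pools."""

    n: np.ndarray  # shape (P0, Q+1), volume-by-load cell counts
    phi: float
    psi: float
    t: float = 0.0

    def validate(self, eco: EcologyParams) -> None:
        if self.n.shape != (eco.P0, eco.Q + 1):
            raise ValueError(
                f"state matrix has shape {self.n.shape}, expected {(eco.P0, eco.Q + 1)}"
            )
        if np.any(self.n < 0) or self.phi < 0 or self.psi < 0:
            raise ValueError("negative entries in chemostat state")
        if not np.isfinite(self.n).all():
            raise ValueError("non-finite entries in chemostat state")

    @property
    def total(self) -> float:
        return float(self.n.sum())

    @classmethod
    def inoculum(cls, eco: EcologyParams, size: float = 1.0) -> "ChemostatState":
        """A small virus-free inoculum of newborn cells in fresh media."""
        n = np.zeros((eco.P0, eco.Q + 1))
        n[0, 0] = size
        return cls(n=n, phi=eco.phi0, psi=eco.psi0)

    @classmethod
    def established(cls, eco: EcologyParams, strat: StrategyParams) -> "ChemostatState":
        """Closed-form estimate of an established, virus-free population.

        Balancing the division cycle against dilution gives a nutrient level
        ``phi* ~ S*B/(A_eff*ln 2)`` with ``S = sum_p 1/p``, from which the
        standing biomass follows from the nutrient balance and the virion
        pool from its quasi-static supply/uptake balance.  The estimate is
        deliberately crude — it only needs to land in the basin of the
        established-population attractor, from which the integrator settles.
        The habitat is bistable under high influent virus: tiny inocula can
        collapse even where a large population persists, and the model's
        equilibrium analysis concerns the established branch.
        """
        A_eff = eco.A * (1.0 - strat.r / eco.E)
        pvals = np.arange(eco.P0, 2 * eco.P0)
        S = float(np.sum(1.0 / pvals))
        if A_eff <= 0:
            return cls.inoculum(eco)
        phi_star = S * eco.B / (A_eff * np.log(2.0))
        if phi_star >= eco.phi0 or eco.phi0 == 0:
            # growth cannot balance dilution even on fresh media: washout
            return cls.inoculum(eco)
        biomass = eco.B * (eco.phi0 - phi_star) / (eco.C * phi_star)
        n = np.zeros((eco.P0, eco.Q + 1))
        w = 1.0 / pvals.astype(float) ** 2
        counts = biomass * w / float(np.sum(pvals * w))
        n[:, 0] = counts
        psi = eco.psi0 * eco.B / (eco.B + eco.C * biomass)
        return cls(n=n, phi=phi_star, psi=psi)

    def copy(self) -> "ChemostatState":
        return ChemostatState(self.n.copy(), self.phi, self.psi, self.t)


@dataclass
class EquilibriumResult:
    """Pseudo-steady-state summary of one chemostat run."""

    N_star: float
    phi_star: float
    psi_star: float
    converged: bool
    extinct: bool
    t_end: float
    final_state: ChemostatState
    lysis_count_rate: float
    pcd_count_rate: float
    division_rate: float
    burst_rates: np.ndarray  # lysis events per unit time, indexed by q
    n_steps: int


def step(
    state: ChemostatState,
    eco: EcologyParams,
    strat: StrategyParams,
    dt: float,
    tables: Optional[RateTables] = None,
) -> ChemostatState:
    """Apply exactly one explicit-Euler update of size ``dt``.

    All fluxes are evaluated simultaneously from the start-of-step state;
    the PCD sweep runs last, so a cell whose concentration crosses the
    threshold during the step is removed before it can ever lyse.  Raises
    :class:`StepSizeError` when dt is too large for the current state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.validate(eco)
    tb = tables if tables is not None else RateTables(eco, strat)
    n = np.ascontiguousarray(state.n, dtype=np.float64).copy()
    new_n = np.zeros_like(n)
    lysq = np.zeros(eco.Q + 1)
    phi, psi, _qmax, _lys, _pcd, _div, _inf, ok, _N, _rmax = K.det_step(
        n, new_n, state.phi, state.psi, dt, tb.A_eff, eco.B, eco.C, eco.F,
        strat.r, eco.phi0, eco.psi0, tb.pvec, tb.lam, tb.det, tb.pcd,
        eco.Q, eco.Q, lysq, eco.Q)
    if not ok:
        raise StepSizeError(
            f"dt={dt:g} gives an exit probability above one for some state; "
            "reduce the step size")
    return ChemostatState(n=new_n, phi=phi, psi=psi, t=state.t + dt)


def run_to_equilibrium(
    eco: EcologyParams,
    strat: StrategyParams,
    init: "ChemostatState | str | None" = None,
    tol: float = 1e-4,
    t_max: float = 500.0,
    window: float = 1.0,
    cap: float = EXIT_PROB_CAP,
    max_steps: int = 200_000_000,
) -> EquilibriumResult:
    """Integrate the chemostat until the windowed mean population stabilises.

    The step size adapts so that no occupied state's total exit probability
    per step exceeds ``cap``.  Convergence is declared when consecutive
    sliding-window means of the total population N change by less than
    ``tol`` relatively; the window widens with elapsed time so that slow
    oscillations average out.  The reported ``N_star`` is the time-averaged N
    over the final window (0 when the population fell below the extinction
    floor).

    ``init`` may be a :class:`ChemostatState`, ``"established"`` (default:
    start from the estimated established population, the branch on which
    equilibria are studied) or ``"inoculum"`` (a single virus-free cell in
    fresh media).
    """
    tb = RateTables(eco, strat)
    if init is None or init == "established":
        st = ChemostatState.established(eco, strat)
    elif init == "inoculum":
        st = ChemostatState.inoculum(eco)
    elif isinstance(init, ChemostatState):
        st = init.copy()
    else:
        raise ValueError(f"unrecognised init {init!r}")
    st.validate(eco)
    n = np.ascontiguousarray(st.n, dtype=np.float64)
    burst = np.zeros(eco.Q + 1)
    n, phi, psi, t, status, N_bar, phi_bar, psi_bar, lys, pcd, div, steps = \
        K.integrate_det(
            n, st.phi, st.psi, tb.A_eff, eco.B, eco.C, eco.F, strat.r,
            eco.phi0, eco.psi0, tb.pvec, tb.lam, tb.det, tb.pcd, eco.Q,
            cap, tb.lam_ctrl_cap, st.t, st.t + t_max, window, tol,
            EXTINCTION_FLOOR, max_steps, burst)
    if not np.isfinite(n).all() or not np.isfinite([phi, psi, N_bar]).all():
        raise ArithmeticError(
            "non-finite chemostat state during integration "
            f"(t={t:g}, phi={phi:g}, psi={psi:g})")
    final = ChemostatState(n=n, phi=phi, psi=psi, t=t)
    extinct = status == K.STATUS_EXTINCT
    return EquilibriumResult(
        N_star=0.0 if extinct else float(N_bar),
        phi_star=float(phi_bar),
        psi_star=float(psi_bar),
        converged=status in (K.STATUS_CONVERGED, K.STATUS_EXTINCT),
        extinct=extinct,
        t_end=float(t),
        final_state=final,
        lysis_count_rate=float(lys),
        pcd_count_rate=float(pcd),
        division_rate=float(div),
        burst_rates=burst,
        n_steps=int(steps),
    )


def burst_size_distribution(result: EquilibriumResult) -> np.ndarray:
    """Histogram of lysis events per unit time over burst size q.

    The entries sum to the total lysis event rate; the support is contained
    in ``{1, ..., Q}`` (a cell can only lyse while it carries virus).  An
    all-zero histogram simply means no lysis occurs (e.g. at ``a = 1``).
    """
    hist = result.burst_rates.copy()
    hist[0] = 0.0
    return hist


def burst_modes(hist: np.ndarray, min_prominence: float = 0.05,
                smooth: int = 3) -> int:
    """Count modes of a burst-size histogram.

    The histogram is lightly smoothed with a moving average and local maxima
    are counted when their prominence (height above the deepest adjacent
    trough) exceeds ``min_prominence`` of the tallest peak.  Two or more
    modes indicate the two-peaked burst-size structure that arises when most
    of the population sits far below the lethal threshold yet lyses at a low
    rate, while a minority reaches the threshold.
    """
    from scipy.signal import find_peaks

    y = np.asarray(hist, dtype=float)
    if y.sum() <= 0:
        return 0
    if smooth > 1:
        kern = np.ones(smooth) / smooth
        y = np.convolve(y, kern, mode="same")
    # pad so that boundary maxima (e.g. a peak at q = Q) are detectable
    ypad = np.concatenate([[0.0], y, [0.0]])
    peaks, props = find_peaks(ypad, prominence=min_prominence * ypad.max())
    return int(len(peaks))


def expected_progeny(
    p: int,
    q: int,
    eco: EcologyParams,
    strat: StrategyParams,
    phi: float,
    psi: float,
) -> float:
    """Expected number of future divisions of one cell at ``(p, q)``.

    The ambient nutrient and virion concentrations are frozen and the focal
    cell follows the single-cell continuous-time Markov chain with growth,
    infection, replication, immunity, lysis and dilution; PCD is disabled
    for the focal cell (the quantity measures what a PCD event forgoes).
    Absorption happens through lysis or washout; each division contributes
    one progeny and restarts the cell at the newborn state ``(P0, 0)``.
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    if not eco.P0 <= p <= 2 * eco.P0 - 1 or not 0 <= q <= eco.Q:
        raise ValueError("state (p, q) out of range")
    if eco.B == 0 and psi == 0:
        raise ValueError(
            "with B=0 and psi=0 an uninfected cell is never absorbed and the "
            "expected progeny diverges")
    P0, Q = eco.P0, eco.Q
    g = eco.A * (1.0 - strat.r / eco.E) * phi
    nstate = P0 * (Q + 1)

    def idx(i, qq):
        return i * (Q + 1) + qq

    rho = (np.arange(Q + 1)[None, :] / Q) * (P0 / np.arange(P0, 2 * P0)[:, None])
    det = rho >= eco.T
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        lam = np.where(det, 0.0, (rho / (eco.T - rho)) ** eco.G)
    lam[:, 0] = 0.0

    A = lil_matrix((nstate, nstate))
    b = np.zeros(nstate)
    for i in range(P0):
        pv = P0 + i
        for qq in range(Q + 1):
            s = idx(i, qq)
            if det[i, qq]:
                A[s, s] = 1.0  # immediate lysis: value 0
                continue
            rates = []
            if i < P0 - 1:
                rates.append((g * pv, idx(i + 1, qq), 0.0))
            elif qq == 0:
                rates.append((g * pv, idx(0, 0), 1.0))  # division: +1 progeny
            if qq == 0 and psi > 0:
                rates.append((eco.C * psi * pv, idx(i, 1), 0.0))
            if qq < Q:
                rates.append((eco.F * qq, idx(i, qq + 1), 0.0))
            if qq >= 1 and strat.r > 0:
                rates.append((strat.r * pv, idx(i, qq - 1), 0.0))
            absorb = eco.B + lam[i, qq]
            R = absorb + sum(rt for rt, _, _ in rates)
            if R <= 0:
                raise ValueError(
                    f"state (p={pv}, q={qq}) has no outgoing transitions; "
                    "the expected progeny is undefined")
            A[s, s] = R
            for rt, dest, reward in rates:
                A[s, dest] -= rt
                b[s] += rt * reward
    V = spsolve(A.tocsr(), b)
    return float(V[idx(p - P0, q)])
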
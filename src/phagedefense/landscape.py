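"""Strategy-space exploration: fitness landscapes over (a, r) and scans.

Fitness of a defense strategy is the equilibrium population size the
strategy sustains in a given ecology.  A landscape is the matrix of
equilibrium sizes over a grid of PCD investments ``a`` and immunity
investments ``r``; its peak locates the optimal strategy, and the
*PCD-sensitivity*

    1 - N(a=0, r=r_opt) / N(a=a_opt, r=r_opt)

measures how much fitness is lost by giving up PCD entirely while keeping
the optimal immunity.  Landscapes with sensitivity >= 0.1 are classified
PCD-sensitive; the rest show a plateau running parallel to the PCD axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chemostat_core import run_to_equilibrium
from .params import EcologyParams, StrategyParams

__all__ = [
    "FitnessLandscape",
    "ScanResult",
    "sweep",
    "optimize",
    "pcd_sensitivity",
    "parameter_scan",
    "SENSITIVITY_THRESHOLD",
]

#: Landscapes at or above this PCD-sensitivity are classified PCD-sensitive.
SENSITIVITY_THRESHOLD = 0.1


@dataclass
class FitnessLandscape:
    eco: EcologyParams
    a_grid: np.ndarray
    r_grid: np.ndarray
    N: np.ndarray  # shape (len(a_grid), len(r_grid))
    converged: np.ndarray
    a_opt: float
    r_opt: float
    N_opt: float
    sensitivity: float = float("nan")
    sensitive: bool = False
    plateau: bool = False


@dataclass
class ScanResult:
    varied: str
    values: np.ndarray
    a_opt_series: np.ndarray
    r_opt_series: np.ndarray
    N_opt_series: np.ndarray
    sensitivity_series: np.ndarray
    extinct: np.ndarray
    #: per-pair differences of a_opt and r_opt/E between adjacent scan points
    a_opt_diffs: np.ndarray = field(default=None)
    rE_opt_diffs: np.ndarray = field(default=None)
    #: pair flagged when both neighbours are PCD-sensitive (>= 0.1)
    pair_sensitive: np.ndarray = field(default=None)


def _argmax_least_investment(N: np.ndarray) -> tuple[int, int]:
    """Index of the maximum of N; ties broken toward smaller a, then smaller r."""
    best = np.nanmax(N)
    cand = np.argwhere(N == best)
    # rows are a, columns are r; lexicographic order of argwhere already
    # prefers the smallest a index, then the smallest r index
    i, j = cand[0]
    return int(i), int(j)


def sweep(
    eco: EcologyParams,
    a_grid: Sequence[float],
    r_grid: Sequence[float],
    tol: float = 1e-4,
    t_max: float = 500.0,
) -> FitnessLandscape:
    """Evaluate the equilibrium population size over a strategy grid.

    The grid is augmented with ``a = 0`` when absent, because the
    PCD-sensitivity measure needs the no-PCD column at the optimal immunity.
    Cells that fail to converge within ``t_max`` enter the landscape with
    their last windowed mean and ``converged=False`` (the model's
    pseudo-steady-state convention).
    """
    a_grid = np.unique(np.concatenate([[0.0], np.asarray(a_grid, dtype=float)]))
    r_grid = np.unique(np.asarray(r_grid, dtype=float))
    if a_grid.min() < 0 or a_grid.max() > 1:
        raise ValueError("a grid must lie within [0, 1]")
    if r_grid.min() < 0 or r_grid.max() > eco.E:
        raise ValueError("r grid must lie within [0, E]")
    N = np.zeros((len(a_grid), len(r_grid)))
    conv = np.zeros_like(N, dtype=bool)
    for i, a in enumerate(a_grid):
        for j, r in enumerate(r_grid):
            res = run_to_equilibrium(eco, StrategyParams(a=a, r=r),
                                     tol=tol, t_max=t_max)
            N[i, j] = res.N_star
            conv[i, j] = res.converged
    i, j = _argmax_least_investment(N)
    land = FitnessLandscape(
        eco=eco, a_grid=a_grid, r_grid=r_grid, N=N, converged=conv,
        a_opt=float(a_grid[i]), r_opt=float(r_grid[j]), N_opt=float(N[i, j]))
    value, sensitive = pcd_sensitivity(land)
    land.sensitivity = value
    land.sensitive = sensitive
    # plateau: the a-profile at r_opt is flat (<1% of the peak) over at
    # least half of the a grid, making the argmax location unstable
    profile = N[:, j]
    if land.N_opt > 0:
        flat = np.abs(profile - land.N_opt) < 0.01 * land.N_opt
        land.plateau = bool(flat.mean() >= 0.5)
    return land


def pcd_sensitivity(
    land: FitnessLandscape, threshold: float = SENSITIVITY_THRESHOLD
) -> tuple[float, bool]:
    """PCD-sensitivity of a landscape and its classification.

    Returns ``(value, sensitive)`` with ``value = 1 - N(0, r_opt)/N_opt``.
    NaN (and False) when every strategy goes extinct.
    """
    if land.N_opt <= 0:
        return float("nan"), False
    i0 = int(np.argwhere(land.a_grid == 0.0)[0][0])
    j = int(np.argwhere(land.r_grid == land.r_opt)[0][0])
    value = 1.0 - land.N[i0, j] / land.N_opt
    # tolerate roundoff at the classification boundary
    return float(value), bool(value >= threshold - 1e-12)


def optimize(
    eco: EcologyParams,
    coarse: tuple[int, int] = (21, 21),
    refinements: int = 3,
    refine_size: tuple[int, int] = (9, 9),
    shrink: float = 5.0,
    tol: float = 1e-4,
    t_max: float = 500.0,
) -> dict:
    """Locate the optimal strategy by nested grid refinement.

    A coarse grid over the full strategy box ``[0, 1] x [0, E]`` is followed
    by ``refinements`` rounds on boxes shrunk ``shrink``-fold around the
    incumbent (which is always re-included, so the refined optimum can never
    be worse than the coarse one).  Ties break toward the least investment:
    smaller a, then smaller r.

    Returns a dict with ``a_opt, r_opt, N_opt, extinct, sensitivity,
    sensitive, landscape`` (the coarse landscape).
    """
    na, nr = coarse
    a_grid = np.linspace(0.0, 1.0, na)
    r_grid = np.linspace(0.0, eco.E, nr)
    land = sweep(eco, a_grid, r_grid, tol=tol, t_max=t_max)
    best_a, best_r, best_N = land.a_opt, land.r_opt, land.N_opt
    if best_N <= 0:
        return dict(a_opt=float("nan"), r_opt=float("nan"), N_opt=0.0,
                    extinct=True, sensitivity=float("nan"), sensitive=False,
                    landscape=land)
    wa = 1.0
    wr = eco.E
    nra, nrr = refine_size
    for _lvl in range(refinements):
        wa /= shrink
        wr /= shrink
        a_lo = min(max(best_a - wa / 2, 0.0), 1.0 - wa) if wa < 1 else 0.0
        r_lo = min(max(best_r - wr / 2, 0.0), eco.E - wr) if wr < eco.E else 0.0
        a_cand = np.unique(np.concatenate(
            [np.linspace(a_lo, a_lo + min(wa, 1.0), nra), [best_a]]))
        r_cand = np.unique(np.concatenate(
            [np.linspace(r_lo, r_lo + min(wr, eco.E), nrr), [best_r]]))
        for a in a_cand:
            for r in r_cand:
                if a == best_a and r == best_r:
                    continue
                res = run_to_equilibrium(eco, StrategyParams(a=float(a), r=float(r)),
                                         tol=tol, t_max=t_max)
                # strict improvement, or equal fitness at less investment
                if res.N_star > best_N or (
                        res.N_star == best_N and (a, r) < (best_a, best_r)):
                    best_a, best_r, best_N = float(a), float(r), res.N_star
    # sensitivity at the refined optimum
    res0 = run_to_equilibrium(eco, StrategyParams(a=0.0, r=best_r),
                              tol=tol, t_max=t_max)
    sens = 1.0 - res0.N_star / best_N if best_N > 0 else float("nan")
    return dict(a_opt=best_a, r_opt=best_r, N_opt=best_N, extinct=False,
                sensitivity=float(sens),
                sensitive=bool(sens >= SENSITIVITY_THRESHOLD - 1e-12),
                landscape=land)


_SCANNABLE = {"psi0", "C", "E", "F", "T", "G", "B"}


def parameter_scan(
    base: EcologyParams,
    varied: str,
    values: Sequence[float],
    hold_moi: bool = False,
    **optimize_kw,
) -> ScanResult:
    """Recompute the optimal strategy along a single-parameter scan.

    ``values`` must be sorted.  For scans of the virus replication rate F it
    is conventional to hold the extrinsic MOI ``C * psi0`` fixed, which is
    automatic since neither C nor psi0 is varied; ``hold_moi=True`` instead
    rescales psi0 to keep ``C * psi0`` at its base value when C is varied.
    Per-point extinction is recorded, not fatal.  Adjacent-point differences
    of ``a_opt`` and ``r_opt/E`` are reported with a flag marking pairs
    where both neighbours are PCD-sensitive, the regime in which optimum
    displacement is meaningful (elsewhere the optimum sits on a plateau).
    """
    if varied not in _SCANNABLE:
        raise ValueError(f"cannot scan {varied!r}; choose one of {sorted(_SCANNABLE)}")
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(values) <= 0):
        raise ValueError("scan values must be strictly increasing")
    n = len(values)
    a_s = np.full(n, np.nan)
    r_s = np.full(n, np.nan)
    N_s = np.zeros(n)
    sens = np.full(n, np.nan)
    ext = np.zeros(n, dtype=bool)
    for k, v in enumerate(values):
        kw = {varied: float(v)}
        if hold_moi and varied == "C":
            kw["psi0"] = base.extrinsic_moi / float(v)
        eco = base.replace(**kw)
        out = optimize(eco, **optimize_kw)
        a_s[k] = out["a_opt"]
        r_s[k] = out["r_opt"]
        N_s[k] = out["N_opt"]
        sens[k] = out["sensitivity"]
        ext[k] = out["extinct"]
    a_d = np.diff(a_s)
    rE_d = np.diff(r_s / base.E)
    pair = (sens[:-1] >= SENSITIVITY_THRESHOLD) & (sens[1:] >= SENSITIVITY_THRESHOLD)
    return ScanResult(
        varied=varied, values=values, a_opt_series=a_s, r_opt_series=r_s,
        N_opt_series=N_s, sensitivity_series=sens, extinct=ext,
        a_opt_diffs=a_d, rE_opt_diffs=rE_d, pair_sensitive=pair)
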
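"""Independent reference implementations used only by the test suite.

Everything here is written directly from the model's published update rules
and standard theory, deliberately structured differently from the package's
optimized kernels (gather-style loops, dense linear algebra, closed forms),
so that agreement is a meaningful check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def rho_of(p, q, P0, Q):
    return (q / Q) * (P0 / p)


def literal_step(n, phi, psi, eco, strat, dt):
    """One explicit-Euler update transcribed term by term.

    For every state (p, q) the growth, replication, immunity, dilution and
    lysis terms are evaluated from the start-of-step state; uninfected
    top-bin cells divide into two newborns; infected top-bin cells are
    arrested; only (p, 0) cells are infected, each consuming one virion;
    states at or above the lethal concentration lyse entirely within the
    step; the lysis probability of other states is capped so the total exit
    probability cannot exceed one; the PCD sweep deletes, last, every
    updated state above the genotype threshold without virion release.
    Returns (n_new, phi_new, psi_new).
    """
    P0, Q = eco.P0, eco.Q
    A_eff = eco.A * (1.0 - strat.r / eco.E)
    g = A_eff * phi

    def lam(p, q):
        rho = rho_of(p, q, P0, Q)
        if rho >= eco.T:
            return None  # deterministic lysis
        if rho == 0:
            return 0.0
        return (rho / (eco.T - rho)) ** eco.G

    def out_probs(p, q):
        """per-channel exit probabilities of state (p, q) for this dt"""
        i = p - P0
        probs = {}
        probs["dilution"] = eco.B * dt
        grow = 0.0
        if p < 2 * P0 - 1 or q == 0:
            grow = g * p * dt
        probs["growth"] = grow
        probs["infection"] = eco.C * psi * p * dt if q == 0 else 0.0
        probs["replication"] = eco.F * q * dt if q < Q else 0.0
        probs["immunity"] = strat.r * p * dt if q >= 1 else 0.0
        lv = lam(p, q)
        base = sum(probs.values())
        probs["lysis"] = min(lv * dt, max(1.0 - base, 0.0))
        return probs

    n_new = np.zeros_like(n, dtype=float)
    released = 0.0
    infected = 0.0
    for p in range(P0, 2 * P0):
        i = p - P0
        for q in range(Q + 1):
            nn = n[i, q]
            if nn == 0:
                continue
            if lam(p, q) is None:
                released += q * nn  # whole state bursts
                continue
            probs = out_probs(p, q)
            n_new[i, q] += nn * (1.0 - sum(probs.values()))
            if probs["growth"] > 0:
                if p < 2 * P0 - 1:
                    n_new[i + 1, q] += nn * probs["growth"]
                else:
                    n_new[0, 0] += 2.0 * nn * probs["growth"]
            if probs["infection"] > 0:
                n_new[i, 1] += nn * probs["infection"]
                infected += nn * probs["infection"]
            if probs["replication"] > 0:
                n_new[i, q + 1] += nn * probs["replication"]
            if probs["immunity"] > 0:
                n_new[i, q - 1] += nn * probs["immunity"]
            if probs["lysis"] > 0:
                released += q * nn * probs["lysis"]

    biomass = sum(p * n[p - P0, q]
                  for p in range(P0, 2 * P0) for q in range(Q + 1))
    phi_new = phi + ((eco.phi0 - phi) * eco.B - eco.C * phi * biomass) * dt
    psi_new = psi + (eco.psi0 - psi) * eco.B * dt - infected + released
    for p in range(P0, 2 * P0):
        for q in range(Q + 1):
            if rho_of(p, q, P0, Q) > 1.0 - strat.a:
                n_new[p - P0, q] = 0.0
    return n_new, max(phi_new, 0.0), max(psi_new, 0.0)


def virus_free_fixed_point(eco, strat):
    """Stationary state of the virus-free chemostat by root finding.

    At steady state the structured growth-division-dilution generator must
    have zero dominant eigenvalue, which pins the nutrient level phi*; the
    nutrient balance then gives the standing biomass, and the corresponding
    eigenvector the stationary volume distribution.  Returns (N_star,
    phi_star, counts_by_volume).
    """
    P0 = eco.P0
    A_eff = eco.A * (1.0 - strat.r / eco.E)
    if A_eff <= 0 or eco.phi0 <= 0:
        return 0.0, eco.phi0, np.zeros(P0)
    pv = np.arange(P0, 2 * P0, dtype=float)

    def growth_eig(phi):
        g = A_eff * phi
        M = np.zeros((P0, P0))
        for i in range(P0):
            M[i, i] -= g * pv[i] + eco.B
            if i < P0 - 1:
                M[i + 1, i] += g * pv[i]
            else:
                M[0, i] += 2.0 * g * pv[i]
        ev = np.linalg.eigvals(M)
        return float(np.max(ev.real))

    if growth_eig(eco.phi0) <= 0:
        return 0.0, eco.phi0, np.zeros(P0)  # washout even on fresh media
    phi_star = brentq(growth_eig, 1e-12 * eco.phi0, eco.phi0, xtol=1e-14)
    biomass = eco.B * (eco.phi0 - phi_star) / (eco.C * phi_star)
    g = A_eff * phi_star
    M = np.zeros((P0, P0))
    for i in range(P0):
        M[i, i] -= g * pv[i] + eco.B
        if i < P0 - 1:
            M[i + 1, i] += g * pv[i]
        else:
            M[0, i] += 2.0 * g * pv[i]
    ev, vec = np.linalg.eig(M)
    v = np.real(vec[:, np.argmax(ev.real)])
    v = np.abs(v)
    counts = v * biomass / float(np.dot(pv, v))
    return float(counts.sum()), float(phi_star), counts


def progeny_pure_birth(p, eco, strat, phi):
    """Closed-form expected divisions of an uninfected cell under uniform
    killing at rate B and no virus.

    The cell survives each volume bin j with probability
    g*j / (g*j + B); reaching division from volume p multiplies the
    survivals up the ladder, and from the newborn state the count renews:
    E0 = P/(1-P) with P the newborn's division probability.
    """
    P0 = eco.P0
    g = eco.A * (1.0 - strat.r / eco.E) * phi

    def reach(p_from):
        pr = 1.0
        for j in range(p_from, 2 * P0):
            pr *= g * j / (g * j + eco.B)
        return pr

    P_newborn = reach(P0)
    E0 = P_newborn / (1.0 - P_newborn)
    return reach(p) * (1.0 + E0)


def progeny_monte_carlo(p, q, eco, strat, phi, psi, n_traj, rng):
    """Monte-Carlo estimate of the expected divisions of a single cell.

    Simulates the continuous-time single-cell chain by competing
    exponential clocks; PCD is disabled for the focal cell.  Returns (mean,
    standard error).
    """
    P0, Q = eco.P0, eco.Q
    g = eco.A * (1.0 - strat.r / eco.E) * phi
    counts = np.empty(n_traj)
    for k in range(n_traj):
        pp, qq = p, q
        divisions = 0
        for _ in range(100000):
            rho = rho_of(pp, qq, P0, Q)
            if rho >= eco.T:
                break  # lysis
            rates = []
            if pp < 2 * P0 - 1 or qq == 0:
                rates.append(("grow", g * pp))
            if qq == 0 and psi > 0:
                rates.append(("infect", eco.C * psi * pp))
            if qq < Q:
                rates.append(("rep", eco.F * qq))
            if qq >= 1 and strat.r > 0:
                rates.append(("imm", strat.r * pp))
            lv = 0.0 if rho == 0 else (rho / (eco.T - rho)) ** eco.G
            rates.append(("lyse", lv))
            rates.append(("wash", eco.B))
            tot = sum(rv for _, rv in rates)
            u = rng.random() * tot
            acc = 0.0
            for name, rv in rates:
                acc += rv
                if u < acc:
                    ev = name
                    break
            if ev == "grow":
                if pp < 2 * P0 - 1:
                    pp += 1
                else:
                    divisions += 1
                    pp, qq = P0, 0
            elif ev == "infect":
                qq = 1
            elif ev == "rep":
                qq += 1
            elif ev == "imm":
                qq -= 1
            else:
                break  # lysis or washout
        counts[k] = divisions
    return float(counts.mean()), float(counts.std(ddof=1) / np.sqrt(n_traj))
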
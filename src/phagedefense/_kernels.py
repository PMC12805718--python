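"""Numba kernels for the chemostat update equations.

The state of one population is the matrix ``n[i, q]`` of cell counts, where
row ``i`` indexes cell volume ``p = P0 + i`` (``i = 0 .. P0-1``) and column
``q`` the intracellular virion count (``q = 0 .. Q``).  One explicit-Euler
step applies, simultaneously from the start-of-step state,

* growth flux ``A*(1-r/E)*phi*p`` from ``(p, q)`` to ``(p+1, q)``; at the top
  volume bin only uninfected cells (``q = 0``) leave, producing two newborns
  at ``(P0, 0)`` (division); infected top-bin cells are division-arrested;
* infection flux ``C*psi*p`` from ``(p, 0)`` to ``(p, 1)`` (superinfection
  exclusion: only virus-free cells ingest virus), each infection removing one
  virion from the pool;
* replication flux ``F*q`` from ``(p, q)`` to ``(p, q+1)``, saturating at Q;
* immunity flux ``r*p`` from ``(p, q)`` to ``(p, q-1)``;
* lysis at per-cell rate ``(rho/(T-rho))**G`` for ``rho < T`` releasing the
  ``q`` intracellular virions into the pool; at ``rho >= T`` the whole cell
  count of the state lyses within the step (probability one);
* dilution of every cell, the nutrient and the virion pool at rate ``B``
  (virions inside washed-out cells leave the system with them),

followed by a PCD sweep that deletes, without virion release, every cell
whose concentration ``rho = (q/Q)*(P0/p)`` exceeds the genotype's threshold
``1 - a``.

The same flux structure is realised stochastically by the tau-leap kernel,
which replaces each deterministic flux by a draw whose expectation equals the
deterministic value (sequential conditioned binomials, so that the channels
of one state never overdraw it).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Status codes returned by the integrators.
STATUS_CONVERGED = 0
STATUS_TMAX = 1
STATUS_EXTINCT = 2
STATUS_MAXSTEPS = 3


@njit(cache=True)
def _controller_dt(n, phi, psi, A_eff, B, C, F, r, pvec, lam, det, pcd,
                   Q, qmax, cap, lam_ctrl_cap):
    """Largest dt such that no occupied state's exit probability exceeds cap.

    Deterministic-lysis and PCD states are excluded (they are emptied with
    probability one by construction), as is the lysis rate itself: its
    per-step probability saturates at one, the correct limit for a
    near-certain event.  Scalar drains of the nutrient and virion pools are
    bounded as well.  ``lam_ctrl_cap`` is retained in the signature for
    call-site stability but no longer enters the bound.
    """
    P0 = n.shape[0]
    g = A_eff * phi
    rmax = B
    biom = 0.0
    biom0 = 0.0
    for i in range(P0):
        p = pvec[i]
        for q in range(qmax + 1):
            nn = n[i, q]
            if nn <= 0.0:
                continue
            biom += p * nn
            if q == 0:
                biom0 += p * nn
            if det[i, q] or pcd[i, q]:
                continue
            rloc = B
            if i < P0 - 1 or q == 0:
                rloc += g * p
            if q == 0:
                rloc += C * psi * p
            if q < Q:
                rloc += F * q
            if q >= 1:
                rloc += r * p
            # lysis is excluded: its per-step probability saturates at one,
            # which is the correct limit for a near-certain event
            if rloc > rmax:
                rmax = rloc
    rphi = B + C * biom
    rpsi = B + C * biom0
    if rphi > rmax:
        rmax = rphi
    if rpsi > rmax:
        rmax = rpsi
    return cap / rmax


@njit(cache=True)
def det_step(n, new_n, phi, psi, dt, A_eff, B, C, F, r, phi0, psi0,
             pvec, lam, det, pcd, Q, qmax, lysq, zero_to):
    """One explicit-Euler step.  Returns scalars and fills ``new_n``.

    ``lysq`` accumulates lysis events by intracellular load q (in cells, not
    rates); ``zero_to`` is the high-water mark of stale content in ``new_n``
    that must be cleared.  Returns (phi_new, psi_new, qmax_new, lys_ev,
    pcd_ev, div_ev, inf_ev, ok, N_new, rmax) where ok is False when dt was
    too large (an exit probability exceeded one, which would create negative
    counts) and rmax is the largest total exit rate of the *updated* state,
    from which the adaptive integrator derives the next step size.
    """
    P0 = n.shape[0]
    g = A_eff * phi
    qtop = qmax + 1
    if qtop > Q:
        qtop = Q
    zt = zero_to if zero_to > qtop else qtop
    if zt > Q:
        zt = Q
    for i in range(P0):
        for q in range(zt + 1):
            new_n[i, q] = 0.0
    ok = True
    inf_tot = 0.0
    rel_tot = 0.0
    lys_ev = 0.0
    div_ev = 0.0
    biom = 0.0
    for i in range(P0):
        p = pvec[i]
        for q in range(qmax + 1):
            nn = n[i, q]
            if nn <= 0.0:
                continue
            biom += p * nn
            if det[i, q]:
                # deterministic lysis: the whole state bursts this step
                lys_ev += nn
                rel_tot += q * nn
                lysq[q] += nn
                continue
            out = B * dt
            gr = 0.0
            if i < P0 - 1:
                gr = g * p * dt
            elif q == 0:
                gr = g * p * dt  # division outflux of the top bin
            out += gr
            infp = 0.0
            if q == 0:
                infp = C * psi * p * dt
                out += infp
            rep = 0.0
            if q < Q:
                rep = F * q * dt
                out += rep
            imm = 0.0
            if q >= 1:
                imm = r * p * dt
                out += imm
            if out > 1.0:
                ok = False
            lp = lam[i, q] * dt
            if lp > 1.0 - out:
                lp = 1.0 - out
                if lp < 0.0:
                    lp = 0.0
            out += lp
            new_n[i, q] += nn * (1.0 - out)
            if i < P0 - 1:
                new_n[i + 1, q] += nn * gr
            elif q == 0:
                dv = nn * gr
                div_ev += dv
                new_n[0, 0] += 2.0 * dv
            if infp > 0.0:
                ii = nn * infp
                new_n[i, 1] += ii
                inf_tot += ii
            if rep > 0.0:
                new_n[i, q + 1] += nn * rep
            if imm > 0.0:
                new_n[i, q - 1] += nn * imm
            if lp > 0.0:
                le = nn * lp
                lys_ev += le
                rel_tot += q * le
                lysq[q] += le
    phi_new = phi + dt * ((phi0 - phi) * B - C * phi * biom)
    psi_new = psi + dt * (psi0 - psi) * B - inf_tot + rel_tot
    if phi_new < 0.0:
        phi_new = 0.0
        ok = False
    if psi_new < 0.0:
        psi_new = 0.0
        ok = False
    # PCD sweep on the updated state; in the same pass collect the total
    # population, the occupancy ceiling and the exit-rate bound used by the
    # adaptive controller for the next step
    pcd_ev = 0.0
    qmax_new = 0
    N_new = 0.0
    g2 = A_eff * phi_new
    rmax = B
    biom2 = 0.0
    biom02 = 0.0
    for i in range(P0):
        p = pvec[i]
        for q in range(qtop + 1):
            v = new_n[i, q]
            if v <= 0.0:
                continue
            if pcd[i, q]:
                pcd_ev += v
                new_n[i, q] = 0.0
                continue
            N_new += v
            if q > qmax_new:
                qmax_new = q
            biom2 += p * v
            if q == 0:
                biom02 += p * v
            if det[i, q]:
                continue
            rloc = B
            if i < P0 - 1 or q == 0:
                rloc += g2 * p
            if q == 0:
                rloc += C * psi_new * p
            if q < Q:
                rloc += F * q
            if q >= 1:
                rloc += r * p
            if rloc > rmax:
                rmax = rloc
    rphi = B + C * biom2
    rpsi = B + C * biom02
    if rphi > rmax:
        rmax = rphi
    if rpsi > rmax:
        rmax = rpsi
    return phi_new, psi_new, qmax_new, lys_ev, pcd_ev, div_ev, inf_tot, ok, \
        N_new, rmax


@njit(cache=True)
def integrate_det(n, phi, psi, A_eff, B, C, F, r, phi0, psi0,
                  pvec, lam, det, pcd, Q, cap, lam_ctrl_cap,
                  t0, t_max, window0, tol, ext_floor, max_steps, lysq_rate):
    """Integrate to pseudo-steady state with adaptive dt and windowed means.

    Convergence: consecutive sliding-window means of the total population N
    differ by less than ``tol`` in relative terms.  The window starts at
    ``window0`` time units and widens as 5% of elapsed time so that slow
    oscillations are averaged over.  Returns the final state in-place plus
    ``(phi, psi, t, status, N_bar, phi_bar, psi_bar, lys_rate, pcd_rate,
    div_rate, n_steps)``; ``lysq_rate`` receives the last window's per-q
    lysis event rates.
    """
    P0 = n.shape[0]
    new_n = np.zeros_like(n)
    lysq = np.zeros(Q + 1)
    lysq_step = np.zeros(Q + 1)
    hw_buf = 0  # high-water mark of stale content in the scratch buffer
    # initial PCD sweep (a cell above threshold dies immediately) + occupancy
    qmax = 0
    for i in range(P0):
        for q in range(Q + 1):
            if n[i, q] > 0.0:
                if pcd[i, q]:
                    n[i, q] = 0.0
                elif q > qmax:
                    qmax = q
    t = t0
    window = window0
    w_t = 0.0
    w_N = 0.0
    w_phi = 0.0
    w_psi = 0.0
    w_lys = 0.0
    w_pcd = 0.0
    w_div = 0.0
    prev_mean = -1.0
    peak = 0.0
    decline = 0
    fast_decline = 0
    status = STATUS_TMAX
    N_bar = -1.0
    phi_bar = phi
    psi_bar = psi
    lys_rate = 0.0
    pcd_rate = 0.0
    div_rate = 0.0
    steps = 0
    dt = _controller_dt(n, phi, psi, A_eff, B, C, F, r, pvec, lam, det,
                        pcd, Q, qmax, cap, lam_ctrl_cap)
    while t < t_max:
        if steps >= max_steps:
            status = STATUS_MAXSTEPS
            break
        qtop = qmax + 1 if qmax + 1 < Q else Q
        for _retry in range(60):
            for q in range(qtop + 1):
                lysq_step[q] = 0.0
            phi_n, psi_n, qmax_n, lys, pcd_ev, div, inf, ok, N, rmax = \
                det_step(n, new_n, phi, psi, dt, A_eff, B, C, F, r, phi0,
                         psi0, pvec, lam, det, pcd, Q, qmax, lysq_step,
                         hw_buf)
            if ok:
                break
            dt *= 0.5
        for q in range(qtop + 1):
            lysq[q] += lysq_step[q]
        phi = phi_n
        psi = psi_n
        tmp = n
        n = new_n
        new_n = tmp
        hw_buf = qtop  # the old state buffer held content up to qtop
        qmax = qmax_n
        t += dt
        steps += 1
        w_t += dt
        w_N += N * dt
        w_phi += phi * dt
        w_psi += psi * dt
        w_lys += lys
        w_pcd += pcd_ev
        w_div += div
        dt = cap / rmax  # controller value for the next step
        if w_t >= window:
            mean = w_N / w_t
            phi_bar = w_phi / w_t
            psi_bar = w_psi / w_t
            lys_rate = w_lys / w_t
            pcd_rate = w_pcd / w_t
            div_rate = w_div / w_t
            for q in range(Q + 1):
                lysq_rate[q] = lysq[q] / w_t
                lysq[q] = 0.0
            N_bar = mean
            if mean > peak:
                peak = mean
            # extinct: below the absolute floor, or in a sustained steady
            # decline (>=6 consecutive windows each dropping >=5%) six
            # orders of magnitude below the population's own peak — far
            # beyond any observed transient overshoot of the initial state
            if mean < ext_floor or (decline >= 10 and mean < 1e-9 * peak) \
                    or (fast_decline >= 6 and mean < 1e-6 * peak):
                status = STATUS_EXTINCT
                N_bar = 0.0
                break
            if prev_mean >= 0.0:
                hi = mean if mean > prev_mean else prev_mean
                if hi > 0.0 and abs(mean - prev_mean) / hi < tol:
                    status = STATUS_CONVERGED
                    break
                if mean < prev_mean:
                    decline += 1
                    if mean < 0.95 * prev_mean:
                        fast_decline += 1
                    else:
                        fast_decline = 0
                else:
                    decline = 0
                    fast_decline = 0
            prev_mean = mean
            w_t = 0.0
            w_N = 0.0
            w_phi = 0.0
            w_psi = 0.0
            w_lys = 0.0
            w_pcd = 0.0
            w_div = 0.0
            window = window0 if window0 > 0.05 * t else 0.05 * t
    if N_bar < 0.0 and w_t > 0.0:
        # never closed a full window: report the partial-window averages
        N_bar = w_N / w_t
        phi_bar = w_phi / w_t
        psi_bar = w_psi / w_t
        lys_rate = w_lys / w_t
        pcd_rate = w_pcd / w_t
        div_rate = w_div / w_t
        for q in range(Q + 1):
            lysq_rate[q] = lysq[q] / w_t
    return n, phi, psi, t, status, N_bar, phi_bar, psi_bar, lys_rate, \
        pcd_rate, div_rate, steps


@njit(cache=True)
def _binom(n, p):
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    return np.random.binomial(n, p)


@njit(cache=True)
def tau_substep(n, new_n, phi, psi, dt, A_eff, B, C, F, r,
                pvec, lam, det, pcd, Q, qmax, lysq, zero_to):
    """Stochastic realisation of one step for a single genotype.

    Fluxes are drawn as sequential conditioned binomials so that the total
    outflow of a state never exceeds its count; each channel's expectation
    equals the deterministic flux.  Returns (qmax_new, inf_tot, rel_tot,
    lys_ev, pcd_ev, div_ev, biom, biom0); the caller updates the shared
    nutrient/virion pools from the realised totals of both genotypes.
    """
    P0 = n.shape[0]
    g = A_eff * phi
    qtop = qmax + 1
    if qtop > Q:
        qtop = Q
    zt = zero_to if zero_to > qtop else qtop
    if zt > Q:
        zt = Q
    for i in range(P0):
        for q in range(zt + 1):
            new_n[i, q] = 0
    inf_tot = 0
    rel_tot = 0
    lys_ev = 0
    div_ev = 0
    biom = 0.0
    biom0 = 0.0
    for i in range(P0):
        p = pvec[i]
        for q in range(qmax + 1):
            nn = n[i, q]
            if nn <= 0:
                continue
            biom += p * nn
            if q == 0:
                biom0 += p * nn
            if det[i, q]:
                lys_ev += nn
                rel_tot += q * nn
                lysq[q] += nn
                continue
            pB = B * dt
            pg = 0.0
            if i < P0 - 1 or q == 0:
                pg = g * p * dt
            pinf = 0.0
            if q == 0:
                pinf = C * psi * p * dt
            prep = 0.0
            if q < Q:
                prep = F * q * dt
            pimm = 0.0
            if q >= 1:
                pimm = r * p * dt
            base = pB + pg + pinf + prep + pimm
            plys = lam[i, q] * dt
            if plys > 1.0 - base:
                plys = 1.0 - base
                if plys < 0.0:
                    plys = 0.0
            rem = nn
            denom = 1.0
            # dilution
            k = _binom(rem, pB / denom)
            rem -= k
            denom -= pB
            # growth / division
            k = _binom(rem, pg / denom) if denom > 0.0 else 0
            if k > 0:
                if i < P0 - 1:
                    new_n[i + 1, q] += k
                else:
                    div_ev += k
                    new_n[0, 0] += 2 * k
            rem -= k
            denom -= pg
            # infection
            k = _binom(rem, pinf / denom) if denom > 0.0 else 0
            if k > 0:
                new_n[i, 1] += k
                inf_tot += k
            rem -= k
            denom -= pinf
            # replication
            k = _binom(rem, prep / denom) if denom > 0.0 else 0
            if k > 0:
                new_n[i, q + 1] += k
            rem -= k
            denom -= prep
            # immunity
            k = _binom(rem, pimm / denom) if denom > 0.0 else 0
            if k > 0:
                new_n[i, q - 1] += k
            rem -= k
            denom -= pimm
            # lysis
            k = _binom(rem, plys / denom) if denom > 0.0 else 0
            if k > 0:
                lys_ev += k
                rel_tot += q * k
                lysq[q] += k
            rem -= k
            new_n[i, q] += rem
    pcd_ev = 0
    qmax_new = 0
    for i in range(P0):
        for q in range(qtop + 1):
            v = new_n[i, q]
            if v <= 0:
                continue
            if pcd[i, q]:
                pcd_ev += v
                new_n[i, q] = 0
            elif q > qmax_new:
                qmax_new = q
    return qmax_new, inf_tot, rel_tot, lys_ev, pcd_ev, div_ev, biom, biom0


@njit(cache=True)
def integrate_tau(n_a, n_c, phi, psi,
                  A_eff_a, r_a, A_eff_c, r_c,
                  B, C, F, phi0, psi0,
                  pvec, lam, det, pcd_a, pcd_c, Q, cap, lam_ctrl_cap,
                  t0, duration, seed, rec_dt,
                  rec_t, rec_fa, rec_na, rec_nc):
    """Advance a two-genotype chemostat for ``duration`` with tau-leaping.

    Both genotypes share phi and psi.  Trajectory samples are written into
    the rec_* buffers every ``rec_dt``; returns (phi, psi, t, n_rec, steps).
    """
    np.random.seed(seed)
    P0 = n_a.shape[0]
    new_a = np.zeros_like(n_a)
    new_c = np.zeros_like(n_c)
    lysq = np.zeros(Q + 1)
    hw_a = 0
    hw_c = 0
    qmax_a = 0
    qmax_c = 0
    Na = 0
    Nc = 0
    for i in range(P0):
        for q in range(Q + 1):
            if pcd_a[i, q]:
                n_a[i, q] = 0
            if pcd_c[i, q]:
                n_c[i, q] = 0
            if n_a[i, q] > 0:
                Na += n_a[i, q]
                if q > qmax_a:
                    qmax_a = q
            if n_c[i, q] > 0:
                Nc += n_c[i, q]
                if q > qmax_c:
                    qmax_c = q
    t = t0
    t_end = t0 + duration
    next_rec = t0
    n_rec = 0
    steps = 0
    while t < t_end:
        if n_rec < rec_t.shape[0] and t >= next_rec:
            rec_t[n_rec] = t
            tot = Na + Nc
            rec_fa[n_rec] = Na / tot if tot > 0 else np.nan
            rec_na[n_rec] = Na
            rec_nc[n_rec] = Nc
            n_rec += 1
            next_rec += rec_dt
        dt_a = _controller_dt(n_a, phi, psi, A_eff_a, B, C, F, r_a, pvec, lam,
                              det, pcd_a, Q, qmax_a, cap, lam_ctrl_cap)
        dt_c = _controller_dt(n_c, phi, psi, A_eff_c, B, C, F, r_c, pvec, lam,
                              det, pcd_c, Q, qmax_c, cap, lam_ctrl_cap)
        dt = dt_a if dt_a < dt_c else dt_c
        if t + dt > t_end:
            dt = t_end - t
        qtop_a = qmax_a + 1 if qmax_a + 1 < Q else Q
        qtop_c = qmax_c + 1 if qmax_c + 1 < Q else Q
        qmax_a, inf_a, rel_a, _lys_a, _pcd_a, _div_a, biom_a, biom0_a = \
            tau_substep(n_a, new_a, phi, psi, dt, A_eff_a, B, C, F, r_a,
                        pvec, lam, det, pcd_a, Q, qmax_a, lysq, hw_a)
        qmax_c, inf_c, rel_c, _lys_c, _pcd_c, _div_c, biom_c, biom0_c = \
            tau_substep(n_c, new_c, phi, psi, dt, A_eff_c, B, C, F, r_c,
                        pvec, lam, det, pcd_c, Q, qmax_c, lysq, hw_c)
        tmp = n_a
        n_a = new_a
        new_a = tmp
        tmp = n_c
        n_c = new_c
        new_c = tmp
        hw_a = qtop_a
        hw_c = qtop_c
        phi = phi + dt * ((phi0 - phi) * B - C * phi * (biom_a + biom_c))
        if phi < 0.0:
            phi = 0.0
        psi = psi + dt * (psi0 - psi) * B - inf_a - inf_c + rel_a + rel_c
        if psi < 0.0:
            psi = 0.0
        Na = 0
        Nc = 0
        for i in range(P0):
            for q in range(qmax_a + 1):
                Na += n_a[i, q]
            for q in range(qmax_c + 1):
                Nc += n_c[i, q]
        t += dt
        steps += 1
    if n_rec < rec_t.shape[0]:
        rec_t[n_rec] = t
        tot = Na + Nc
        rec_fa[n_rec] = Na / tot if tot > 0 else np.nan
        rec_na[n_rec] = Na
        rec_nc[n_rec] = Nc
        n_rec += 1
    return n_a, n_c, phi, psi, t, n_rec, steps
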
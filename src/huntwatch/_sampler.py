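"""Adaptive Metropolis-within-Gibbs kernel for the NB trend model.

Hot path of :mod:`huntwatch.model`, JIT-compiled with numba.  Works on a
province x year array of counts with an observation mask, and a parameter
state laid out as

    [alpha, beta, u (R), v (P), gamma (T), sigma_u, sigma_v, sigma_gamma, theta]

with hard sum-to-zero constraints: u sums to zero over regions (the last
region absorbs proposals), v sums to zero within each constraint group
(per region for nested intercepts, globally for province-only), and the
random walk is anchored at gamma[0] = 0.

Internally time is centred at its training mean (tc), which decorrelates
alpha and beta; the caller converts the intercept back to the
first-training-year parameterisation.  Two extra joint proposals move along
the near-flat ridges the random walk creates (level: alpha vs gamma;
slope: beta vs gamma drift); they leave the likelihood invariant and are
essential for mixing.

Single-site Gaussian random-walk proposals with Robbins-Monro adaptation of
each site's log step size toward 44% acceptance during warmup; scales are
frozen afterwards so the post-warmup chain is a valid Markov chain.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TARGET_ACC = 0.44


@njit(cache=True)
def _dll_shift(y, obs, eta, theta, rows, delta):
    """Log-likelihood change when eta shifts by delta on given provinces."""
    out = 0.0
    P, T = y.shape
    for ri in range(rows.shape[0]):
        p = rows[ri]
        for t in range(T):
            if obs[p, t]:
                e = eta[p, t]
                out += y[p, t] * delta - (y[p, t] + theta) * (
                    math.log(theta + math.exp(e + delta)) - math.log(theta + math.exp(e))
                )
    return out


@njit(cache=True)
def run_chain(
    y,
    obs,
    region_index,
    region_rows_flat,
    region_rows_off,
    vfree_idx,
    vfree_partner,
    tc,
    use_linear,
    use_u,
    use_v,
    use_rw,
    mu_alpha,
    sd_alpha,
    sd_beta,
    hn_u,
    hn_v,
    hn_g,
    inv_theta_rate,
    n_warmup,
    n_draws,
    seed,
    init,
):
    """Run one chain; returns (draws, acc_rates).

    draws: (n_draws, 2 + R + P + T + 4) in the layout documented above
    (sigma/theta stored on their natural scale).
    """
    np.random.seed(seed)
    P, T = y.shape
    R = region_rows_off.shape[0] - 1
    m = vfree_idx.shape[0]

    alpha = init[0]
    beta = init[1]
    u = init[2 : 2 + R].copy()
    v = init[2 + R : 2 + R + P].copy()
    g = init[2 + R + P : 2 + R + P + T].copy()
    lsu = math.log(init[2 + R + P + T])
    lsv = math.log(init[2 + R + P + T + 1])
    lsg = math.log(init[2 + R + P + T + 2])
    lth = math.log(init[2 + R + P + T + 3])

    eta = np.empty((P, T))
    for p in range(P):
        for t in range(T):
            eta[p, t] = alpha + u[region_index[p]] + v[p] + beta * tc[t] + g[t]

    all_rows = np.arange(P)
    one_row = np.empty(1, dtype=np.int64)

    # adaptive log step sizes
    ls_alpha = math.log(0.02)
    ls_beta = math.log(0.01)
    ls_u = np.full(max(R - 1, 1), math.log(0.02))
    ls_v = np.full(max(m, 1), math.log(0.03))
    ls_g = np.full(max(T - 1, 1), math.log(0.02))
    ls_su = math.log(0.3)
    ls_sv = math.log(0.3)
    ls_sg = math.log(0.3)
    ls_th = math.log(0.15)
    ls_lev = math.log(0.02)
    ls_slo = math.log(0.01)
    ls_gsc = math.log(0.3)

    n_sites = 9 + max(R - 1, 0) + m + max(T - 1, 0)
    acc = np.zeros(n_sites)
    tries = np.zeros(n_sites)

    dim = 2 + R + P + T + 4
    draws = np.empty((n_draws, dim))

    total = n_warmup + n_draws
    for it in range(total):
        warm = it < n_warmup
        rm = (it + 1.0) ** -0.6 if warm else 0.0
        site = 0

        # ---- alpha ---------------------------------------------------
        step = math.exp(ls_alpha)
        d = np.random.normal(0.0, step)
        dll = _dll_shift(y, obs, eta, math.exp(lth), all_rows, d)
        dll += ((alpha - mu_alpha) ** 2 - (alpha + d - mu_alpha) ** 2) / (
            2.0 * sd_alpha * sd_alpha
        )
        ok = math.log(np.random.random()) < dll
        if ok:
            alpha += d
            for p in range(P):
                for t in range(T):
                    eta[p, t] += d
        tries[site] += 1
        acc[site] += 1.0 if ok else 0.0
        if warm:
            ls_alpha += rm * ((1.0 if ok else 0.0) - TARGET_ACC)
        site += 1

        # ---- beta ----------------------------------------------------
        if use_linear:
            step = math.exp(ls_beta)
            d = np.random.normal(0.0, step)
            theta = math.exp(lth)
            dll = 0.0
            for p in range(P):
                for t in range(T):
                    if obs[p, t]:
                        e = eta[p, t]
                        dd = d * tc[t]
                        dll += y[p, t] * dd - (y[p, t] + theta) * (
                            math.log(theta + math.exp(e + dd))
                            - math.log(theta + math.exp(e))
                        )
            dll += (beta**2 - (beta + d) ** 2) / (2.0 * sd_beta * sd_beta)
            ok = math.log(np.random.random()) < dll
            if ok:
                beta += d
                for p in range(P):
                    for t in range(T):
                        eta[p, t] += d * tc[t]
            tries[site] += 1
            acc[site] += 1.0 if ok else 0.0
            if warm:
                ls_beta += rm * ((1.0 if ok else 0.0) - TARGET_ACC)
        site += 1

        # ---- region effects u (last region absorbs) ------------------
        if use_u and R > 1:
            theta = math.exp(lth)
            su = math.exp(lsu)
            for r in range(R - 1):
                step = math.exp(ls_u[r])
                d = np.random.normal(0.0, step)
                dll = 0.0
                # region r shifts by +d
                for k in range(region_rows_off[r], region_rows_off[r + 1]):
                    p = region_rows_flat[k]
                    one_row[0] = p
                    dll += _dll_shift(y, obs, eta, theta, one_row, d)
                # last region shifts by -d
                for k in range(region_rows_off[R - 1], region_rows_off[R]):
                    p = region_rows_flat[k]
                    one_row[0] = p
                    dll += _dll_shift(y, obs, eta, theta, one_row, -d)
                dll += (u[r] ** 2 - (u[r] + d) ** 2) / (2.0 * su * su)
                dll += (u[R - 1] ** 2 - (u[R - 1] - d) ** 2) / (2.0 * su * su)
                ok = math.log(np.random.random()) < dll
                if ok:
                    u[r] += d
                    u[R - 1] -= d
                    for k in range(region_rows_off[r], region_rows_off[r + 1]):
                        p = region_rows_flat[k]
                        for t in range(T):
                            eta[p, t] += d
                    for k in range(region_rows_off[R - 1], region_rows_off[R]):
                        p = region_rows_flat[k]
                        for t in range(T):
                            eta[p, t] -= d
                tries[site] += 1
                acc[site] += 1.0 if ok else 0.0
                if warm:
                    ls_u[r] += rm * ((1.0 if ok else 0.0) - TARGET_ACC)
                site += 1
        else:
            site += max(R - 1, 0)

        # ---- province effects v (group partner absorbs) --------------
        if use_v and m > 0:
            theta = math.exp(lth)
            sv = math.exp(lsv)
            for j in range(m):
                p = vfree_idx[j]
                q = vfree_partner[j]
                step = math.exp(ls_v[j])
                d = np.random.normal(0.0, step)
                one_row[0] = p
                dll = _dll_shift(y, obs, eta, theta, one_row, d)
                one_row[0] = q
                dll += _dll_shift(y, obs, eta, theta, one_row, -d)
                dll += (v[p] ** 2 - (v[p] + d) ** 2) / (2.0 * sv * sv)
                dll += (v[q] ** 2 - (v[q] - d) ** 2) / (2.0 * sv * sv)
                ok = math.log(np.random.random()) < dll
                if ok:
                    v[p] += d
                    v[q] -= d
                    for t in range(T):
                        eta[p, t] += d
                        eta[q, t] -= d
                tries[site] += 1
                acc[site] += 1.0 if ok else 0.0
                if warm:
                    ls_v[j] += rm * ((1.0 if ok else 0.0) - TARGET_ACC)
                site += 1
        else:
            site += m

        # ---- random-walk states gamma[1..T-1] ------------------------
        if use_rw and T > 1:
            theta = math.exp(lth)
            sg = math.exp(lsg)
            for t in range(1, T):
                step = math.exp(ls_g[t - 1])
                d = np.random.normal(0.0, step)
                dll = 0.0
                for p in range(P):
                    if obs[p, t]:
                        e = eta[p, t]
                        dll += y[p, t] * d - (y[p, t] + theta) * (
                            math.log(theta + math.exp(e + d))
                            - math.log(theta + math.exp(e))
                        )
                inc1 = g[t] - g[t - 1]
                dll += (inc1**2 - (inc1 + d) ** 2) / (2.0 * sg * sg)
                if t + 1 < T:
                    inc2 = g[t + 1] - g[t]
                    dll += (inc2**2 - (inc2 - d) ** 2) / (2.0 * sg * sg)
                ok = math.log(np.random.random()) < dll
                if ok:
                    g[t] += d
                    for p in range(P):
                        eta[p, t] += d
                tries[site] += 1
                acc[site] += 1.0 if ok else 0.0
                if warm:
                    ls_g[t - 1] += rm * ((1.0 if ok else 0.0) - TARGET_ACC)
                site += 1
        else:
            site += T - 1

        # ---- level ridge: alpha + d, gamma[1..] - d ------------------
        if use_rw and T > 1:
            sg = math.exp(lsg)
            step = math.exp(ls_lev)
            d = np.random.normal(0.0, step)
            # likelihood invariant except year 0 (gamma[0] pinned): shift only
            # t >= 1 cells net zero <-> shift year-0 cells by +d
            theta = math.exp(lth)
            dll = 0.0
            for p in range(P):
                if obs[p, 0]:
                    e = eta[p, 0]
                    dll += y[p, 0] * d - (y[p, 0] + theta) * (
                        math.log(theta + math.exp(e + d))
                        - math.log(theta + math.exp(e))
                    )
            dll += ((alpha - mu_alpha) ** 2 - (alpha + d - mu_alpha) ** 2) / (
                2.0 * sd_alpha * sd_alpha
            )
            inc1 = g[1] - g[0]
            dll += (inc1**2 - (inc1 - d) ** 2) / (2.0 * sg * sg)
            ok = math.log(np.random.random()) < dll
            if ok:
                alpha += d
                for t in range(1, T):
                    g[t] -= d
                for p in range(P):
                    eta[p, 0] += d
            tries[site] += 1
            acc[site] += 1.0 if ok else 0.0
            if warm:
                ls_lev += rm * ((1.0 if ok else 0.0) - TARGET_ACC)
        site += 1

        # ---- slope ridge: beta + d, gamma drift - d ------------------
        if use_rw and use_linear and T > 1:
            sg = math.exp(lsg)
            step = math.exp(ls_slo)
            d = np.random.normal(0.0, step)
            # eta change: d*tc[t] - d*t = -d*(t - tc[t]) = -d*tbar (constant),
            # cancelled by alpha += d*tbar  => likelihood invariant
            tbar = tc[0] * -1.0  # tc[t] = t - tbar with t starting at 0
            dll = (beta**2 - (beta + d) ** 2) / (2.0 * sd_beta * sd_beta)
            a_new = alpha + d * tbar
            dll += ((alpha - mu_alpha) ** 2 - (a_new - mu_alpha) ** 2) / (
                2.0 * sd_alpha * sd_alpha
            )
            for t in range(1, T):
                inc = g[t] - g[t - 1]
                dll += (inc**2 - (inc - d) ** 2) / (2.0 * sg * sg)
            ok = math.log(np.random.random()) < dll
            if ok:
                beta += d
                alpha = a_new
                for t in range(1, T):
                    g[t] -= d * t
            tries[site] += 1
            acc[site] += 1.0 if ok else 0.0
            if warm:
                ls_slo += rm * ((1.0 if ok else 0.0) - TARGET_ACC)
        site += 1

        # ---- funnel move: scale gamma and sigma_gamma jointly --------
        # gamma -> c*gamma, log sigma_gamma -> +d with c = e^d keeps the
        # increment prior invariant (Jacobian cancels), so only the
        # likelihood, the half-normal on sigma and the log-scale Jacobian
        # change; this decorrelates the random-walk states from their scale.
        if use_rw and T > 1:
            step = math.exp(ls_gsc)
            d = np.random.normal(0.0, step)
            c = math.exp(d)
            theta = math.exp(lth)
            s_old = math.exp(lsg)
            s_new = math.exp(lsg + d)
            dll = 0.0
            for t in range(1, T):
                dt = g[t] * (c - 1.0)
                for p in range(P):
                    if obs[p, t]:
                        e = eta[p, t]
                        dll += y[p, t] * dt - (y[p, t] + theta) * (
                            math.log(theta + math.exp(e + dt))
                            - math.log(theta + math.exp(e))
                        )
            dll += (s_old * s_old - s_new * s_new) / (2.0 * hn_g * hn_g) + d
            ok = math.log(np.random.random()) < dll
            if ok:
                lsg += d
                for t in range(1, T):
                    dt = g[t] * (c - 1.0)
                    g[t] *= c
                    for p in range(P):
                        eta[p, t] += dt
            tries[site] += 1
            acc[site] += 1.0 if ok else 0.0
            if warm:
                ls_gsc += rm * ((1.0 if ok else 0.0) - TARGET_ACC)
        site += 1

        # ---- variance components (prior-only conditionals) -----------
        if use_u and R > 1:
            step = math.exp(ls_su)
            d = np.random.normal(0.0, step)
            s_old = math.exp(lsu)
            s_new = math.exp(lsu + d)
            su2 = 0.0
            for r in range(R):
                su2 += u[r] * u[r]
            dll = (
                -R * (lsu + d)
                - su2 / (2.0 * s_new * s_new)
                - s_new * s_new / (2.0 * hn_u * hn_u)
                + (lsu + d)
            ) - (
                -R * lsu
                - su2 / (2.0 * s_old * s_old)
                - s_old * s_old / (2.0 * hn_u * hn_u)
                + lsu
            )
            ok = math.log(np.random.random()) < dll
            if ok:
                lsu += d
            tries[site] += 1
            acc[site] += 1.0 if ok else 0.0
            if warm:
                ls_su += rm * ((1.0 if ok else 0.0) - TARGET_ACC)
        site += 1

        if use_v and m > 0:
            step = math.exp(ls_sv)
            d = np.random.normal(0.0, step)
            s_old = math.exp(lsv)
            s_new = math.exp(lsv + d)
            sv2 = 0.0
            for p in range(P):
                sv2 += v[p] * v[p]
            dll = (
                -P * (lsv + d)
                - sv2 / (2.0 * s_new * s_new)
                - s_new * s_new / (2.0 * hn_v * hn_v)
                + (lsv + d)
            ) - (
                -P * lsv
                - sv2 / (2.0 * s_old * s_old)
                - s_old * s_old / (2.0 * hn_v * hn_v)
                + lsv
            )
            ok = math.log(np.random.random()) < dll
            if ok:
                lsv += d
            tries[site] += 1
            acc[site] += 1.0 if ok else 0.0
            if warm:
                ls_sv += rm * ((1.0 if ok else 0.0) - TARGET_ACC)
        site += 1

        if use_rw and T > 1:
            step = math.exp(ls_sg)
            d = np.random.normal(0.0, step)
            s_old = math.exp(lsg)
            s_new = math.exp(lsg + d)
            sg2 = 0.0
            for t in range(1, T):
                inc = g[t] - g[t - 1]
                sg2 += inc * inc
            n_inc = T - 1
            dll = (
                -n_inc * (lsg + d)
                - sg2 / (2.0 * s_new * s_new)
                - s_new * s_new / (2.0 * hn_g * hn_g)
                + (lsg + d)
            ) - (
                -n_inc * lsg
                - sg2 / (2.0 * s_old * s_old)
                - s_old * s_old / (2.0 * hn_g * hn_g)
                + lsg
            )
            ok = math.log(np.random.random()) < dll
            if ok:
                lsg += d
            tries[site] += 1
            acc[site] += 1.0 if ok else 0.0
            if warm:
                ls_sg += rm * ((1.0 if ok else 0.0) - TARGET_ACC)
        site += 1

        # ---- dispersion theta ---------------------------------------
        step = math.exp(ls_th)
        d = np.random.normal(0.0, step)
        th_old = math.exp(lth)
        th_new = math.exp(lth + d)
        dll = 0.0
        for p in range(P):
            for t in range(T):
                if obs[p, t]:
                    yy = y[p, t]
                    mu = math.exp(eta[p, t])
                    dll += (
                        th_new * math.log(th_new)
                        - math.lgamma(th_new)
                        + math.lgamma(yy + th_new)
                        - (yy + th_new) * math.log(th_new + mu)
                    ) - (
                        th_old * math.log(th_old)
                        - math.lgamma(th_old)
                        + math.lgamma(yy + th_old)
                        - (yy + th_old) * math.log(th_old + mu)
                    )
        # prior: 1/theta ~ Exponential(inv_theta_rate), on log-theta scale
        dll += (-inv_theta_rate * math.exp(-(lth + d)) - (lth + d)) - (
            -inv_theta_rate * math.exp(-lth) - lth
        )
        ok = math.log(np.random.random()) < dll
        if ok:
            lth += d
        tries[site] += 1
        acc[site] += 1.0 if ok else 0.0
        if warm:
            ls_th += rm * ((1.0 if ok else 0.0) - TARGET_ACC)
        site += 1

        # ---- store ---------------------------------------------------
        if not warm:
            k = it - n_warmup
            draws[k, 0] = alpha
            draws[k, 1] = beta
            for r in range(R):
                draws[k, 2 + r] = u[r]
            for p in range(P):
                draws[k, 2 + R + p] = v[p]
            for t in range(T):
                draws[k, 2 + R + P + t] = g[t]
            draws[k, 2 + R + P + T] = math.exp(lsu)
            draws[k, 2 + R + P + T + 1] = math.exp(lsv)
            draws[k, 2 + R + P + T + 2] = math.exp(lsg)
            draws[k, 2 + R + P + T + 3] = math.exp(lth)

    rates = np.zeros(n_sites)
    for s in range(n_sites):
        rates[s] = acc[s] / tries[s] if tries[s] > 0 else np.nan
    return draws, rates
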
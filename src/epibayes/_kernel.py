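"""Compiled single-site Gibbs sweep with residual updating.

The whole chain runs inside one numba-jitted function so the per-effect
update costs O(N) with no Python overhead.  The kernel maintains the
residual vector eps = y - mu - Z theta incrementally; a full recomputation
every ``refresh`` iterations caps floating-point drift, and the maximum
deviation between the maintained and recomputed residual is tracked every
iteration and returned.

Randomness uses numba's internal legacy RNG, seeded once per chain, so a
chain is bit-reproducible given (seed, chain_id).
"""

import numpy as np
from numba import njit

__all__ = ["gibbs_chain"]


@njit(cache=True, fastmath=False)
def gibbs_chain(
    Zt,            # (M, N) transposed design, C-contiguous
    y,             # (N,)
    zjtz,          # (M,) column sums of squares
    group_of_col,  # (M,) int64
    C_flat,        # concatenated slab constants, group g at C_off[g]:C_off[g+1]
    C_off,         # (G+1,) int64
    prior_flat,    # concatenated Dirichlet priors (spike first), at P_off
    P_off,         # (G+1,) int64
    fix_pi,        # (G,) uint8; 1 = keep pi at its initial value
    v0,
    s0sq,
    iterations,
    burn_in,
    thin,
    rng_seed,
    sigma_eps_init,
    sigma_g_init,  # (G,)
    pi_init,       # same layout as prior_flat
    refresh,
    out_mu,        # (S,)
    out_seps,      # (S,)
    out_sg,        # (S, G)
    out_pi,        # (S, len(prior_flat))
    out_theta,     # (S, M)
    out_mix,       # (S, M) int8
):
    np.random.seed(rng_seed)
    M, N = Zt.shape
    G = sigma_g_init.shape[0]
    VAR_FLOOR = 1e-12

    mu = 0.0
    theta = np.zeros(M)
    mix = np.zeros(M, dtype=np.int8)
    sigma_eps = max(sigma_eps_init, VAR_FLOOR)
    sigma_g = np.empty(G)
    for g in range(G):
        sigma_g[g] = max(sigma_g_init[g], VAR_FLOOR)
    pi = pi_init.copy()

    eps = np.empty(N)
    for i in range(N):
        eps[i] = y[i] - mu

    order = np.arange(M)
    max_comp = 0
    for g in range(G):
        lc = C_off[g + 1] - C_off[g] + 1
        if lc > max_comp:
            max_comp = lc
    scores = np.empty(max_comp)
    weights = np.empty(max_comp)
    resid = np.empty(N)

    max_dev = 0.0
    save_row = 0

    for it in range(iterations):
        # ---- intercept: Normal(mean(eps + mu), sigma_eps / N)
        s = 0.0
        for i in range(N):
            s += eps[i]
        mu_new = np.random.normal(mu + s / N, np.sqrt(sigma_eps / N))
        d = mu - mu_new
        for i in range(N):
            eps[i] += d
        mu = mu_new

        # ---- shuffle the global update order (Fisher-Yates)
        for i in range(M - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp

        # ---- single-site effect updates with residual updating
        for t in range(M):
            j = order[t]
            g = group_of_col[j]
            old = theta[j]
            dot = 0.0
            for i in range(N):
                dot += Zt[j, i] * eps[i]
            zjty = dot + old * zjtz[j]

            c0 = C_off[g]
            L = C_off[g + 1] - c0
            p0 = P_off[g]
            scores[0] = np.log(pi[p0])
            best = scores[0]
            for l in range(1, L + 1):
                sig_l = sigma_g[g] * C_flat[c0 + l - 1]
                denom = sigma_eps + sig_l * zjtz[j]
                sc = (
                    np.log(pi[p0 + l])
                    - 0.5 * np.log1p(sig_l * zjtz[j] / sigma_eps)
                    + 0.5 * zjty * zjty * sig_l / (sigma_eps * denom)
                )
                scores[l] = sc
                if sc > best:
                    best = sc
            tot = 0.0
            for l in range(L + 1):
                w = np.exp(scores[l] - best)
                weights[l] = w
                tot += w
            u = np.random.random() * tot
            acc = 0.0
            sel = L  # guards against u landing past the last bin by rounding
            for l in range(L + 1):
                acc += weights[l]
                if u <= acc:
                    sel = l
                    break

            if sel == 0:
                new = 0.0
            else:
                sig_l = sigma_g[g] * C_flat[c0 + sel - 1]
                prec = zjtz[j] + sigma_eps / sig_l
                new = np.random.normal(zjty / prec, np.sqrt(sigma_eps / prec))
            mix[j] = sel
            diff = old - new
            if diff != 0.0:
                for i in range(N):
                    eps[i] += Zt[j, i] * diff
            theta[j] = new

        # ---- residual variance: scaled-inv-chi2(v0 + N, (eps'eps + v0 s0sq)/(v0+N))
        sse = 0.0
        for i in range(N):
            sse += eps[i] * eps[i]
        sigma_eps = (sse + v0 * s0sq) / max(np.random.chisquare(v0 + N), 1e-100)
        if sigma_eps < VAR_FLOOR:
            sigma_eps = VAR_FLOOR

        # ---- per-group variance and mixture proportions
        for g in range(G):
            c0 = C_off[g]
            L = C_off[g + 1] - c0
            p0 = P_off[g]
            Sg = 0.0
            mg = 0.0
            for l in range(L + 1):
                weights[l] = 0.0  # reuse as occupancy counts
            for j in range(M):
                if group_of_col[j] == g:
                    l = mix[j]
                    weights[l] += 1.0
                    if l != 0:
                        Sg += theta[j] * theta[j] / C_flat[c0 + l - 1]
                        mg += 1.0
            sigma_g[g] = (Sg + v0 * s0sq) / max(np.random.chisquare(v0 + mg), 1e-100)
            if sigma_g[g] < VAR_FLOOR:
                sigma_g[g] = VAR_FLOOR
            if fix_pi[g] == 0:
                tot = 0.0
                for l in range(L + 1):
                    gam = np.random.standard_gamma(prior_flat[p0 + l] + weights[l])
                    pi[p0 + l] = gam
                    tot += gam
                for l in range(L + 1):
                    pi[p0 + l] /= tot

        # ---- residual-drift tracking and periodic refresh
        for i in range(N):
            resid[i] = y[i] - mu
        for j in range(M):
            tj = theta[j]
            if tj != 0.0:
                for i in range(N):
                    resid[i] -= Zt[j, i] * tj
        dev = 0.0
        for i in range(N):
            a = abs(resid[i] - eps[i])
            if a > dev:
                dev = a
        if dev > max_dev:
            max_dev = dev
        if (it + 1) % refresh == 0:
            for i in range(N):
                eps[i] = resid[i]

        # ---- thinned post-burn-in storage
        if it >= burn_in and (it - burn_in + 1) % thin == 0:
            out_mu[save_row] = mu
            out_seps[save_row] = sigma_eps
            for g in range(G):
                out_sg[save_row, g] = sigma_g[g]
            for k in range(pi.shape[0]):
                out_pi[save_row, k] = pi[k]
            for j in range(M):
                out_theta[save_row, j] = theta[j]
                out_mix[save_row, j] = mix[j]
            save_row += 1

    return max_dev
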
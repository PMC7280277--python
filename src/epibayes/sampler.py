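"""Single-site Gibbs sampler over the grouped spike-and-slab posterior.

Two layers live here:

* plain-numpy conditional-draw functions (:func:`sample_intercept`,
  :func:`sample_effect`, ...) that state each full conditional explicitly
  and are convenient to test against closed forms and quadrature;
* :func:`run_chain`, which executes the same updates through the compiled
  kernel in :mod:`epibayes._kernel` for whole-chain speed.

Every effect update forms the partial residual ``ytilde = eps + Z_j theta_j``
implicitly, evaluates the marginal likelihood of the spike and of each slab,
samples a mixture assignment, and redraws the effect from its conjugate
normal conditional when a slab is selected.  Maintaining ``eps`` makes each
update O(N), so a full sweep is O(N * M).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernel import gibbs_chain
from .model import GroupedDesign, Hyperparams

__all__ = [
    "SamplerState",
    "ChainStore",
    "sample_intercept",
    "mixture_log_likelihoods",
    "selection_probabilities",
    "select_mixture",
    "sample_effect",
    "sample_group_variance",
    "sample_pi",
    "sample_residual_variance",
    "sample_scaled_inv_chi2",
    "run_chain",
    "run_chains",
    "INIT_SCALE_LADDER",
]

VAR_FLOOR = 1e-12

#: multiplicative perturbation of the initial variance components used to
#: give parallel chains overdispersed starting values
INIT_SCALE_LADDER = (0.5, 1.0, 2.0, 4.0)


@dataclass
class SamplerState:
    """Mutable state of one Gibbs chain.

    ``theta[j] == 0`` exactly when ``mix[j] == 0`` (the spike); ``eps`` is
    kept equal to ``y - mu - Z theta``.
    """

    mu: float
    theta: np.ndarray
    mix: np.ndarray
    sigma_g_sq: np.ndarray          # (G,)
    pi_g: list                      # per group, length L_g + 1, sums to 1
    sigma_eps_sq: float
    eps: np.ndarray

    @classmethod
    def initial(cls, design: GroupedDesign, init_scale: float = 1.0) -> "SamplerState":
        """All effects in the spike; half the phenotypic variance assigned to
        the residual and half split evenly across the groups.

        ``pi`` starts at the mean of its full conditional given the all-spike
        assignment, i.e. Dirichlet(prior + (M_g, 0, ..., 0)) — spike mass
        ~ M_g/(M_g+L+1).  Starting ``pi`` at the *prior* mean instead would
        contradict the all-spike state: with near-uniform mixture odds and
        weak slabs being almost likelihood-indifferent, most null columns
        enter the model in the very first sweep and the chain starts inside
        a degenerate massively-polygenic mode it then cannot leave.

        ``init_scale`` multiplies the variance components so parallel chains
        can start overdispersed.
        """
        var_y = design.y.var(ddof=1)
        G = len(design.groups)
        pi_g = []
        for g in design.groups:
            conc = g.dirichlet_prior.copy()
            conc[0] += g.m  # occupancy of the all-spike initial assignment
            pi_g.append(conc / conc.sum())
        return cls(
            mu=0.0,
            theta=np.zeros(design.m_total),
            mix=np.zeros(design.m_total, dtype=np.int8),
            sigma_g_sq=np.full(G, max(0.5 * var_y / G * init_scale, VAR_FLOOR)),
            pi_g=pi_g,
            sigma_eps_sq=max(0.5 * var_y * init_scale, VAR_FLOOR),
            eps=design.y.copy(),
        )


def sample_intercept(state: SamplerState, y: np.ndarray, rng: np.random.Generator) -> float:
    """Draw mu ~ Normal(mean(eps + mu_old), sigma_eps^2 / N) and update eps."""
    n = y.size
    if n == 0:
        raise ValueError("empty phenotype")
    mean = state.mu + state.eps.mean()
    mu_new = rng.normal(mean, np.sqrt(state.sigma_eps_sq / n))
    state.eps += state.mu - mu_new
    state.mu = mu_new
    return mu_new


def mixture_log_likelihoods(zj_ty, zj_tz, sigma_eps_sq, sigma_g_sq, C, pi) -> np.ndarray:
    """Log marginal score of the spike and each slab for one effect.

    Spike: ``log pi_0``.  Slab ``l`` with variance ``sig_l = sigma_g_sq*C_l``:

        log pi_l - 0.5*log(1 + sig_l*zj_tz/sigma_eps_sq)
                 + 0.5*zj_ty^2*sig_l / (sigma_eps_sq*(sigma_eps_sq + sig_l*zj_tz))

    which is the log of ``pi_l`` times the Gaussian marginal-likelihood ratio
    of slab ``l`` against the spike.
    """
    C = np.asarray(C, dtype=np.float64)
    pi = np.asarray(pi, dtype=np.float64)
    if zj_tz <= 0:
        raise ValueError("zj_tz must be positive")
    if sigma_eps_sq <= 0 or sigma_g_sq <= 0:
        raise ValueError("variances must be positive")
    if pi.size != C.size + 1:
        raise ValueError("pi must have length len(C)+1")
    with np.errstate(divide="ignore"):
        scores = np.empty(C.size + 1)
        scores[0] = np.log(pi[0])
        sig = sigma_g_sq * C
        scores[1:] = (
            np.log(pi[1:])
            - 0.5 * np.log1p(sig * zj_tz / sigma_eps_sq)
            + 0.5 * zj_ty**2 * sig / (sigma_eps_sq * (sigma_eps_sq + sig * zj_tz))
        )
    return scores


def selection_probabilities(log_scores: np.ndarray) -> np.ndarray:
    """p(l) = 1 / sum_j exp(score_j - score_l), via pairwise differences."""
    s = np.asarray(log_scores, dtype=np.float64)
    m = s.max()  # shifting by the max makes every pairwise difference <= 0
    if not np.isfinite(m):
        raise ValueError("all log-scores are -inf")
    w = np.exp(s - m)  # exp of the pairwise difference to the best score
    return w / w.sum()


def select_mixture(log_scores: np.ndarray, rng: np.random.Generator) -> int:
    """Sample a mixture index from the normalized score probabilities."""
    p = selection_probabilities(log_scores)
    tot = p.sum()
    if tot <= 0:
        raise ValueError("no mixture has positive probability")
    return int(rng.choice(p.size, p=p / tot))


def sample_effect(
    j: int,
    state: SamplerState,
    design: GroupedDesign,
    rng: np.random.Generator,
    Z: np.ndarray | None = None,
    group_of_col: np.ndarray | None = None,
    zjtz: np.ndarray | None = None,
) -> SamplerState:
    """Gibbs update of effect ``j`` (global column index) with residual updating.

    The optional ``Z``/``group_of_col``/``zjtz`` arguments let callers avoid
    re-concatenating the design matrix on every call.
    """
    if Z is None:
        Z = design.full_matrix()
    if j < 0 or j >= Z.shape[1]:
        raise KeyError(f"unknown column index {j}")
    if group_of_col is None:
        group_of_col = np.repeat(np.arange(len(design.groups)), [g.m for g in design.groups])
    if zjtz is None:
        zjtz = (Z**2).sum(axis=0)
    g = int(group_of_col[j])
    grp = design.groups[g]
    zj = Z[:, j]
    old = state.theta[j]
    zj_ty = zj @ state.eps + old * zjtz[j]

    scores = mixture_log_likelihoods(
        zj_ty, zjtz[j], state.sigma_eps_sq, state.sigma_g_sq[g], grp.C, state.pi_g[g]
    )
    sel = select_mixture(scores, rng)
    if sel == 0:
        new = 0.0
    else:
        sig_l = state.sigma_g_sq[g] * grp.C[sel - 1]
        prec = zjtz[j] + state.sigma_eps_sq / sig_l
        new = rng.normal(zj_ty / prec, np.sqrt(state.sigma_eps_sq / prec))
    if old != new:
        state.eps += zj * (old - new)
    state.theta[j] = new
    state.mix[j] = sel
    return state


def sample_scaled_inv_chi2(df: float, scale: float, rng: np.random.Generator, size=None):
    """Draw from the scaled inverse-chi-square distribution: df*scale/chi2_df.

    Chi-square draws at near-zero df can underflow to exactly zero; they are
    clipped at 1e-100 so the heavy upper tail stays finite.
    """
    return df * scale / np.maximum(rng.chisquare(df, size=size), 1e-100)


def sample_group_variance(
    effects_in_model: np.ndarray,
    c_of_effects: np.ndarray,
    m_g: int,
    hyper: Hyperparams,
    rng: np.random.Generator,
) -> float:
    """Draw sigma_g^2 from its conjugate scaled-inv-chi2 conditional.

    ``effects_in_model`` are the nonzero (slab) effect values in the group,
    ``c_of_effects`` the mixture constant of each, so the sufficient statistic
    is S_g = sum theta_j^2 / C_mix(j), identifying sigma_g^2 as the common
    scale of the slab variances.
    """
    if m_g < 0:
        raise ValueError("m_g must be nonnegative")
    theta = np.asarray(effects_in_model, dtype=np.float64)
    c = np.asarray(c_of_effects, dtype=np.float64)
    S_g = float((theta**2 / c).sum()) if theta.size else 0.0
    df = hyper.v0 + m_g
    scale = (S_g + hyper.v0 * hyper.s0sq) / df
    return max(float(sample_scaled_inv_chi2(df, scale, rng)), VAR_FLOOR)


def sample_pi(counts: np.ndarray, prior: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet(prior + counts) draw over the spike and slab proportions."""
    counts = np.asarray(counts, dtype=np.float64)
    prior = np.asarray(prior, dtype=np.float64)
    if counts.shape != prior.shape:
        raise ValueError("counts and prior must have the same length")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    return rng.dirichlet(prior + counts)


def sample_residual_variance(eps: np.ndarray, hyper: Hyperparams, rng: np.random.Generator) -> float:
    """Scaled-inv-chi2 draw with df = v0 + N, scale = (eps'eps + v0 s0sq)/(v0 + N)."""
    eps = np.asarray(eps, dtype=np.float64)
    n = eps.size
    if n < 1:
        raise ValueError("empty residual vector")
    df = hyper.v0 + n
    scale = (eps @ eps + hyper.v0 * hyper.s0sq) / df
    return max(float(sample_scaled_inv_chi2(df, scale, rng)), VAR_FLOOR)


# ---------------------------------------------------------------------------


@dataclass
class ChainStore:
    """Thinned posterior samples of one chain.

    ``theta``/``mix`` are dense (samples x columns); spike samples are exact
    zeros, which keeps posterior summaries trivial and serializes sparsely.
    """

    col_ids: list
    group_names: list
    group_of_col: np.ndarray
    mixture_constants: list        # per group, the slab constants C
    mu: np.ndarray                 # (S,)
    sigma_eps_sq: np.ndarray       # (S,)
    sigma_g_sq: np.ndarray         # (S, G)
    pi: list                       # per group: (S, L_g+1)
    theta: np.ndarray              # (S, M)
    mix: np.ndarray                # (S, M) int8
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.mu.size

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def group_columns(self, g: int) -> np.ndarray:
        return np.nonzero(self.group_of_col == g)[0]


def _pack_groups(design: GroupedDesign):
    C_flat = np.concatenate([g.C for g in design.groups])
    C_off = np.zeros(len(design.groups) + 1, dtype=np.int64)
    P_flat = np.concatenate([g.dirichlet_prior for g in design.groups])
    P_off = np.zeros(len(design.groups) + 1, dtype=np.int64)
    for i, g in enumerate(design.groups):
        C_off[i + 1] = C_off[i] + g.C.size
        P_off[i + 1] = P_off[i] + g.dirichlet_prior.size
    group_of_col = np.repeat(
        np.arange(len(design.groups), dtype=np.int64), [g.m for g in design.groups]
    )
    return C_flat, C_off, P_flat, P_off, group_of_col


def run_chain(
    design: GroupedDesign,
    iterations: int = 20_000,
    burn_in: int = 10_000,
    thin: int = 10,
    seed: int = 0,
    chain_id: int = 0,
    refresh: int = 100,
    init_scale: float = 1.0,
    fix_pi: dict | None = None,
) -> ChainStore:
    """Run one Gibbs chain and return its thinned post-burn-in samples.

    Fully reproducible given ``(seed, chain_id)``.  ``fix_pi`` maps a group
    name to a fixed mixture-proportion vector (spike first), bypassing the
    Dirichlet update for that group — useful for degenerate designs such as
    forcing every effect into the spike.
    """
    if not (iterations > burn_in >= 0):
        raise ValueError("need iterations > burn_in >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")

    C_flat, C_off, P_flat, P_off, group_of_col = _pack_groups(design)
    G = len(design.groups)
    M = design.m_total
    n_saved = (iterations - burn_in) // thin

    Zt = np.ascontiguousarray(design.full_matrix().T)
    zjtz = np.einsum("ji,ji->j", Zt, Zt)

    state0 = SamplerState.initial(design, init_scale=init_scale)
    pi_init = np.empty_like(P_flat)
    fix_flags = np.zeros(G, dtype=np.uint8)
    for i, g in enumerate(design.groups):
        sl = slice(P_off[i], P_off[i + 1])
        if fix_pi is not None and g.name in fix_pi:
            v = np.asarray(fix_pi[g.name], dtype=np.float64)
            if v.size != g.n_mixtures or np.any(v < 0):
                raise ValueError(f"invalid fixed pi for group {g.name!r}")
            pi_init[sl] = v / v.sum()
            fix_flags[i] = 1
        else:
            pi_init[sl] = state0.pi_g[i]

    rng_seed = int(np.random.SeedSequence([seed, chain_id]).generate_state(1)[0] % (2**31))

    out_mu = np.empty(n_saved)
    out_seps = np.empty(n_saved)
    out_sg = np.empty((n_saved, G))
    out_pi = np.empty((n_saved, P_flat.size))
    out_theta = np.empty((n_saved, M))
    out_mix = np.empty((n_saved, M), dtype=np.int8)

    max_dev = gibbs_chain(
        Zt, design.y, zjtz, group_of_col,
        C_flat, C_off, P_flat, P_off, fix_flags,
        design.hyper.v0, design.hyper.s0sq,
        iterations, burn_in, thin, rng_seed,
        state0.sigma_eps_sq, state0.sigma_g_sq, pi_init, refresh,
        out_mu, out_seps, out_sg, out_pi, out_theta, out_mix,
    )

    pi_list = [out_pi[:, P_off[i]:P_off[i + 1]].copy() for i in range(G)]
    return ChainStore(
        col_ids=design.col_ids,
        group_names=design.group_names(),
        group_of_col=group_of_col,
        mixture_constants=[g.C.copy() for g in design.groups],
        mu=out_mu,
        sigma_eps_sq=out_seps,
        sigma_g_sq=out_sg,
        pi=pi_list,
        theta=out_theta,
        mix=out_mix,
        meta={
            "seed": seed,
            "chain_id": chain_id,
            "iterations": iterations,
            "burn_in": burn_in,
            "thin": thin,
            "init_scale": init_scale,
            "max_residual_deviation": float(max_dev),
        },
    )


def run_chains(design: GroupedDesign, n_chains: int = 4, seed: int = 0, **kwargs) -> list:
    """Run several chains with overdispersed starting variances.

    Chain ``k`` multiplies the initial variance components by
    ``INIT_SCALE_LADDER[k % 4]`` and uses its own RNG stream derived from
    ``(seed, k)``.
    """
    return [
        run_chain(
            design,
            seed=seed,
            chain_id=k,
            init_scale=INIT_SCALE_LADDER[k % len(INIT_SCALE_LADDER)],
            **kwargs,
        )
        for k in range(n_chains)
    ]
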
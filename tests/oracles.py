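"""Independent oracles for the sampler tests.

These deliberately avoid the package's own update formulas: the mixture
marginal is obtained by 1-D numerical quadrature of the integrated
likelihood, and the multi-effect posterior by the exact closed-form
multivariate-normal conditional (all effects in one slab, variances fixed).
"""

import numpy as np
from scipy.integrate import quad


def log_marginal_ratio_quadrature(zj_ty, zj_tz, sigma_eps_sq, sig_l):
    """log of the slab/spike marginal-likelihood ratio by quadrature.

    Integrates exp((2 b zj_ty - b^2 zj_tz) / (2 sigma_eps_sq)) * N(b; 0, sig_l)
    over b, which is the ratio of int N(ytilde; Z_j b, s2 I) N(b; 0, sig_l) db
    to N(ytilde; 0, s2 I) with the common constant cancelled.
    """
    sd = np.sqrt(sig_l)

    def integrand(b):
        return (
            np.exp((2 * b * zj_ty - b * b * zj_tz) / (2 * sigma_eps_sq))
            * np.exp(-0.5 * (b / sd) ** 2)
            / (sd * np.sqrt(2 * np.pi))
        )

    val, _ = quad(integrand, -12 * sd, 12 * sd, limit=200)
    return np.log(val)


def exact_slab_posterior(Z, y, sigma_eps_sq, sig_l):
    """Exact N(m, V) conditional of all effects jointly in one slab.

    Precision = Z'Z / sigma_eps_sq + I / sig_l; m = V Z'y / sigma_eps_sq.
    """
    M = Z.shape[1]
    P = Z.T @ Z / sigma_eps_sq + np.eye(M) / sig_l
    V = np.linalg.inv(P)
    m = V @ (Z.T @ y) / sigma_eps_sq
    return m, V


def joint_conditional_sampler(Z, y, sigma_eps_sq, sig_l, n_draws, seed):
    """Brute-force sampler drawing all effects jointly from the exact
    multivariate conditional."""
    m, V = exact_slab_posterior(Z, y, sigma_eps_sq, sig_l)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(m, V, size=n_draws)


def batch_means_se(x, n_batches=40):
    """Monte-Carlo standard error of a (possibly autocorrelated) chain mean
    via non-overlapping batch means."""
    x = np.asarray(x)
    n = x.size // n_batches * n_batches
    batches = x[:n].reshape(n_batches, -1).mean(axis=1)
    return batches.std(ddof=1) / np.sqrt(n_batches)
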
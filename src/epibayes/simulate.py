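"""Synthetic methylation, genotype and phenotype generator.

The generative model emulates a whole-blood methylation array measured on a
mixture of K cell types:

* each individual's cell-type proportions are a Dirichlet draw whose
  concentration is ``sp * base_proportions`` — larger ``sp`` means cell
  composition varies less across individuals;
* a fraction ``p`` of probes are differentially methylated (DMPs): their
  cell-type mean levels are truncated-normal draws around the array base
  level with spread ``tau``, and each individual's cell-specific level
  varies around that mean with the same spread (``indiv_sd``), giving DMPs
  probe-specific biological variation on top of the shared cell-composition
  signal.  Non-DMPs sit at the base level in every cell type;
* the observed matrix adds i.i.d. measurement noise with sd ``vartheta``.

Phenotypes are linear in the probe (and optionally genotype) columns with
Gaussian effects; genotypes can be coupled to causal probes through a
binomial-logistic link so that SNPs tag methylation variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .model import standardize

__all__ = [
    "MethylSimParams",
    "SimulatedDataset",
    "simulate_methylation",
    "choose_causal_probes",
    "simulate_sparse_phenotype",
    "simulate_correlated_genotypes",
    "simulate_joint_phenotype",
    "scenario_grid",
]


@dataclass
class MethylSimParams:
    """Parameters of the methylation-array generator.

    Defaults reproduce the base simulation scenario: 2000 individuals,
    103,638 probes, five cell types, 15% DMPs with spread tau = 0.07,
    nearly-constant cell proportions (sp = 1000), measurement noise
    sd 0.01, and 100 causal probes explaining 60% of phenotypic variance.
    """

    n: int = 2000
    m: int = 103_638
    k: int = 5
    p: float = 0.15
    tau: float = 0.07
    sp: float = 1000.0
    vartheta: float = 0.01
    n_causal: int = 100
    ve: float = 0.6
    seed: int = 0
    base_level: float = 0.5
    base_proportions: np.ndarray | None = None
    indiv_sd: float | None = None  # None -> tau; 0 disables individual variation

    def __post_init__(self) -> None:
        if not (0 < self.p < 1):
            raise ValueError("p must be in (0, 1)")
        if self.tau <= 0 or self.sp <= 0 or self.vartheta < 0:
            raise ValueError("tau, sp must be positive and vartheta nonnegative")
        if not (0 <= self.ve < 1):
            raise ValueError("ve must be in [0, 1)")
        if self.n_causal > round(self.p * self.m):
            raise ValueError("n_causal exceeds the number of DMPs")
        if self.base_proportions is not None:
            bp = np.asarray(self.base_proportions, dtype=np.float64)
            if bp.size != self.k or np.any(bp <= 0):
                raise ValueError("base_proportions must be k positive values")
            object.__setattr__(self, "base_proportions", bp / bp.sum())


@dataclass
class SimulatedDataset:
    """Observed matrix plus the full generative truth."""

    O: np.ndarray                   # (N, M) observed methylation
    Mmat: np.ndarray                # (N, M) noiseless methylation
    R: np.ndarray                   # (N, K) cell proportions, rows sum to 1
    S: np.ndarray                   # (K, M) cell-type mean levels
    dmp_idx: np.ndarray             # DMP column indices
    params: MethylSimParams
    causal_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    beta: np.ndarray | None = None          # (M,) probe effects (0 off-support)
    y: np.ndarray | None = None
    X: np.ndarray | None = None             # optional genotypes (N, M_snp)
    beta_g: np.ndarray | None = None        # SNP effects
    meta: dict = field(default_factory=dict)


def _truncated_normal(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    """Exact rejection sampling of Normal(mean, sd^2) truncated to [0, 1].

    The means used here always lie inside [0, 1], so acceptance is >= 1/2
    and the redraw loop terminates quickly.
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=np.float64), size)
    out = rng.normal(mean, sd)
    bad = (out < 0.0) | (out > 1.0)
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd)
        bad = (out < 0.0) | (out > 1.0)
    return out


def _dirichlet_rows(rng: np.random.Generator, alpha: np.ndarray, n: int) -> np.ndarray:
    R = rng.dirichlet(alpha, size=n)
    # tiny concentrations can underflow every gamma draw in a row to zero
    bad = ~np.isfinite(R).all(axis=1) | (R.sum(axis=1) <= 0)
    while bad.any():
        R[bad] = rng.dirichlet(alpha, size=int(bad.sum()))
        bad = ~np.isfinite(R).all(axis=1) | (R.sum(axis=1) <= 0)
    return R


def simulate_methylation(params: MethylSimParams) -> SimulatedDataset:
    """Generate cell proportions, cell-type levels and the observed matrix."""
    rng = np.random.default_rng(params.seed)
    n, m, k = params.n, params.m, params.k
    base_prop = (
        params.base_proportions
        if params.base_proportions is not None
        else np.full(k, 1.0 / k)
    )
    R = _dirichlet_rows(rng, params.sp * base_prop, n)

    n_dmp = int(round(params.p * m))
    dmp_idx = np.sort(rng.choice(m, size=n_dmp, replace=False))

    S = np.full((k, m), params.base_level)
    S[:, dmp_idx] = _truncated_normal(rng, params.base_level, params.tau, (k, n_dmp))

    Mmat = R @ S
    indiv_sd = params.tau if params.indiv_sd is None else params.indiv_sd
    if indiv_sd > 0 and n_dmp > 0:
        # individual-level cell-specific levels around the cell-type means
        Mdmp = np.zeros((n, n_dmp))
        for kk in range(k):
            levels = _truncated_normal(rng, S[kk, dmp_idx], indiv_sd, (n, n_dmp))
            Mdmp += R[:, kk][:, None] * levels
        Mmat[:, dmp_idx] = Mdmp

    O = Mmat + rng.normal(0.0, params.vartheta, size=(n, m)) if params.vartheta > 0 else Mmat.copy()
    return SimulatedDataset(O=O, Mmat=Mmat, R=R, S=S, dmp_idx=dmp_idx, params=params)


def choose_causal_probes(
    ds: SimulatedDataset,
    n_causal: int,
    rng: np.random.Generator,
    confounding: str = "random",
) -> np.ndarray:
    """Pick the causal probe set from the DMPs.

    ``confounding='random'`` samples uniformly; ``'ranked'`` picks the DMPs
    whose observed columns are most correlated with the cell proportions
    (largest L2 norm of the K correlations), inducing stronger
    phenotype/cell-composition confounding.
    """
    if n_causal > ds.dmp_idx.size:
        raise ValueError("n_causal exceeds the number of DMPs")
    if confounding == "random":
        return np.sort(rng.choice(ds.dmp_idx, size=n_causal, replace=False))
    if confounding == "ranked":
        Oc = ds.O[:, ds.dmp_idx] - ds.O[:, ds.dmp_idx].mean(axis=0)
        Rc = ds.R - ds.R.mean(axis=0)
        o_sd = Oc.std(axis=0)
        r_sd = Rc.std(axis=0)
        cors = (Rc.T @ Oc) / (ds.O.shape[0] * np.outer(r_sd, np.where(o_sd > 0, o_sd, 1.0)))
        norm = np.linalg.norm(cors, axis=0)
        top = np.argsort(norm)[::-1][:n_causal]
        return np.sort(ds.dmp_idx[top])
    raise ValueError(f"unknown confounding mode {confounding!r}")


def simulate_sparse_phenotype(
    ds: SimulatedDataset,
    n_causal: int | None = None,
    ve: float | None = None,
    use_noisy: bool = False,
    seed: int = 0,
    sigma_beta_sq: float = 0.5 / 100,
    confounding: str = "random",
) -> SimulatedDataset:
    """Phenotype from a sparse set of causal probes explaining exactly ``ve``.

    Effects are drawn N(0, sigma_beta_sq) over the causal probes; the
    realized genetic-value vector (noiseless matrix by default, observed
    matrix when ``use_noisy``) is rescaled so its sample variance is exactly
    ``ve`` of the phenotypic variance, and the residual is orthogonalized to
    it, making the design value the exact generative truth.
    """
    params = ds.params
    n_causal = params.n_causal if n_causal is None else n_causal
    ve = params.ve if ve is None else ve
    rng = np.random.default_rng(seed)
    n, m = ds.O.shape

    beta = np.zeros(m)
    if n_causal == 0:
        y = rng.normal(size=n)
        y = (y - y.mean()) / y.std()
        return replace(ds, causal_idx=np.empty(0, dtype=np.int64), beta=beta, y=y,
                       meta={**ds.meta, "ve": 0.0, "use_noisy": use_noisy})

    causal = choose_causal_probes(ds, n_causal, rng, confounding)
    raw_beta = rng.normal(0.0, np.sqrt(sigma_beta_sq), size=n_causal)
    design_mat = ds.O if use_noisy else ds.Mmat
    g = design_mat[:, causal] @ raw_beta
    g = g - g.mean()
    g_sd = g.std()
    if g_sd <= 0:
        raise ValueError("degenerate genetic values; check the causal set")
    scale = np.sqrt(ve) / g_sd
    g *= scale
    beta[causal] = raw_beta * scale

    e = rng.normal(size=n)
    e = e - e.mean()
    if ve > 0:
        e -= g * (e @ g) / (g @ g)  # orthogonalize so Var(g)/Var(y) is exact
    e *= np.sqrt(1.0 - ve) / e.std()
    y = g + e
    return replace(
        ds,
        causal_idx=causal,
        beta=beta,
        y=y,
        meta={
            **ds.meta,
            "ve": ve,
            "use_noisy": use_noisy,
            "sigma_beta_sq": sigma_beta_sq,
            "beta_rescale": scale,
            "confounding": confounding,
        },
    )


def simulate_correlated_genotypes(
    ds: SimulatedDataset,
    c_range: tuple = (20.0, 25.0),
    seed: int = 0,
    m_snps: int | None = None,
    ensure_polymorphic: bool = True,
) -> np.ndarray:
    """Genotypes in {0,1,2} coupled to the causal probes.

    SNP ``j`` matching causal probe ``j`` is drawn
    ``Binomial(2, logistic(c*M_ij - 10))`` with ``c ~ Uniform(c_range)``
    per column, tying the allele count to that probe's methylation level.
    Remaining SNPs use independent base-level methylation draws, so they
    carry the same marginal allele-frequency spectrum but no coupling.

    With ``ensure_polymorphic`` (default) monomorphic columns are redrawn
    (finally flipping one entry) so downstream standardization never sees a
    constant column.
    """
    if ds.causal_idx.size == 0:
        raise ValueError("dataset has no causal probes; simulate a phenotype first")
    rng = np.random.default_rng(seed)
    n = ds.O.shape[0]
    m_snps = ds.O.shape[1] if m_snps is None else m_snps
    if m_snps < ds.causal_idx.size:
        raise ValueError("m_snps smaller than the causal probe count")
    params = ds.params

    X = np.empty((n, m_snps), dtype=np.int8)
    c_all = rng.uniform(c_range[0], c_range[1], size=m_snps)
    causal_cols = {int(j): rank for rank, j in enumerate(ds.causal_idx)}

    for j in range(m_snps):
        if j in causal_cols:
            levels = ds.Mmat[:, ds.causal_idx[causal_cols[j]]]
        else:
            levels = _truncated_normal(rng, params.base_level, params.tau, (n,))
        prob = expit(c_all[j] * levels - 10.0)
        col = rng.binomial(2, prob).astype(np.int8)
        if ensure_polymorphic:
            tries = 0
            while col.min() == col.max() and tries < 100:
                col = rng.binomial(2, prob).astype(np.int8)
                tries += 1
            if col.min() == col.max():
                i = int(rng.integers(n))
                col[i] = col[i] + 1 if col[i] < 2 else col[i] - 1
        X[:, j] = col
    return X


def simulate_joint_phenotype(
    ds: SimulatedDataset,
    X: np.ndarray,
    seed: int = 0,
    n_cpg: int = 100,
    n_large: int = 100,
    n_small: int = 900,
    var_cpg: float = 0.5,
    var_large: float = 0.2,
    var_small: float = 0.1,
    var_eps: float = 0.2,
) -> SimulatedDataset:
    """Phenotype with both methylation and genotype effects.

    ``y = O beta_cpg + X beta_g + eps`` over the standardized observed
    methylation and genotype matrices: ``n_cpg`` probe effects
    N(0, var_cpg/n_cpg) on the causal probes, ``n_large`` genotype effects
    N(0, var_large/n_large) on the SNP columns coupled to those probes,
    ``n_small`` effects N(0, var_small/n_small) on other SNPs, and
    eps ~ N(0, var_eps).  Component variances sum to 1 in expectation.
    Realized variance shares are recorded in ``meta``.
    """
    rng = np.random.default_rng(seed)
    n, m = ds.O.shape
    m_snps = X.shape[1]
    if ds.causal_idx.size < n_cpg:
        raise ValueError(f"need at least {n_cpg} causal probes")
    if m_snps < n_large + n_small:
        raise ValueError("genotype matrix too small for the stated effect counts")

    Os = standardize(ds.O)
    Xs = standardize(X.astype(np.float64))

    cpg_cols = ds.causal_idx[:n_cpg]
    beta = np.zeros(m)
    beta[cpg_cols] = rng.normal(0.0, np.sqrt(var_cpg / n_cpg), size=n_cpg)

    large_cols = cpg_cols  # SNPs coupled to causal probes share their index
    rest = np.setdiff1d(np.arange(m_snps), large_cols)
    small_cols = np.sort(rng.choice(rest, size=n_small, replace=False))
    beta_g = np.zeros(m_snps)
    if n_large > 0 and var_large > 0:
        beta_g[large_cols] = rng.normal(0.0, np.sqrt(var_large / n_large), size=n_large)
    if n_small > 0 and var_small > 0:
        beta_g[small_cols] = rng.normal(0.0, np.sqrt(var_small / n_small), size=n_small)

    g_cpg = Os @ beta
    g_snp = Xs @ beta_g
    eps = rng.normal(0.0, np.sqrt(var_eps), size=n)
    y = g_cpg + g_snp + eps
    var_y = y.var()
    return replace(
        ds,
        beta=beta,
        beta_g=beta_g,
        X=X,
        y=y,
        meta={
            **ds.meta,
            "share_cpg": float(g_cpg.var() / var_y),
            "share_snp": float(g_snp.var() / var_y),
            "share_eps": float(eps.var() / var_y),
            "cov_cpg_snp": float(np.cov(g_cpg, g_snp)[0, 1] / var_y),
        },
    )


def scenario_grid(replicates: int = 15) -> list:
    """The full factorial simulation grid: one axis varied at a time around
    the base scenario (p=0.15, tau=0.07, sp=1000, vartheta=0.01), each
    setting replicated; 17 settings x 15 replicates = 255 datasets.  The
    vartheta axis builds the phenotype on the *noisy* matrix (use_noisy)."""
    base = dict(p=0.15, tau=0.07, sp=1000.0, vartheta=0.01)
    settings = []
    for p in (0.1, 0.3, 0.7, 0.9):
        settings.append({**base, "p": p, "use_noisy": False})
    for tau in (0.01, 0.03, 0.05, 0.09):
        settings.append({**base, "tau": tau, "use_noisy": False})
    for sp in (0.001, 0.1, 1.0, 10.0, 1000.0):
        settings.append({**base, "sp": sp, "use_noisy": False})
    for vt in (0.01, 0.025, 0.05, 0.075):
        settings.append({**base, "vartheta": vt, "use_noisy": True})
    grid = []
    for si, s in enumerate(settings):
        for rep in range(replicates):
            grid.append({**s, "seed": si * 1000 + rep, "replicate": rep})
    return grid
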
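"""Data model for the grouped spike-and-slab mixture regression.

The regression is ``y = mu + Z theta + eps`` where the columns of ``Z`` are
partitioned into named covariate *groups* (e.g. SNP dosages, methylation
probes, fixed covariates such as age and sex).  Each group ``g`` carries its
own spike-and-slab mixture prior: an effect is either exactly zero (the
spike) or drawn from one of ``L_g`` zero-mean Gaussian slabs whose variances
are ``sigma_g^2 * C_l`` for a strictly increasing set of dimensionless
constants ``C``.  The mixture proportions ``pi_g`` (spike included) follow a
Dirichlet prior, and ``sigma_g^2`` and the residual variance follow weakly
informative scaled inverse-chi-square priors.

All covariate columns and the phenotype are centred and scaled to unit
sample variance before entering the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Hyperparams",
    "CovariateGroup",
    "GroupedDesign",
    "standardize",
    "standardize_phenotype",
]

# Tolerances for the standardization invariants.
_MEAN_TOL = 1e-10
_VAR_TOL = 1e-8


@dataclass(frozen=True)
class Hyperparams:
    """Scaled inverse-chi-square prior df ``v0`` and scale ``s0sq``.

    The defaults (0.001, 0.001) give an essentially flat prior on the
    variance components.
    """

    v0: float = 0.001
    s0sq: float = 0.001

    def __post_init__(self) -> None:
        if not (self.v0 > 0 and self.s0sq > 0):
            raise ValueError("v0 and s0sq must be strictly positive")


def standardize(raw_matrix: np.ndarray, col_ids=None) -> np.ndarray:
    """Centre and scale every column to mean 0 and sample variance 1.

    Missing values (NaN) are imputed with the column mean before scaling,
    which leaves the centred column mean at zero.  Sample variance uses the
    N-1 denominator.

    Raises
    ------
    ValueError
        If a column is constant (zero variance after imputation) or entirely
        missing.  The offending column id is included in the message.
    """
    X = np.asarray(raw_matrix, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    X = X.copy()
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least two rows to standardize")
    ids = list(col_ids) if col_ids is not None else list(range(m))

    nan_mask = np.isnan(X)
    if nan_mask.any():
        all_missing = nan_mask.all(axis=0)
        if all_missing.any():
            bad = ids[int(np.argmax(all_missing))]
            raise ValueError(f"column {bad!r} is entirely missing")
        col_means = np.nanmean(X, axis=0)
        X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])

    mean = X.mean(axis=0)
    X -= mean
    sd = X.std(axis=0, ddof=1)
    zero = sd <= 0
    if zero.any():
        bad = ids[int(np.argmax(zero))]
        raise ValueError(f"constant column {bad!r}")
    X /= sd
    return X


def standardize_phenotype(raw_y: np.ndarray) -> np.ndarray:
    """Centre the phenotype and scale it to unit sample variance."""
    y = np.asarray(raw_y, dtype=np.float64).ravel().copy()
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values")
    y -= y.mean()
    sd = y.std(ddof=1)
    if sd <= 0:
        raise ValueError("phenotype is constant")
    return y / sd


@dataclass
class CovariateGroup:
    """A named block of standardized covariate columns with its mixture prior.

    Parameters
    ----------
    name:
        Group label (unique within a design).
    Z:
        (N, M_g) matrix; columns must already be centred/unit-variance
        (see :func:`standardize`).
    C:
        Strictly increasing, positive mixture-variance constants; slab ``l``
        has prior variance ``sigma_g^2 * C[l-1]``.
    col_ids:
        Column identifiers; defaults to ``name:0 .. name:M_g-1``.
    dirichlet_prior:
        Concentration vector of length ``len(C) + 1`` (spike first).
        Defaults to all ones.
    """

    name: str
    Z: np.ndarray
    C: np.ndarray
    col_ids: list = None
    dirichlet_prior: np.ndarray = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if self.Z.ndim != 2:
            raise ValueError("Z must be 2-dimensional")
        self.C = np.asarray(self.C, dtype=np.float64).ravel()
        if self.C.size == 0 or np.any(self.C <= 0):
            raise ValueError("mixture constants C must be positive")
        if np.any(np.diff(self.C) <= 0):
            raise ValueError("mixture constants C must be strictly increasing")
        if self.col_ids is None:
            self.col_ids = [f"{self.name}:{j}" for j in range(self.Z.shape[1])]
        else:
            self.col_ids = list(self.col_ids)
        if len(self.col_ids) != self.Z.shape[1]:
            raise ValueError("col_ids length does not match Z columns")
        if self.dirichlet_prior is None:
            self.dirichlet_prior = np.ones(self.C.size + 1)
        self.dirichlet_prior = np.asarray(self.dirichlet_prior, dtype=np.float64).ravel()
        if self.dirichlet_prior.size != self.C.size + 1:
            raise ValueError(
                "dirichlet_prior must have length len(C)+1 (spike + slabs)"
            )
        if np.any(self.dirichlet_prior <= 0):
            raise ValueError("dirichlet_prior entries must be positive")
        self._check_standardized()

    def _check_standardized(self) -> None:
        means = self.Z.mean(axis=0)
        if np.any(np.abs(means) >= _MEAN_TOL):
            j = int(np.argmax(np.abs(means)))
            raise ValueError(
                f"column {self.col_ids[j]!r} not centred (mean {means[j]:.3g})"
            )
        var = self.Z.var(axis=0, ddof=1)
        if np.any(np.abs(var - 1.0) >= _VAR_TOL):
            j = int(np.argmax(np.abs(var - 1.0)))
            raise ValueError(
                f"column {self.col_ids[j]!r} not unit variance (var {var[j]:.6g})"
            )

    @property
    def n_mixtures(self) -> int:
        """Number of mixture components including the spike."""
        return self.C.size + 1

    @property
    def m(self) -> int:
        return self.Z.shape[1]


@dataclass
class GroupedDesign:
    """Standardized phenotype plus an ordered list of covariate groups."""

    y: np.ndarray
    groups: list
    hyper: Hyperparams = field(default_factory=Hyperparams)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        n = self.y.size
        if not self.groups:
            raise ValueError("at least one covariate group is required")
        seen = set()
        for g in self.groups:
            if g.Z.shape[0] != n:
                raise ValueError(
                    f"group {g.name!r} has {g.Z.shape[0]} rows, phenotype has {n}"
                )
            for cid in g.col_ids:
                if cid in seen:
                    raise ValueError(f"duplicate column id {cid!r}")
                seen.add(cid)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def m_total(self) -> int:
        return sum(g.m for g in self.groups)

    @property
    def col_ids(self) -> list:
        out = []
        for g in self.groups:
            out.extend(g.col_ids)
        return out

    def group_names(self) -> list:
        return [g.name for g in self.groups]

    def full_matrix(self) -> np.ndarray:
        """Concatenated (N, M_total) design matrix in group order."""
        return np.concatenate([g.Z for g in self.groups], axis=1)
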
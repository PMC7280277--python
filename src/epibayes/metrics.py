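"""Benchmark metrics comparing estimated probe effects against simulation truth.

The suite covers effect-recovery accuracy (correlation, regression slope,
MSE), discovery quality (selected loci, FDR), cell-type-confounding
diagnostics (norm of the correlation between the probe predictor and the
cell proportions; correlation of the leading principal component with the
effect error lifted to individual space) and the estimated probe-variance
share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["BenchmarkReport", "evaluate_estimates"]


@dataclass
class BenchmarkReport:
    rho: float        # correlation of true and estimated effects
    slope: float      # slope of regressing estimates on truth
    loci: int         # number of selected probes
    mse: float        # MSE over all effects
    mse_sig: float    # MSE over the selected probes (nan if none)
    fdr: float        # false discovery rate of the selected set
    cellnorm: float   # || cor(g_hat, R_k) ||_2 over cell types
    pcnorm: float     # | cor(PC1(O), O (beta_hat - beta)) |
    sigma_cg: float   # estimated probe-attributable variance fraction

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _safe_corr(a: np.ndarray, b: np.ndarray, what: str) -> float:
    if a.std() == 0 or b.std() == 0:
        warnings.warn(f"zero variance in {what}; correlation set to 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_estimates(
    beta_true: np.ndarray,
    beta_hat: np.ndarray,
    selected,
    O: np.ndarray,
    R: np.ndarray,
    sigma_cg_hat: float = np.nan,
) -> BenchmarkReport:
    """Compute the full benchmark report.

    ``selected`` holds the column indices called trait-associated (typically
    those with posterior inclusion probability > 0.95); FDR counts the
    selected probes that are not truly causal, over max(1, #selected).
    """
    beta_true = np.asarray(beta_true, dtype=np.float64).ravel()
    beta_hat = np.asarray(beta_hat, dtype=np.float64).ravel()
    if beta_true.shape != beta_hat.shape:
        raise ValueError("effect vectors differ in length")
    if O.shape[1] != beta_true.size:
        raise ValueError("O has the wrong number of columns")
    if O.shape[0] != R.shape[0]:
        raise ValueError("O and R differ in rows")
    selected = np.asarray(sorted(set(int(j) for j in np.atleast_1d(selected))), dtype=np.int64) \
        if np.size(selected) else np.empty(0, dtype=np.int64)

    rho = _safe_corr(beta_true, beta_hat, "effects")
    var_true = beta_true.var(ddof=1)
    slope = float(np.cov(beta_true, beta_hat)[0, 1] / var_true) if var_true > 0 else np.nan
    mse = float(np.mean((beta_true - beta_hat) ** 2))
    mse_sig = (
        float(np.mean((beta_true[selected] - beta_hat[selected]) ** 2))
        if selected.size
        else float("nan")
    )

    causal = set(np.nonzero(beta_true != 0)[0].tolist())
    false = sum(1 for j in selected if int(j) not in causal)
    fdr = false / max(1, selected.size)

    g_hat = O @ beta_hat
    if g_hat.std() == 0:
        warnings.warn("zero-variance predictor; cellnorm set to 0")
        cellnorm = 0.0
    else:
        cors = [_safe_corr(g_hat, R[:, k], f"cell proportion {k}") for k in range(R.shape[1])]
        cellnorm = float(np.linalg.norm(cors))

    # effect error lifted to individual space, against the leading PC of O
    err_indiv = O @ (beta_hat - beta_true)
    pc1 = PCA(n_components=1).fit_transform(O - O.mean(axis=0)).ravel()
    pcnorm = abs(_safe_corr(pc1, err_indiv, "effect error"))

    return BenchmarkReport(
        rho=rho,
        slope=slope,
        loci=int(selected.size),
        mse=mse,
        mse_sig=mse_sig,
        fdr=float(fdr),
        cellnorm=cellnorm,
        pcnorm=pcnorm,
        sigma_cg=float(sigma_cg_hat),
    )
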
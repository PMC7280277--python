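"""Phenotypic prediction from posterior-mean effects.

The predictor is the posterior mean of every effect (spike samples count as
zero) multiplied into the target cohort's centred-and-scaled marker
readings; accuracy is the squared correlation with the target phenotype,
plus the slope (and SE) of regressing the phenotype on the predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sampler import ChainStore

__all__ = ["build_predictor", "evaluate_prediction", "PredictionReport"]

log = logging.getLogger(__name__)


def build_predictor(chain: ChainStore) -> pd.Series:
    """Posterior-mean effect per column (zeros for never-in-model columns)."""
    if chain.n_samples < 1:
        raise ValueError("empty chain")
    return pd.Series(chain.theta.mean(axis=0), index=chain.col_ids, name="effect")


@dataclass
class PredictionReport:
    r2: float
    adj_r2: float
    slope: float
    slope_se: float
    n: int
    dropped_effect_mass: float  # sum |effect| of training columns absent in target


def evaluate_prediction(
    effects: pd.Series,
    new_Z,
    new_y: np.ndarray,
    col_ids=None,
    adjusted: bool = False,
) -> PredictionReport:
    """Score the posterior-mean predictor on a target cohort.

    ``new_Z`` must be standardized within the target cohort and ``new_y``
    centred/scaled.  If ``new_Z`` is a DataFrame (or ``col_ids`` is given),
    effects are aligned by column id and training effects missing from the
    target are dropped, with the lost absolute effect mass logged.
    """
    if isinstance(new_Z, pd.DataFrame):
        col_ids = list(new_Z.columns)
        new_Z = new_Z.to_numpy(dtype=np.float64)
    new_Z = np.asarray(new_Z, dtype=np.float64)
    new_y = np.asarray(new_y, dtype=np.float64).ravel()

    if col_ids is not None:
        aligned = effects.reindex(col_ids)
        missing = set(effects.index) - set(col_ids)
        dropped = float(effects.loc[sorted(missing)].abs().sum()) if missing else 0.0
        if dropped > 0:
            log.warning(
                "dropping %d training columns absent from target (|effect| mass %.4g)",
                len(missing), dropped,
            )
        beta = aligned.fillna(0.0).to_numpy()
    else:
        beta = effects.to_numpy()
        dropped = 0.0
    if new_Z.shape[1] != beta.size:
        raise ValueError("effect vector does not match target matrix columns")
    if new_Z.shape[0] != new_y.size:
        raise ValueError("target matrix and phenotype differ in rows")

    g = new_Z @ beta
    n = new_y.size
    if g.std() == 0:
        return PredictionReport(0.0, 0.0, float("nan"), float("nan"), n, dropped)

    r = np.corrcoef(g, new_y)[0, 1]
    r2 = float(r**2)
    adj = float(1 - (1 - r2) * (n - 1) / (n - 2)) if n > 2 else float("nan")
    fit = sm.OLS(new_y, sm.add_constant(g)).fit()
    return PredictionReport(
        r2=adj if adjusted else r2,
        adj_r2=adj,
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        n=n,
        dropped_effect_mass=dropped,
    )
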
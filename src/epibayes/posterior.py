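"""Posterior summaries: inclusion probabilities, variance partitioning,
convergence diagnostics, and whole-genome term enrichment with a ROPE rule.

Enrichment works on the full posterior over effects rather than on a
thresholded hit list: in every saved sample, a term's share of in-model
effect variance (p.PVE) is compared with its share of in-model mapped
probes (p.Term); the ratio is the term's enrichment for that sample.  A
term is called enriched only if its inclusion probability exceeds a
threshold AND 95% of its enrichment posterior lies outside the region of
practical equivalence, on one side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampler import ChainStore

__all__ = [
    "AnnotationMap",
    "EnrichmentPosterior",
    "compute_pip",
    "partition_variance",
    "mixture_variance_decomposition",
    "geweke_z",
    "convergence_diagnostics",
    "term_enrichment",
    "rope_decision",
]


def compute_pip(chain: ChainStore) -> pd.Series:
    """Posterior inclusion probability per column: the fraction of saved
    samples in which the effect is in any slab (mixture index != 0)."""
    if chain.n_samples < 1:
        raise ValueError("empty chain")
    pip = (chain.mix != 0).mean(axis=0)
    return pd.Series(pip, index=chain.col_ids, name="pip")


def _group_predictor_variance(chain: ChainStore, Z: np.ndarray | None) -> np.ndarray:
    """(S, G) realized variance captured by each group per saved sample.

    With the design matrix the exact Var(Z_g theta_g) is used; without it
    the sum of squared effects, which coincides for uncorrelated
    unit-variance columns.
    """
    S, G = chain.n_samples, chain.n_groups
    out = np.empty((S, G))
    for g in range(G):
        cols = chain.group_columns(g)
        th = chain.theta[:, cols]
        if Z is not None:
            pred = Z[:, cols] @ th.T  # (N, S)
            out[:, g] = pred.var(axis=0, ddof=1)
        else:
            out[:, g] = (th**2).sum(axis=1)
    return out


def partition_variance(chain: ChainStore, Z: np.ndarray | None = None):
    """Per-sample normalized variance shares and their posterior summaries.

    Each saved sample is partitioned into the variance captured by every
    covariate group plus the residual variance, all divided by their sum so
    the shares add to one.  Group variance is the realized variance of the
    group's predictor (see the methods note for why the realized quantity,
    rather than the prior-scale hyperparameter, measures the variance
    attributable to a group).

    Returns ``(shares, summary)``: an (S, G+1) DataFrame with one column
    per group plus ``residual``, and a DataFrame of posterior means with
    equal-tailed 95% credible intervals.
    """
    gv = _group_predictor_variance(chain, Z)
    comps = np.column_stack([gv, chain.sigma_eps_sq])
    shares = comps / comps.sum(axis=1, keepdims=True)
    names = list(chain.group_names) + ["residual"]
    df = pd.DataFrame(shares, columns=names)
    summary = pd.DataFrame(
        {
            "mean": df.mean(),
            "ci_low": df.quantile(0.025),
            "ci_high": df.quantile(0.975),
        }
    )
    return df, summary


def mixture_variance_decomposition(chain: ChainStore, var_y: float = 1.0):
    """Variance contributed by each (group, mixture) class per sample.

    For unit-variance columns the contribution of an in-model effect is
    theta^2, so the class total is the sum of squared effects assigned to
    that mixture, as a fraction of Var(y).  Also reports the in-model count
    per class.  Returns a tidy DataFrame with per-sample rows and a summary
    with posterior means.
    """
    rows = []
    for g in range(chain.n_groups):
        cols = chain.group_columns(g)
        mix = chain.mix[:, cols]
        th = chain.theta[:, cols]
        n_slab = chain.mixture_constants[g].size
        for l in range(1, n_slab + 1):
            mask = mix == l
            contrib = np.where(mask, th**2, 0.0).sum(axis=1) / var_y
            count = mask.sum(axis=1)
            rows.append(
                pd.DataFrame(
                    {
                        "sample": np.arange(chain.n_samples),
                        "group": chain.group_names[g],
                        "mixture": l,
                        "C": chain.mixture_constants[g][l - 1],
                        "variance_share": contrib,
                        "n_effects": count,
                    }
                )
            )
    per_sample = pd.concat(rows, ignore_index=True)
    summary = (
        per_sample.groupby(["group", "mixture", "C"])[["variance_share", "n_effects"]]
        .mean()
        .reset_index()
    )
    return per_sample, summary


# ---------------------------------------------------------------------------
# convergence diagnostics


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density of a chain at frequency zero, via a Bartlett-window
    sum of autocovariances (lag cutoff ~ n^(1/3) scaled)."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    xc = x - x.mean()
    if n < 2 or np.allclose(xc, 0):
        return 0.0
    lag_max = min(n - 1, max(1, int(2 * n ** (1 / 3))))
    acov = np.correlate(xc, xc, mode="full")[n - 1 : n + lag_max] / n
    w = 1.0 - np.arange(1, lag_max + 1) / (lag_max + 1)
    return float(acov[0] + 2.0 * (w * acov[1:]).sum())


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score: standardized difference between the means
    of the first ``first`` and last ``last`` fractions of the chain, with
    spectral-density standard errors.  NaN when undefined (constant chain)."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 50:
        raise ValueError("need at least 50 samples for the Geweke diagnostic")
    a = x[: int(first * n)]
    b = x[n - int(last * n) :]
    sa, sb = _spectral_density_zero(a), _spectral_density_zero(b)
    denom = sa / a.size + sb / b.size
    if denom <= 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(denom))


def convergence_diagnostics(chains) -> pd.DataFrame:
    """Geweke z per chain and, with >= 2 chains, rank-normalized split R-hat
    across chains, for sigma_eps_sq and every group's sigma_g_sq.

    Undefined diagnostics (constant chains) are reported as NaN rather than
    raised.
    """
    if isinstance(chains, ChainStore):
        chains = [chains]
    if not chains:
        raise ValueError("no chains supplied")
    names = ["sigma_eps_sq"] + [f"sigma_g_sq[{g}]" for g in chains[0].group_names]

    def series(ch, i):
        return ch.sigma_eps_sq if i == 0 else ch.sigma_g_sq[:, i - 1]

    rows = []
    for i, name in enumerate(names):
        gz = []
        for ch in chains:
            try:
                z = geweke_z(series(ch, i))
            except ValueError:
                z = float("nan")
            gz.append(z)
        rhat = float("nan")
        if len(chains) >= 2:
            arr = np.stack([series(ch, i) for ch in chains])
            if np.allclose(arr.std(axis=1), 0):
                rhat = float("nan")
            else:
                import arviz as az

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rhat = float(az.rhat(az.convert_to_dataset(arr))["x"].values)
        rows.append({"parameter": name, "geweke_z": gz, "rhat": rhat})
    df = pd.DataFrame(rows)
    df["max_abs_geweke"] = df["geweke_z"].apply(
        lambda v: np.nanmax(np.abs(v)) if np.any(np.isfinite(v)) else np.nan
    )
    return df


# ---------------------------------------------------------------------------
# enrichment


@dataclass
class AnnotationMap:
    """Many-to-many covariate -> term assignment."""

    pairs: list  # (column_id, term_id)
    terms: list = field(init=False)

    def __post_init__(self) -> None:
        seen = set()
        clean = []
        for cid, tid in self.pairs:
            key = (cid, tid)
            if key in seen:
                raise ValueError(f"duplicate annotation pair {key}")
            seen.add(key)
            clean.append(key)
        self.pairs = clean
        self.terms = sorted({t for _, t in clean})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationMap":
        return cls(list(df.itertuples(index=False, name=None)))

    def columns_for_term(self, term) -> set:
        return {c for c, t in self.pairs if t == term}

    def mapped_columns(self) -> set:
        return {c for c, _ in self.pairs}


@dataclass
class EnrichmentPosterior:
    """Per-term enrichment samples (defined only where the term is in the
    model) and term inclusion probabilities."""

    enrichment: dict      # term -> np.ndarray of per-sample enrichment values
    term_ip: dict         # term -> inclusion probability in [0, 1]
    n_samples: int


def term_enrichment(chain: ChainStore, annot: AnnotationMap) -> EnrichmentPosterior:
    """Posterior enrichment of every annotated term.

    Per saved sample: p.PVE is the term's share of the total in-model
    squared effects, p.Term its share of in-model probes mapped to any
    term; enrichment is p.PVE / p.Term.  Samples in which no in-model probe
    maps to the term contribute nothing to the enrichment vector but still
    count toward the term's inclusion probability denominator.
    """
    col_index = {c: i for i, c in enumerate(chain.col_ids)}
    mapped_any = np.array(
        [col_index[c] for c in annot.mapped_columns() if c in col_index], dtype=np.int64
    )
    if mapped_any.size == 0:
        raise ValueError("annotation covers no chain column")
    term_cols = {
        t: np.array(
            [col_index[c] for c in annot.columns_for_term(t) if c in col_index],
            dtype=np.int64,
        )
        for t in annot.terms
    }

    in_model = chain.mix != 0
    th2 = chain.theta**2
    total_pve = th2.sum(axis=1)                     # all in-model effects
    n_mapped = in_model[:, mapped_any].sum(axis=1)  # in-model probes mapped to any term

    enrichment, term_ip = {}, {}
    for t, cols in term_cols.items():
        if cols.size == 0:
            enrichment[t] = np.empty(0)
            term_ip[t] = 0.0
            continue
        n_term = in_model[:, cols].sum(axis=1)
        present = n_term > 0
        term_ip[t] = float(present.mean())
        ok = present & (n_mapped > 0) & (total_pve > 0)
        p_pve = th2[np.ix_(ok.nonzero()[0], cols)].sum(axis=1) / total_pve[ok]
        p_term = n_term[ok] / n_mapped[ok]
        enrichment[t] = p_pve / p_term
    return EnrichmentPosterior(enrichment=enrichment, term_ip=term_ip, n_samples=chain.n_samples)


def rope_decision(
    post: EnrichmentPosterior,
    rope: tuple = (0.5, 1.5),
    ip_threshold: float = 0.95,
    mass: float = 0.95,
    min_samples: int = 20,
) -> pd.DataFrame:
    """ROPE verdict per term.

    ``enriched-above``/``enriched-below`` require the term inclusion
    probability to exceed ``ip_threshold`` AND at least ``mass`` of the
    enrichment posterior outside the ROPE on a single side; terms with
    fewer than ``min_samples`` defined enrichment samples are
    ``insufficient``.
    """
    lo, hi = rope
    rows = []
    for t, vals in post.enrichment.items():
        ip = post.term_ip[t]
        if vals.size < min_samples:
            verdict = "insufficient"
        elif ip <= ip_threshold:
            verdict = "not-significant"
        else:
            above = (vals >= hi).mean()
            below = (vals <= lo).mean()
            if above >= mass:
                verdict = "enriched-above"
            elif below >= mass:
                verdict = "enriched-below"
            else:
                verdict = "not-significant"
        rows.append(
            {
                "term": t,
                "ip": ip,
                "n_samples": int(vals.size),
                "mean_enrichment": float(vals.mean()) if vals.size else float("nan"),
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows).set_index("term")
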
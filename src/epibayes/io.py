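"""Readers/writers and design assembly.

Interchange formats are plain text: TSV/CSV matrices with a header row of
column ids and a leading sample-id column, 2-column TSV phenotypes and
annotations, PLINK .bed/.bim/.fam genotype blocks, and a TOML run
configuration.  Chain stores serialize to a directory of CSVs plus a JSON
metadata file.
"""

from __future__ import annotations

import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CovariateGroup, GroupedDesign, Hyperparams, standardize, standardize_phenotype
from .plink import read_plink
from .posterior import AnnotationMap
from .sampler import ChainStore

__all__ = [
    "read_phenotype",
    "read_block",
    "read_annotation",
    "build_design",
    "load_design",
    "write_chains",
    "read_chains",
    "write_chain",
    "read_chain",
]

log = logging.getLogger(__name__)

STORE_VERSION = 1
MIN_SAMPLES = 10


def read_phenotype(path) -> pd.Series:
    """2-column TSV (sample id, value); a header row is auto-detected."""
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    has_header = False
    try:
        float(first.iloc[0, 1])
    except (TypeError, ValueError):
        has_header = True
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None,
                     dtype={0: str}, names=None if has_header else ["sample", "value"])
    df.columns = ["sample", "value"]
    df["sample"] = df["sample"].astype(str)
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype")
    return df.set_index("sample")["value"].astype(float)


def read_block(path) -> pd.DataFrame:
    """Covariate block: TSV/CSV with header of column ids and a sample-id
    first column, or a PLINK prefix / .bed path (allele counts 0/1/2)."""
    p = Path(path)
    if p.suffix == ".bed" or (not p.exists() and Path(str(p) + ".bed").exists()):
        prefix = str(p)[: -len(".bed")] if p.suffix == ".bed" else str(p)
        ids, snps, geno = read_plink(prefix)
        return pd.DataFrame(geno, index=pd.Index(ids, name="sample"), columns=snps)
    sep = "," if p.suffix == ".csv" else "\t"
    df = pd.read_csv(p, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def read_annotation(path) -> AnnotationMap:
    """2-column TSV (column_id, term_id)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["column_id", "term_id"], dtype=str)
    return AnnotationMap(list(df.itertuples(index=False, name=None)))


def build_design(
    pheno: pd.Series,
    blocks: dict,
    mixtures: dict,
    dirichlet: dict | None = None,
    group_map: pd.Series | None = None,
    hyper: Hyperparams | None = None,
) -> GroupedDesign:
    """Join blocks on sample id, standardize, and group columns.

    ``blocks`` maps block name -> DataFrame (samples x columns); ``mixtures``
    maps final group name -> slab constants.  ``group_map`` (column id ->
    group name) optionally reassigns columns across blocks; unmapped columns
    stay in their block's group.  Sample ids are intersected and a warning
    logged when rows are lost; fewer than 10 shared samples is an error.
    """
    ids = pheno.index
    if ids.duplicated().any():
        raise ValueError("duplicate sample ids")
    for name, df in blocks.items():
        if df.index.duplicated().any():
            raise ValueError(f"duplicate sample ids in block {name!r}")
        ids = ids.intersection(df.index)
    if len(ids) < len(pheno):
        log.warning("sample intersection kept %d of %d phenotyped individuals",
                    len(ids), len(pheno))
    if len(ids) < MIN_SAMPLES:
        raise ValueError(f"only {len(ids)} samples shared across inputs")
    ids = list(ids)

    # final group of every column
    col_group, col_data = {}, {}
    for bname, df in blocks.items():
        for cid in df.columns:
            if cid in col_data:
                raise ValueError(f"duplicate column id {cid!r}")
            g = bname
            if group_map is not None and cid in group_map.index:
                g = group_map.loc[cid]
            col_group[cid] = g
            col_data[cid] = df.loc[ids, cid]

    groups = []
    for gname in mixtures:
        cols = [c for c, g in col_group.items() if g == gname]
        if not cols:
            raise ValueError(f"group {gname!r} has no columns")
        raw = np.column_stack([col_data[c].to_numpy(dtype=float) for c in cols])
        Z = standardize(raw, col_ids=cols)
        prior = None if dirichlet is None else dirichlet.get(gname)
        groups.append(CovariateGroup(gname, Z, mixtures[gname], col_ids=cols,
                                     dirichlet_prior=prior))
    unassigned = sorted({g for g in col_group.values()} - set(mixtures))
    if unassigned:
        raise ValueError(f"no mixture constants for group(s) {unassigned}")

    y = standardize_phenotype(pheno.loc[ids].to_numpy())
    design = GroupedDesign(y=y, groups=groups, hyper=hyper or Hyperparams())
    log.info("design: N=%d, groups=%s", design.n,
             {g.name: (g.m, list(g.C)) for g in design.groups})
    return design


def load_design(config_path) -> GroupedDesign:
    """Assemble a GroupedDesign from a TOML run configuration.

    ::

        pheno = "pheno.tsv"
        group_map = "map.tsv"          # optional: column_id -> group name
        [groups.methylation]
        file = "meth.csv"              # TSV/CSV block or PLINK prefix/.bed
        mixtures = [0.01, 0.1, 1.0]
        dirichlet = [1, 1, 1, 1]       # optional, spike first
        [hyper]                        # optional
        v0 = 0.001
        s0sq = 0.001
    """
    cfg_path = Path(config_path)
    with open(cfg_path, "rb") as fh:
        cfg = tomllib.load(fh)
    base = cfg_path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    pheno = read_phenotype(_resolve(cfg["pheno"]))
    blocks, mixtures, dirichlet = {}, {}, {}
    for gname, spec in cfg["groups"].items():
        if "file" in spec:
            blocks[gname] = read_block(_resolve(spec["file"]))
        mixtures[gname] = np.asarray(spec["mixtures"], dtype=float)
        if "dirichlet" in spec:
            dirichlet[gname] = np.asarray(spec["dirichlet"], dtype=float)
    group_map = None
    if "group_map" in cfg:
        gm = pd.read_csv(_resolve(cfg["group_map"]), sep="\t", header=None,
                         names=["column_id", "group"], dtype=str)
        group_map = gm.set_index("column_id")["group"]
    hyper = Hyperparams(**cfg["hyper"]) if "hyper" in cfg else None
    return build_design(pheno, blocks, mixtures, dirichlet or None, group_map, hyper)


# ---------------------------------------------------------------------------
# chain store persistence


def write_chains(chains, path) -> None:
    """Serialize chains to ``path``/: columns.csv, hyperparams.csv,
    effects.csv (sparse: nonzero effects only) and meta.json."""
    if isinstance(chains, ChainStore):
        chains = [chains]
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    ref = chains[0]

    pd.DataFrame({
        "column_id": ref.col_ids,
        "group": [ref.group_names[g] for g in ref.group_of_col],
    }).to_csv(out / "columns.csv", index=False)

    hyper_rows, eff_rows = [], []
    for ch in chains:
        cid = ch.meta.get("chain_id", 0)
        for s in range(ch.n_samples):
            row = {"chain": cid, "sample": s, "mu": ch.mu[s],
                   "sigma_eps_sq": ch.sigma_eps_sq[s]}
            for g, gname in enumerate(ch.group_names):
                row[f"sigma_g_sq.{gname}"] = ch.sigma_g_sq[s, g]
                for l in range(ch.pi[g].shape[1]):
                    row[f"pi.{gname}.{l}"] = ch.pi[g][s, l]
            hyper_rows.append(row)
        samp, col = np.nonzero(ch.mix != 0)
        eff_rows.append(pd.DataFrame({
            "chain": cid,
            "sample": samp,
            "column_id": np.asarray(ch.col_ids, dtype=object)[col],
            "mixture": ch.mix[samp, col],
            "value": ch.theta[samp, col],
        }))
    # shortest round-trippable float formatting keeps the store lossless
    fmt = lambda v: repr(float(v))  # noqa: E731
    pd.DataFrame(hyper_rows).to_csv(out / "hyperparams.csv", index=False, float_format=fmt)
    pd.concat(eff_rows, ignore_index=True).to_csv(out / "effects.csv", index=False,
                                                  float_format=fmt)

    meta = {
        "version": STORE_VERSION,
        "group_names": ref.group_names,
        "mixture_constants": [list(map(float, c)) for c in ref.mixture_constants],
        "chains": [
            {**{k: v for k, v in ch.meta.items()}, "n_samples": ch.n_samples}
            for ch in chains
        ],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_chains(path) -> list:
    """Inverse of :func:`write_chains`; raises on version mismatch or a
    truncated store."""
    src = Path(path)
    meta = json.loads((src / "meta.json").read_text())
    if meta.get("version") != STORE_VERSION:
        raise ValueError(f"chain store version {meta.get('version')!r} unsupported")
    cols = pd.read_csv(src / "columns.csv", dtype={"column_id": str})
    col_ids = cols["column_id"].tolist()
    group_names = meta["group_names"]
    gindex = {g: i for i, g in enumerate(group_names)}
    group_of_col = cols["group"].map(gindex).to_numpy(dtype=np.int64)
    mixture_constants = [np.asarray(c, dtype=float) for c in meta["mixture_constants"]]
    col_pos = {c: i for i, c in enumerate(col_ids)}

    hyper = pd.read_csv(src / "hyperparams.csv", float_precision="round_trip")
    effects = pd.read_csv(src / "effects.csv", dtype={"column_id": str},
                          float_precision="round_trip")
    chains = []
    for ch_meta in meta["chains"]:
        cid = ch_meta.get("chain_id", 0)
        S = ch_meta["n_samples"]
        h = hyper[hyper["chain"] == cid].sort_values("sample")
        if len(h) != S:
            raise ValueError(
                f"chain {cid}: store truncated ({len(h)} of {S} hyperparameter rows)"
            )
        M = len(col_ids)
        theta = np.zeros((S, M))
        mix = np.zeros((S, M), dtype=np.int8)
        e = effects[effects["chain"] == cid]
        if len(e) and (e["sample"].max() >= S or not e["column_id"].isin(col_pos).all()):
            raise ValueError(f"chain {cid}: effects table inconsistent with metadata")
        rows = e["sample"].to_numpy()
        jcols = e["column_id"].map(col_pos).to_numpy(dtype=np.int64) if len(e) else np.empty(0, dtype=np.int64)
        theta[rows, jcols] = e["value"].to_numpy()
        mix[rows, jcols] = e["mixture"].to_numpy()
        pi = [
            h[[f"pi.{g}.{l}" for l in range(mixture_constants[gi].size + 1)]].to_numpy()
            for gi, g in enumerate(group_names)
        ]
        chains.append(ChainStore(
            col_ids=col_ids,
            group_names=group_names,
            group_of_col=group_of_col,
            mixture_constants=mixture_constants,
            mu=h["mu"].to_numpy(),
            sigma_eps_sq=h["sigma_eps_sq"].to_numpy(),
            sigma_g_sq=h[[f"sigma_g_sq.{g}" for g in group_names]].to_numpy(),
            pi=pi,
            theta=theta,
            mix=mix,
            meta={k: v for k, v in ch_meta.items() if k != "n_samples"},
        ))
    return chains


def write_chain(chain: ChainStore, path) -> None:
    write_chains([chain], path)


def read_chain(path) -> ChainStore:
    chains = read_chains(path)
    if len(chains) != 1:
        raise ValueError(f"expected a single chain, found {len(chains)}")
    return chains[0]
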
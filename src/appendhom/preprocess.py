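"""Expression filtering, TMM normalization and grouped log2-CPM.

Each taxon's count matrix is handled separately (no joint cross-taxon
normalization).  Filtering keeps a gene when every sample of at least one
tissue reaches ``cpm_min`` counts per million and the gene's total CPM
reaches ``cpm_total_min``; CPM here uses raw library sizes, before TMM.

TMM (trimmed mean of M-values) computes one positive scaling factor per
sample from a doubly trimmed, precision-weighted mean of per-gene log
ratios against a reference sample; factors are rescaled to geometric mean
one so they only redistribute, never change, total depth.

Grouped LCPM summarizes each (taxon, tissue) group as
``log2((sum counts + 0.5) / (sum effective library size) * 1e6)``, with an
exact sentinel (default -21) whenever the group's summed raw count is zero.
All threshold comparisons in this module are inclusive (``>=``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import CountMatrix

__all__ = ["filter_by_expression", "tmm_factors", "grouped_lcpm", "cpm"]


def cpm(cm: CountMatrix, library_sizes: np.ndarray | None = None) -> np.ndarray:
    """Counts per million per cell, using raw library sizes by default."""
    lib = cm.library_sizes if library_sizes is None else np.asarray(library_sizes, float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive to compute CPM")
    return cm.counts / lib * 1e6


def filter_by_expression(cm: CountMatrix, meta: pd.DataFrame, cfg: AnalysisConfig) -> CountMatrix:
    """Drop genes expressed below biologically relevant levels.

    Keeps gene *g* iff there exists a tissue in which **every** sample has
    ``CPM >= cfg.cpm_min``, and the gene's CPM summed over all samples is
    ``>= cfg.cpm_total_min``.
    """
    meta = meta.set_index("sample_id").loc[list(cm.sample_ids)]
    mat = cpm(cm)
    per_tissue_ok = np.zeros(cm.shape[0], dtype=bool)
    for _, idx in meta.groupby("tissue").groups.items():
        cols = cm.sample_ids.get_indexer(idx)
        per_tissue_ok |= (mat[:, cols] >= cfg.cpm_min).all(axis=1)
    keep = per_tissue_ok & (mat.sum(axis=1) >= cfg.cpm_total_min)
    if not keep.any():
        warnings.warn("no genes pass the expression filter", stacklevel=2)
    return CountMatrix(cm.gene_ids[keep], cm.sample_ids, cm.counts[keep])


def _quantile75(x: np.ndarray) -> float:
    # linear-interpolation (type-7) quantile, fixed for a deterministic
    # reference-sample choice
    return float(np.quantile(x, 0.75, method="linear"))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (both raw counts)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("no genes positive in both sample and reference")
    o = obs[pos] / n_obs
    r = ref[pos] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # delta-method variance of M under binomial sampling
    v = (n_obs - obs[pos]) / (n_obs * obs[pos]) + (n_ref - ref[pos]) / (n_ref * ref[pos])
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank(method="average").to_numpy()
    rank_a = pd.Series(a).rank(method="average").to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    f = np.sum(w * m[keep]) / np.sum(w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(cm: CountMatrix, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Trimmed-mean-of-M-values normalization factors per sample.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean 75th percentile across samples.  For each other sample, genes
    positive in both are doubly trimmed (30% on M, 5% on A by default) and
    the factor is ``2**`` (precision-weighted mean of the surviving M
    values).  Factors are rescaled to geometric mean one.

    Returns a frame with ``sample_id``, ``tmm_factor``, ``effective_libsize``.
    """
    if cfg is None:
        cfg = AnalysisConfig()
    if cm.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = cm.library_sizes.astype(float)
    if (lib <= 0).any():
        bad = cm.sample_ids[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    mat = cm.counts / lib * 1e6
    q = np.array([_quantile75(mat[:, j]) for j in range(cm.shape[1])])
    ref_j = int(np.argmin(np.abs(q - q.mean())))
    ref = cm.counts[:, ref_j].astype(float)
    factors = np.ones(cm.shape[1])
    for j in range(cm.shape[1]):
        if j == ref_j:
            continue
        obs = cm.counts[:, j].astype(float)
        try:
            factors[j] = _tmm_pair(obs, ref, lib[j], lib[ref_j], cfg.tmm_trim_m, cfg.tmm_trim_a)
        except ValueError as exc:
            raise ValueError(f"sample {cm.sample_ids[j]!r}: {exc}") from exc
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.DataFrame(
        {
            "sample_id": cm.sample_ids,
            "tmm_factor": factors,
            "effective_libsize": lib * factors,
        }
    )


def grouped_lcpm(
    cm: CountMatrix,
    meta: pd.DataFrame,
    nf: pd.DataFrame,
    cfg: AnalysisConfig,
    *,
    min_count: float = 10.0,
    min_replicate_frac: float = 2.0 / 3.0,
) -> pd.DataFrame:
    """Per-(gene, tissue) log2 counts per million with a zero sentinel.

    For each tissue group, ``lcpm = log2((sum counts + 0.5) /
    (sum effective libsize) * 1e6)`` when the summed raw count is positive,
    and exactly ``cfg.lcpm_zero_sentinel`` when it is zero.  A gene is
    retained only if, in at least one tissue, at least two-thirds of the
    replicates have a raw count of at least ``min_count``.

    Returns a long frame with ``gene_id``, ``taxon``, ``tissue``, ``lcpm``.
    """
    meta = meta.set_index("sample_id").loc[list(cm.sample_ids)]
    nf = nf.set_index("sample_id").loc[list(cm.sample_ids)]
    eff = nf["effective_libsize"].to_numpy(float)
    if (eff <= 0).any():
        raise ValueError("effective library sizes must be positive")

    groups = meta.groupby(["taxon", "tissue"], sort=True).groups
    retain = np.zeros(cm.shape[0], dtype=bool)
    rows = []
    for (taxon, tissue), idx in groups.items():
        cols = cm.sample_ids.get_indexer(idx)
        sub = cm.counts[:, cols]
        group_lib = eff[cols].sum()
        if group_lib <= 0:
            raise ValueError(f"group ({taxon}, {tissue}) has zero total library size")
        total = sub.sum(axis=1)
        lcpm = np.where(
            total == 0,
            cfg.lcpm_zero_sentinel,
            np.log2((total + 0.5) / group_lib * 1e6),
        )
        retain |= (sub >= min_count).sum(axis=1) >= min_replicate_frac * len(cols)
        rows.append(
            pd.DataFrame(
                {"gene_id": cm.gene_ids, "taxon": taxon, "tissue": tissue, "lcpm": lcpm}
            )
        )
    out = pd.concat(rows, ignore_index=True)
    kept = set(cm.gene_ids[retain])
    out = out[out["gene_id"].isin(kept)]
    return out.sort_values(["gene_id", "taxon", "tissue"], kind="stable").reset_index(drop=True)
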
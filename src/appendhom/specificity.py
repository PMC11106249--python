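"""Tau tissue-specificity index and strict/relaxed specific-gene lists.

Tau summarizes how concentrated a gene's expression is across tissues:

    tau = sum_i (1 - xhat_i) / (n - 1),   xhat_i = x_i / max_j x_j

so tau = 0 for perfectly uniform expression and tau = 1 for single-tissue
expression.  Input expression is log2-CPM clipped below at zero (the zero
sentinel therefore reads as "not expressed").  A gene enters the *strict*
list when tau >= 0.9, assigned to its single argmax tissue; it enters the
*relaxed* list when tau >= 0.75, assigned to every tissue whose relative
expression is at least 75% of the maximum, which admits genes shared among
several cranial-appendage tissues.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import AnalysisConfig

__all__ = ["tau", "specificity_lists"]


def tau(expr) -> float:
    """Tissue-specificity index of a nonnegative expression vector.

    Returns NaN (with a warning) for an all-zero vector; raises on negative
    input — callers clip log-scale expression at zero first.
    """
    x = np.asarray(expr, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-D vector of length >= 2")
    if (x < 0).any():
        raise ValueError("tau requires nonnegative expression (clip first)")
    m = x.max()
    if m == 0:
        warnings.warn("tau undefined for an all-zero vector", stacklevel=2)
        return float("nan")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def specificity_lists(
    lcpm: pd.DataFrame,
    cfg: AnalysisConfig,
    *,
    control_tissues: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Per-gene tau records for one taxon's grouped log2-CPM table.

    ``lcpm`` is the long frame from :func:`appendhom.preprocess.grouped_lcpm`
    (one taxon).  Expression is clipped below at zero before tau.  Output
    columns: ``gene_id, taxon, tau, strict_tissue, relaxed_tissues``
    (tuple, sorted), ``control_specific`` (assigned, under the applicable
    rule, to a tissue in ``control_tissues``), and ``excluded`` with a
    reason for genes expressed in no tissue after clipping.
    """
    taxa = lcpm["taxon"].unique()
    if len(taxa) != 1:
        raise ValueError("specificity_lists expects a single-taxon LCPM table")
    taxon = taxa[0]
    wide = lcpm.pivot_table(index="gene_id", columns="tissue", values="lcpm", sort=True)
    if wide.isna().any().any():
        raise ValueError("LCPM table is missing (gene, tissue) entries")
    tissues = list(wide.columns)
    if len(tissues) < 2:
        raise ValueError("tau needs at least two tissues")
    mat = np.clip(wide.to_numpy(float), 0.0, None)
    mx = mat.max(axis=1)
    expressed = mx > 0

    records = []
    for i, gene in enumerate(wide.index):
        if not expressed[i]:
            records.append(
                {
                    "gene_id": gene,
                    "taxon": taxon,
                    "tau": np.nan,
                    "strict_tissue": None,
                    "relaxed_tissues": (),
                    "control_specific": False,
                    "excluded": "no_expressed_tissue",
                }
            )
            continue
        xhat = mat[i] / mx[i]
        t = float(np.sum(1.0 - xhat) / (len(tissues) - 1))
        # lexicographic tie-break: tissues are already sorted
        strict_tissue = tissues[int(np.argmax(xhat))] if t >= cfg.tau_strict else None
        if t >= cfg.tau_relaxed:
            relaxed = tuple(
                tis for tis, v in zip(tissues, xhat) if v >= cfg.relaxed_assign_frac
            )
        else:
            relaxed = ()
        assigned = set(relaxed) | ({strict_tissue} if strict_tissue else set())
        records.append(
            {
                "gene_id": gene,
                "taxon": taxon,
                "tau": t,
                "strict_tissue": strict_tissue,
                "relaxed_tissues": relaxed,
                "control_specific": bool(assigned & set(control_tissues)),
                "excluded": None,
            }
        )
    out = pd.DataFrame.from_records(records)
    return out.sort_values("gene_id", kind="stable").reset_index(drop=True)
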
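"""Competitive gene-set ranking and regulator-target overlap testing.

The ranking asks whether genes in a set have mean signed statistics
different from genes outside it, inflating the set-mean variance by
VIF = 1 + (m - 1) * rho_bar to account for inter-gene correlation, where
rho_bar is the mean pairwise correlation of the set genes' model residuals
(floored at zero so the correction is never anti-conservative).  This is
the camera-style two-tailed competitive test: its direction reports whether
the set tends to be overexpressed or underexpressed.

Regulator overlaps replace an online overlap service with a local
hypergeometric upper-tail test of each (significant set, regulator target
list) pair against the analysis universe, BH-adjusted across pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import GeneSet

__all__ = ["camera_rank", "regulator_overlap"]


def _mean_pairwise_correlation(resid: np.ndarray) -> float:
    """Mean off-diagonal correlation among rows (genes) of a residual block."""
    if resid.shape[0] < 2:
        return 0.0
    sd = resid.std(axis=1)
    ok = sd > 0
    if ok.sum() < 2:
        return 0.0
    c = np.corrcoef(resid[ok])
    m = c.shape[0]
    return float((c.sum() - m) / (m * (m - 1)))


def camera_rank(
    gene_stats: pd.Series,
    sets: list[GeneSet],
    residuals: pd.DataFrame,
    *,
    analysis_id: str = "",
    fixed_rho: float | None = None,
) -> pd.DataFrame:
    """Rank gene sets competitively against the rest of the universe.

    Parameters
    ----------
    gene_stats:
        Signed standardized per-gene statistics (index = gene symbols).
    sets:
        Gene sets; members matched by uppercase symbol.
    residuals:
        Per-gene residual matrix (gene x sample) used to estimate the mean
        inter-gene correlation of each set.  Ignored when ``fixed_rho`` is
        given.
    fixed_rho:
        Optional fixed inter-gene correlation override.

    Returns a frame with ``set_name, analysis_id, m, direction, rho,
    vif, pvalue, fdr`` sorted by p-value; sets with fewer than two members
    in the universe are skipped with a warning and listed in the attribute
    ``.attrs["skipped"]``.
    """
    stats_idx = pd.Index([g.upper() for g in gene_stats.index])
    values = pd.Series(gene_stats.to_numpy(float), index=stats_idx)
    N = len(values)
    total_var = float(values.var(ddof=1))
    rows = []
    skipped = []
    for gs in sets:
        members = sorted(gs.members & set(stats_idx))
        m = len(members)
        if m < 2 or N - m < 2:
            skipped.append(gs.name)
            continue
        in_set = values.loc[members].to_numpy()
        out_mean = (values.sum() - in_set.sum()) / (N - m)
        delta = float(in_set.mean() - out_mean)
        if fixed_rho is not None:
            rho = float(fixed_rho)
        else:
            block = residuals.loc[residuals.index.intersection(members)].to_numpy(float)
            rho = _mean_pairwise_correlation(block)
        rho_eff = max(rho, 0.0)
        vif = 1.0 + (m - 1) * rho_eff
        se = np.sqrt(total_var * (vif / m + 1.0 / (N - m)))
        t = delta / se if se > 0 else 0.0
        p = float(2.0 * stats.t.sf(abs(t), df=N - 2))
        rows.append(
            {
                "set_name": gs.name,
                "analysis_id": analysis_id,
                "m": m,
                "direction": "Up" if delta >= 0 else "Down",
                "rho": rho,
                "vif": vif,
                "pvalue": p,
            }
        )
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} gene set(s) with <2 members in universe", stacklevel=2
        )
    out = pd.DataFrame(
        rows, columns=["set_name", "analysis_id", "m", "direction", "rho", "vif", "pvalue"]
    )
    if not out.empty:
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
        out = out.sort_values(["pvalue", "set_name"], kind="stable").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    out.attrs["skipped"] = skipped
    return out


def regulator_overlap(
    sets: list[GeneSet],
    target_lists: list[GeneSet],
    universe,
    *,
    de_tables: dict[str, pd.DataFrame] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric overlap of gene sets with regulator target lists.

    All counts are computed after intersecting with ``universe``.  The
    upper-tail p-value is P(X >= k) for overlap k between a set of size n
    and a target list of size K in a universe of size N; q-values are BH
    across all (set, regulator) pairs.  When ``de_tables`` (analysis_id ->
    DE result frame) is given, significant regulators are flagged with the
    analyses in which the regulator gene itself is differentially expressed.
    """
    uni = {str(g).upper() for g in universe}
    if not uni:
        raise ValueError("universe must be non-empty")
    N = len(uni)
    rows = []
    for gs in sets:
        set_u = gs.members & uni
        n = len(set_u)
        for tl in target_lists:
            targ_u = tl.members & uni
            K = len(targ_u)
            k = len(set_u & targ_u)
            assert k <= min(K, n), "overlap exceeds its bounds: counting bug"
            p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K and n else 1.0
            rows.append(
                {
                    "set_name": gs.name,
                    "regulator": tl.name.upper(),
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "pvalue": min(p, 1.0),
                }
            )
    out = pd.DataFrame(rows, columns=["set_name", "regulator", "k", "K", "n", "N", "pvalue"])
    if out.empty:
        out["qvalue"] = pd.Series(dtype=float)
        out["regulator_de_in"] = pd.Series(dtype=object)
        return out
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    flags = []
    for reg, q in zip(out["regulator"], out["qvalue"]):
        hits = []
        if de_tables and q < alpha:
            for aid, table in sorted(de_tables.items()):
                row = table[table["gene_id"] == reg]
                if not row.empty and (row["direction"] != "ns").any():
                    hits.append(aid)
        flags.append(",".join(hits))
    out["regulator_de_in"] = flags
    return out.sort_values(["set_name", "regulator"], kind="stable").reset_index(drop=True)
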
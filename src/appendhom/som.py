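"""Self-organizing-map clustering of gene expression profiles.

Gene log2-CPM profiles (rows standardized to mean 0, sd 1 across tissue
columns) are mapped onto a rectangular grid of units by online Kohonen
training with sum-of-squares distances: each presentation updates the
best-matching unit and its grid neighbors toward the observation, with a
linearly declining learning rate and a neighborhood radius shrinking from
two-thirds of the grid diagonal down to one unit (at which point updates
are k-means-like).  The trained units' codebook vectors are then grouped
by k-medoid (PAM) clustering, with the cluster count chosen by the
Tibshirani gap statistic against uniform reference data, and each
(cluster, tissue) cell summarized as the mean log2-CPM of member genes,
excluding zero-count sentinel entries.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .config import AnalysisConfig

__all__ = [
    "SOMModel",
    "standardize_profiles",
    "train_som",
    "kmedoids",
    "gap_statistic_k",
    "choose_k",
    "cluster_summaries",
    "som_input_genes",
]


@dataclasses.dataclass
class SOMModel:
    """A trained map plus its unit diagnostics and k-medoid clustering."""

    rows: int
    cols: int
    codebook: np.ndarray                 # (units, dims)
    dim_names: list[str]
    mapping: pd.Series                   # gene -> unit index
    unit_counts: np.ndarray              # genes per unit
    unit_quality: np.ndarray             # mean SS distance of mapped genes
    unit_neighbor_dist: np.ndarray       # mean SS distance to grid neighbors
    unit_cluster: np.ndarray | None = None
    k: int | None = None
    quantization_error_start: float = np.nan
    quantization_error_end: float = np.nan
    dropped_genes: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.rows * self.cols


def standardize_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Scale each gene row to mean 0, sd 1; drop constant rows (recorded)."""
    mat = profiles.to_numpy(float)
    sd = mat.std(axis=1)
    keep = sd > 0
    dropped = profiles.index[~keep].tolist()
    mat = mat[keep]
    mat = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, keepdims=True)
    return pd.DataFrame(mat, index=profiles.index[keep], columns=profiles.columns), dropped


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def train_som(
    profiles: pd.DataFrame,
    cfg: AnalysisConfig,
    seed: int,
    *,
    standardize: bool = True,
) -> SOMModel:
    """Train a rectangular Kohonen map on gene expression profiles.

    ``profiles`` is gene x tissue-column; rows are standardized unless the
    caller already did so.  Training order is canonical: genes are sorted
    lexicographically before the seeded shuffle, so permuting the input
    rows cannot change the result for a fixed seed.
    """
    if standardize:
        profiles, dropped = standardize_profiles(profiles)
    else:
        dropped = []
    profiles = profiles.sort_index(kind="stable")
    data = profiles.to_numpy(float)
    G, d = data.shape
    rows, cols = cfg.som_rows, cfg.som_cols
    n_units = rows * cols
    if G < n_units:
        warnings.warn(f"fewer genes ({G}) than map units ({n_units})", stacklevel=2)

    rng = np.random.default_rng(seed)
    codebook = data[rng.choice(G, size=n_units, replace=G < n_units)].copy()

    coords = _grid_coords(rows, cols)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)

    def bmu_and_qe(cb: np.ndarray) -> tuple[np.ndarray, float]:
        d2 = ((data[:, None, :] - cb[None, :, :]) ** 2).sum(-1)
        bmu = d2.argmin(axis=1)
        return bmu, float(d2[np.arange(G), bmu].mean())

    _, qe_start = bmu_and_qe(codebook)

    total = cfg.som_epochs * G
    r0 = float(np.ceil(2.0 / 3.0 * np.sqrt((rows - 1) ** 2 + (cols - 1) ** 2)))
    r0 = max(r0, 1.0)
    step = 0
    for _epoch in range(cfg.som_epochs):
        order = rng.permutation(G)
        for g in order:
            frac = step / max(total - 1, 1)
            alpha = cfg.som_alpha_start + frac * (cfg.som_alpha_end - cfg.som_alpha_start)
            radius = r0 + frac * (1.0 - r0)
            x = data[g]
            d2 = ((codebook - x) ** 2).sum(axis=1)
            b = int(d2.argmin())
            gd2 = grid_d2[b]
            # strict radius: at radius 1 only the BMU updates (k-means-like
            # end phase)
            within = gd2 < radius**2
            h = np.exp(-gd2[within] / (2.0 * radius**2))
            codebook[within] += alpha * h[:, None] * (x - codebook[within])
            step += 1

    bmu, qe_end = bmu_and_qe(codebook)
    mapping = pd.Series(bmu, index=profiles.index, name="unit")
    unit_counts = np.bincount(bmu, minlength=n_units)
    d2_all = ((data[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    quality = np.full(n_units, np.nan)
    for u in range(n_units):
        members = bmu == u
        if members.any():
            quality[u] = d2_all[members, u].mean()
    neighbor = (grid_d2 > 0) & (grid_d2 <= 2.0)  # rook+diagonal adjacency
    cb_d2 = ((codebook[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    with np.errstate(invalid="ignore"):
        neigh_dist = np.array(
            [cb_d2[u, neighbor[u]].mean() if neighbor[u].any() else np.nan for u in range(n_units)]
        )
    return SOMModel(
        rows=rows,
        cols=cols,
        codebook=codebook,
        dim_names=list(profiles.columns),
        mapping=mapping,
        unit_counts=unit_counts,
        unit_quality=quality,
        unit_neighbor_dist=neigh_dist,
        quantization_error_start=qe_start,
        quantization_error_end=qe_end,
        dropped_genes=dropped,
    )


# --------------------------------------------------------------------------
# k-medoids (PAM) and the gap statistic


def kmedoids(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning Around Medoids on Euclidean distances (BUILD + SWAP).

    Deterministic.  Returns (medoid indices, labels)."""
    X = np.asarray(X, float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    D = np.sqrt(np.maximum(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1), 0.0))
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids_arr = np.array(sorted(medoids))
    # SWAP
    for _ in range(100):
        cost = D[:, medoids_arr].min(axis=1).sum()
        best = (0.0, None)
        for mi, m in enumerate(medoids_arr):
            for h in range(n):
                if h in medoids_arr:
                    continue
                trial = medoids_arr.copy()
                trial[mi] = h
                new_cost = D[:, trial].min(axis=1).sum()
                if cost - new_cost > best[0] + 1e-12:
                    best = (cost - new_cost, trial)
        if best[1] is None:
            break
        medoids_arr = np.sort(best[1])
    labels = np.argmin(D[:, medoids_arr], axis=1)
    return medoids_arr, labels


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Tibshirani's W_k: sum over clusters of pairwise squared distances
    divided by twice the cluster size."""
    total = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        if len(sub) < 2:
            continue
        d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
        total += d2.sum() / (2.0 * len(sub))
    return total


def gap_statistic_k(
    codebook: np.ndarray,
    k_max: int,
    B: int,
    seed: int,
) -> tuple[int, pd.DataFrame]:
    """Choose the k-medoid cluster count by the gap statistic.

    For k = 1..k_max, Gap(k) = mean_b log W*_kb - log W_k over B uniform
    reference datasets drawn over each codebook dimension's observed range;
    the chosen k is the smallest with Gap(k) >= Gap(k+1) - s_{k+1}.
    """
    X = np.asarray(codebook, float)
    n = X.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of units")
    if B < 10:
        raise ValueError("need at least 10 reference datasets")
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    live = span > 0
    if not live.all():
        warnings.warn("dropping zero-range dimensions from the gap reference", stacklevel=2)
    rng = np.random.default_rng(seed)

    logW = np.empty(k_max)
    for k in range(1, k_max + 1):
        _, labels = kmedoids(X, k)
        logW[k - 1] = np.log(max(_within_dispersion(X, labels), 1e-300))
    logW_ref = np.empty((B, k_max))
    for b in range(B):
        ref = np.zeros_like(X)
        ref[:, live] = rng.uniform(lo[live], hi[live], size=(n, int(live.sum())))
        for k in range(1, k_max + 1):
            _, labels = kmedoids(ref[:, live], k)
            logW_ref[b, k - 1] = np.log(max(_within_dispersion(ref[:, live], labels), 1e-300))

    gap = logW_ref.mean(axis=0) - logW
    sk = logW_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    chosen = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - sk[k]:
            chosen = k
            break
    table = pd.DataFrame(
        {"k": np.arange(1, k_max + 1), "logW": logW, "gap": gap, "sk": sk}
    )
    return chosen, table


def choose_k(model: SOMModel, cfg: AnalysisConfig, seed: int) -> SOMModel:
    """Cluster a trained map's codebook by PAM with gap-selected k (in place)."""
    k, _table = gap_statistic_k(model.codebook, cfg.kmedoid_k_max, cfg.gap_B, seed)
    _, labels = kmedoids(model.codebook, k)
    model.k = k
    model.unit_cluster = labels + 1  # 1-based cluster ids
    return model


def som_input_genes(direction_profile: pd.DataFrame) -> pd.Index:
    """Genes significantly DE in >=1 test analysis but not in every one.

    ``direction_profile`` is gene x analysis with values in
    {up, down, ns, absent}."""
    sig = direction_profile.isin(["up", "down"])
    present = direction_profile != "absent"
    any_sig = sig.any(axis=1)
    all_sig = (sig | ~present).all(axis=1) & present.any(axis=1)
    return direction_profile.index[any_sig & ~all_sig]


def cluster_summaries(
    model: SOMModel,
    lcpm: pd.DataFrame,
    sentinel: float = -21.0,
) -> pd.DataFrame:
    """Mean log2-CPM per (cluster, tissue), excluding zero-count sentinels.

    ``lcpm`` is long-format with ``gene_id``, ``tissue`` (or taxon+tissue)
    and ``lcpm``.  Cells with no valid entries are missing, not zero.
    """
    if model.unit_cluster is None:
        raise ValueError("model has no k-medoid clustering; run choose_k first")
    gene_cluster = model.mapping.map(lambda u: model.unit_cluster[u])
    df = lcpm.copy()
    if "taxon" in df.columns:
        df["column"] = df["taxon"].astype(str) + ":" + df["tissue"].astype(str)
    else:
        df["column"] = df["tissue"].astype(str)
    df = df[df["gene_id"].isin(gene_cluster.index)]
    df["cluster_id"] = df["gene_id"].map(gene_cluster)
    valid = df[df["lcpm"] != sentinel]
    out = (
        valid.groupby(["cluster_id", "column"])["lcpm"]
        .mean()
        .rename("mean_lcpm")
        .reset_index()
        .rename(columns={"column": "tissue"})
    )
    return out.sort_values(["cluster_id", "tissue"], kind="stable").reset_index(drop=True)
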
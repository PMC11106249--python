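"""Negative-binomial GLM differential expression against pooled somatic controls.

Each analysis contrasts one or more test tissues against the six pooled
somatic control organs within a taxon, with optional age/sex/species
covariates.  The model for gene *g* in sample *s* is

    y_gs ~ NB(mu_gs, phi_g),   log mu_gs = x_s' beta_g + log(effective libsize_s)

with variance ``mu + phi mu^2``.  Gene-wise dispersions are estimated by a
Cox-Reid adjusted profile likelihood on a grid, a trend over abundance is
fitted by lowess, and tagwise values are shrunk toward the trend with a
prior-weighted average (empirical Bayes).  The test-vs-control contrast is
assessed with a quasi-likelihood F statistic whose denominator variance is
itself moderated across genes, and p-values are Benjamini-Hochberg adjusted
within the analysis.

This is deliberately the same model family and testing style as the
standard quasi-likelihood pipelines for bulk RNA-seq; the contract here is
statistical calibration (type-I error, effect recovery), not numerical
identity with any particular implementation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .io import CountMatrix

__all__ = [
    "DesignSpec",
    "DEFit",
    "fit_de",
    "bh_adjust",
    "combined_vs_separate",
    "direction_of",
]

_PHI_GRID = np.logspace(-4, np.log10(5.0), 61)
_LN2 = np.log(2.0)


@dataclasses.dataclass(frozen=True)
class DesignSpec:
    """One differential-expression analysis.

    ``test_tissues`` are contrasted, as a single group, against all samples
    with role ``somatic``.  ``covariates`` name metadata columns (subset of
    age/sex/species) entered as categorical fixed effects.
    """

    analysis_id: str
    test_tissues: tuple[str, ...]
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.test_tissues:
            raise ValueError("DesignSpec needs at least one test tissue")


@dataclasses.dataclass
class DEFit:
    """Diagnostics from a fitted analysis (inputs to the gene-set stage)."""

    analysis_id: str
    sample_ids: pd.Index
    dispersion: pd.Series           # shrunk tagwise phi per gene
    dispersion_trend: pd.Series
    dispersion_tagwise: pd.Series
    residuals: pd.DataFrame         # gene x sample, log2-CPM scale
    zscores: pd.Series              # signed standard-normal gene statistics


# --------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def direction_of(fdr: np.ndarray, log2fc: np.ndarray, alpha: float) -> np.ndarray:
    """'up'/'down' when significant at ``alpha``, else 'ns'."""
    out = np.where(
        (fdr < alpha) & (log2fc > 0), "up", np.where((fdr < alpha) & (log2fc < 0), "down", "ns")
    )
    return out.astype(object)


# --------------------------------------------------------------------------
# NB GLM internals (vectorized over genes; shared design matrix)


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    mu = np.maximum(mu, 1e-10)
    r = 1.0 / np.maximum(phi, 1e-12)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    t2 = (y + r) * np.log((y + r) / (mu + r))
    return 2.0 * (t1 - t2).sum(axis=1)


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    maxit: int = 60,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for NB log-linear models.

    Returns (beta (G,p), mu (G,n), deviance (G,))."""
    G, n = y.shape
    p = X.shape[1]
    mu = np.maximum(y, 0.5).astype(float)
    eta = np.log(mu)
    phi_c = phi[:, None]
    ridge = 1e-10 * np.eye(p)
    dev = _nb_deviance(y, mu, phi)
    beta = np.zeros((G, p))
    for _ in range(maxit):
        W = mu / (1.0 + phi_c * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True)
        XtWz = np.einsum("np,gn->gp", X, W * z, optimize=True)
        beta = np.linalg.solve(XtWX + ridge, XtWz[..., None])[..., 0]
        eta = np.clip(beta @ X.T + offset[None, :], -45.0, 45.0)
        mu = np.exp(eta)
        dev_new = _nb_deviance(y, mu, phi)
        if np.max(np.abs(dev_new - dev) / (np.abs(dev) + 1.0)) < tol:
            dev = dev_new
            break
        dev = dev_new
    return beta, mu, dev


def _apl_grid(y: np.ndarray, mu: np.ndarray, X: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood at each grid dispersion.

    Fitted means are held fixed (one-step approximation)."""
    G, n = y.shape
    out = np.empty((G, grid.size))
    mu = np.maximum(mu, 1e-10)
    gln_y1 = special.gammaln(y + 1.0)
    for k, phi in enumerate(grid):
        r = 1.0 / phi
        ll = (
            special.gammaln(y + r)
            - special.gammaln(r)
            - gln_y1
            + y * np.log(mu / (mu + r))
            + r * np.log(r / (mu + r))
        ).sum(axis=1)
        W = mu / (1.0 + phi * mu)
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True)
        sign, logdet = np.linalg.slogdet(XtWX)
        out[:, k] = ll - 0.5 * logdet
    return out


def _grid_argmax(apl: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Argmax over the grid with parabolic refinement in log-dispersion."""
    i = np.argmax(apl, axis=1)
    lg = np.log(grid)
    est = lg[i].copy()
    interior = (i > 0) & (i < grid.size - 1)
    ii = i[interior]
    rows = np.flatnonzero(interior)
    y0 = apl[rows, ii - 1]
    y1 = apl[rows, ii]
    y2 = apl[rows, ii + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    step = lg[1] - lg[0]
    est[interior] = lg[ii] + np.clip(shift, -1.0, 1.0) * step
    return np.exp(est)


def _dispersion_trend(phi_tag: np.ndarray, abundance: np.ndarray) -> np.ndarray:
    """Lowess trend of log dispersion over average log2-CPM (non-negative)."""
    if phi_tag.size < 10:
        return np.full_like(phi_tag, np.exp(np.mean(np.log(np.maximum(phi_tag, 1e-6)))))
    fit = lowess(
        np.log(np.maximum(phi_tag, 1e-6)),
        abundance,
        frac=0.5,
        it=1,
        xvals=abundance,
    )
    return np.maximum(np.exp(fit), 1e-6)


def _trigamma_inverse(x: float) -> float:
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-10:
            break
    return float(y)


def _fit_scaled_f(s2: np.ndarray, df1: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to sample variances (moderation).

    Returns (prior variance s0^2, prior df d0; d0 may be inf)."""
    z = np.log(np.maximum(s2, 1e-12))
    e = z - special.digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df1 / 2.0))
    if evar > 0:
        df2 = 2.0 * _trigamma_inverse(evar)
        s20 = float(np.exp(emean + special.digamma(df2 / 2.0) - np.log(df2 / 2.0)))
    else:
        df2 = np.inf
        s20 = float(np.exp(emean))
    return s20, df2


# --------------------------------------------------------------------------
# design construction


def _build_design(meta: pd.DataFrame, test_mask: np.ndarray, covariates) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(meta)), test_mask.astype(float)]
    names = ["intercept", "test"]
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"covariate {cov!r} not in metadata")
        levels = sorted(meta[cov].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} does not vary across included samples")
        for lev in levels[1:]:
            cols.append((meta[cov].astype(str) == lev).to_numpy(float))
            names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify an offending covariate: one whose removal restores full rank
        for cov in covariates:
            keep = [j for j, nm in enumerate(names) if not nm.startswith(f"{cov}[")]
            sub = X[:, keep]
            if np.linalg.matrix_rank(sub) == sub.shape[1]:
                raise ValueError(
                    f"design is collinear: covariate {cov!r} is confounded with the "
                    "test/control indicator or another covariate"
                )
        raise ValueError("design matrix is rank-deficient")
    return X, names


# --------------------------------------------------------------------------
# public fitting interface


def fit_de(
    cm: CountMatrix,
    meta: pd.DataFrame,
    nf: pd.DataFrame,
    design: DesignSpec,
    cfg: AnalysisConfig,
    *,
    return_details: bool = False,
):
    """Fit one test-vs-somatic differential expression analysis.

    Returns a frame with ``gene_id, analysis_id, log2fc, pvalue, fdr,
    direction`` (and with ``return_details`` also a :class:`DEFit` holding
    residuals and signed z statistics for the gene-set stage).
    """
    meta = meta.set_index("sample_id").loc[list(cm.sample_ids)].reset_index()
    missing_t = set(design.test_tissues) - set(meta["tissue"])
    if missing_t:
        raise ValueError(f"test tissues absent from metadata: {sorted(missing_t)}")
    include = meta["tissue"].isin(design.test_tissues) | (meta["role"] == "somatic")
    sub_meta = meta[include].reset_index(drop=True)
    test_mask = sub_meta["tissue"].isin(design.test_tissues).to_numpy()
    n_test, n_ctrl = int(test_mask.sum()), int((~test_mask).sum())
    if n_test < 2 or n_ctrl < 2:
        raise ValueError(
            f"analysis {design.analysis_id!r}: need >=2 replicates per group "
            f"(test={n_test}, control={n_ctrl})"
        )
    X, _names = _build_design(sub_meta, test_mask, design.covariates)

    sub_cm = cm.subset_samples(sub_meta["sample_id"])
    y = sub_cm.counts.astype(float)
    eff = (
        nf.set_index("sample_id")
        .loc[list(sub_meta["sample_id"]), "effective_libsize"]
        .to_numpy(float)
    )
    offset = np.log(eff)

    G, n = y.shape
    p = X.shape[1]
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    nonzero = y.sum(axis=1) > 0

    # --- dispersion: tagwise APL -> abundance trend -> EB shrinkage
    phi0 = np.full(G, 0.1)
    _, mu0, _ = _irls(y, X, offset, phi0)
    apl = _apl_grid(y, mu0, X, _PHI_GRID)
    phi_tag = _grid_argmax(apl, _PHI_GRID)
    abundance = np.log2(y.mean(axis=1) / np.mean(eff) * 1e6 + 0.5)
    phi_trend = _dispersion_trend(phi_tag[nonzero], abundance[nonzero]) if nonzero.any() else np.array([])
    trend_full = np.full(G, 0.1)
    trend_full[nonzero] = phi_trend
    d0 = cfg.dispersion_prior_df
    w = df_resid / (df_resid + d0)
    phi_shrunk = np.exp(w * np.log(phi_tag) + (1 - w) * np.log(trend_full))

    # --- full and reduced fits at the shrunk dispersion
    beta, mu, dev_full = _irls(y, X, offset, phi_shrunk)
    X0 = np.delete(X, 1, axis=1)
    _, _, dev_red = _irls(y, X0, offset, phi_shrunk)

    # --- quasi-likelihood F-test with moderated denominator variance
    s2 = np.maximum(dev_full, 0.0) / df_resid
    s20, d0q = _fit_scaled_f(s2[nonzero], df_resid) if nonzero.any() else (1.0, np.inf)
    if np.isfinite(d0q):
        s2_post = (d0q * s20 + df_resid * s2) / (d0q + df_resid)
        df_total = d0q + df_resid
    else:
        s2_post = np.full(G, s20)
        df_total = np.inf
    s2_post = np.maximum(s2_post, 1e-8)
    fstat = np.maximum(dev_red - dev_full, 0.0) / s2_post
    if np.isfinite(df_total):
        pvals = stats.f.sf(fstat, 1, df_total)
    else:
        pvals = stats.chi2.sf(fstat, 1)

    log2fc = beta[:, 1] / _LN2
    # genes with no counts at all carry no evidence
    log2fc[~nonzero] = 0.0
    pvals[~nonzero] = 1.0
    pvals = np.clip(pvals, 0.0, 1.0)
    fdr = bh_adjust(pvals)

    result = pd.DataFrame(
        {
            "gene_id": sub_cm.gene_ids,
            "analysis_id": design.analysis_id,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "direction": direction_of(fdr, log2fc, cfg.fdr_alpha),
        }
    ).sort_values("gene_id", kind="stable").reset_index(drop=True)

    if not return_details:
        return result

    lcpm_obs = np.log2((y + 0.5) / eff * 1e6)
    lcpm_fit = np.log2((mu + 0.5) / eff * 1e6)
    resid = pd.DataFrame(lcpm_obs - lcpm_fit, index=sub_cm.gene_ids, columns=sub_cm.sample_ids)
    z = np.sign(log2fc) * stats.norm.isf(np.clip(pvals, 1e-300, 1.0) / 2.0)
    details = DEFit(
        analysis_id=design.analysis_id,
        sample_ids=sub_cm.sample_ids,
        dispersion=pd.Series(phi_shrunk, index=sub_cm.gene_ids),
        dispersion_trend=pd.Series(trend_full, index=sub_cm.gene_ids),
        dispersion_tagwise=pd.Series(phi_tag, index=sub_cm.gene_ids),
        residuals=resid,
        zscores=pd.Series(z, index=sub_cm.gene_ids),
    )
    return result, details


def combined_vs_separate(
    cm: CountMatrix,
    meta: pd.DataFrame,
    nf: pd.DataFrame,
    cfg: AnalysisConfig,
    *,
    extra_covariates: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run the combined-age and per-age appendage analyses.

    The combined model treats every appendage sample as one tissue with age
    and sex covariates; the per-age models drop the age covariate (within
    one age it would be collinear with the test indicator) and keep sex.
    Returns ``(combined table, {age: table})``.
    """
    meta = meta.set_index("sample_id").loc[list(cm.sample_ids)].reset_index()
    app = meta[meta["role"] == "appendage"]
    if app.empty:
        raise ValueError("no appendage samples present")
    ages = sorted(app["age"].astype(str).unique())
    if len(ages) < 2:
        raise ValueError("combined-vs-separate analysis needs >=2 appendage age levels")
    tissues = tuple(sorted(app["tissue"].unique()))

    combined = fit_de(
        cm,
        meta,
        nf,
        DesignSpec("combined", tissues, ("age", "sex") + extra_covariates),
        cfg,
    )

    per_age: dict[str, pd.DataFrame] = {}
    for age in ages:
        keep = (meta["role"] == "somatic") | (
            (meta["role"] == "appendage") & (meta["age"].astype(str) == age)
        )
        ids = meta.loc[keep, "sample_id"]
        sub_cm = cm.subset_samples(ids)
        sub_meta = meta[keep]
        age_tissues = tuple(
            sorted(sub_meta.loc[sub_meta["role"] == "appendage", "tissue"].unique())
        )
        per_age[age] = fit_de(
            sub_cm,
            sub_meta,
            nf,
            DesignSpec(f"age_{age}", age_tissues, ("sex",) + extra_covariates),
            cfg,
        )
    return combined, per_age
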
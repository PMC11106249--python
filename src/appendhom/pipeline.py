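"""End-to-end orchestration: counts in, homology calls and report out.

Chains the stages for each taxon (filter -> TMM -> grouped LCPM -> per-tissue
DE against pooled somatic controls -> tau lists), then runs the
within-species control filter, outgroup-conditioned homology calls for both
the differential-expression and tau evidence modes, shared-proportion
tables, and optionally SOM clustering, into one deterministic JSON report.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .config import AnalysisConfig
from .diffexpr import DesignSpec, combined_vs_separate, fit_de
from .homology import (
    build_report,
    call_homology,
    shared_proportions,
    tau_homology,
    within_species_distinct,
)
from .io import CountMatrix
from .preprocess import filter_by_expression, grouped_lcpm, tmm_factors
from .som import choose_k, cluster_summaries, som_input_genes, train_som
from .specificity import specificity_lists

__all__ = ["TaxonResults", "run_taxon", "run_pipeline"]


@dataclasses.dataclass
class TaxonResults:
    """Per-taxon intermediate results."""

    taxon: str
    taxon_role: str
    filtered: CountMatrix
    norm_factors: pd.DataFrame
    lcpm: pd.DataFrame
    de: dict[str, pd.DataFrame]          # analysis_id -> DE table
    tau: pd.DataFrame
    appendage_tissues: tuple[str, ...]
    control_tissues: tuple[str, ...]


def _covariates_for(meta: pd.DataFrame) -> tuple[str, ...]:
    covs = []
    if meta["sex"].nunique() > 1:
        covs.append("sex")
    if meta["species"].nunique() > 1:
        covs.append("species")
    return tuple(covs)


def run_taxon(
    cm: CountMatrix,
    meta: pd.DataFrame,
    cfg: AnalysisConfig,
    *,
    combined_age: bool = False,
) -> TaxonResults:
    """Preprocess one taxon and run every per-tissue DE analysis.

    Each appendage and each control tissue is contrasted, separately,
    against the pooled somatic organs.  With ``combined_age`` the appendage
    tissues are additionally analyzed together (age + sex covariates) under
    the analysis id ``combined``, alongside the per-age analyses.
    """
    taxon = meta["taxon"].iloc[0]
    role = meta["taxon_role"].iloc[0] if "taxon_role" in meta.columns else ""
    filtered = filter_by_expression(cm, meta, cfg)
    nf = tmm_factors(filtered, cfg)
    lcpm = grouped_lcpm(filtered, meta, nf, cfg)

    appendage = tuple(sorted(meta.loc[meta["role"] == "appendage", "tissue"].unique()))
    controls = tuple(sorted(meta.loc[meta["role"] == "control", "tissue"].unique()))
    covs = _covariates_for(meta)

    de: dict[str, pd.DataFrame] = {}
    if combined_age and appendage:
        # the per-age analyses already contrast each appendage age against
        # the somatic pool, so separate per-tissue appendage fits would be
        # duplicates in the one-tissue-per-age layout
        combined, per_age = combined_vs_separate(filtered, meta, nf, cfg)
        de["combined"] = combined
        for age, table in per_age.items():
            de[f"age_{age}"] = table
    else:
        for tissue in appendage:
            de[tissue] = fit_de(filtered, meta, nf, DesignSpec(tissue, (tissue,), covs), cfg)
    for tissue in controls:
        de[tissue] = fit_de(filtered, meta, nf, DesignSpec(tissue, (tissue,), covs), cfg)

    tau_table = specificity_lists(lcpm, cfg, control_tissues=set(controls))
    return TaxonResults(
        taxon=taxon,
        taxon_role=role,
        filtered=filtered,
        norm_factors=nf,
        lcpm=lcpm,
        de=de,
        tau=tau_table,
        appendage_tissues=appendage,
        control_tissues=controls,
    )


def run_pipeline(
    datasets: dict[str, tuple[CountMatrix, pd.DataFrame]],
    cfg: AnalysisConfig,
    *,
    include_som: bool = False,
) -> dict:
    """Run the full homology assessment over ingroup_a, ingroup_b, outgroup.

    ``datasets`` maps taxon name to (counts, metadata); metadata must carry
    a ``taxon_role`` column.  Returns a dict with per-taxon results, the
    homology call tables per evidence mode, shared-proportion tables, and
    the JSON report text under ``"report"``.
    """
    by_role: dict[str, TaxonResults] = {}
    for taxon, (cm, meta) in datasets.items():
        if "taxon_role" not in meta.columns:
            raise ValueError(f"metadata for {taxon!r} lacks a taxon_role column")
        res = run_taxon(cm, meta, cfg, combined_age=(meta["taxon_role"].iloc[0] == "ingroup_a"))
        by_role[res.taxon_role] = res
    for need in ("ingroup_a", "ingroup_b"):
        if need not in by_role:
            raise ValueError(f"pipeline needs a taxon with role {need!r}")
    a, b = by_role["ingroup_a"], by_role["ingroup_b"]
    out = by_role.get("outgroup")

    prof_a = within_species_distinct(
        {aid: t for aid, t in a.de.items() if aid not in a.control_tissues},
        {c: a.de[c] for c in a.control_tissues},
    )
    prof_b = within_species_distinct(
        {aid: t for aid, t in b.de.items() if aid not in b.control_tissues},
        {c: b.de[c] for c in b.control_tissues},
    )
    outgroup_tables = {c: out.de[c] for c in out.control_tissues} if out else None
    calls_de = call_homology(prof_a, prof_b, outgroup_tables, evidence_mode="de")

    horn_analyses = sorted(
        set(a.de) - set(a.control_tissues)
    )
    antler_tissues = list(b.appendage_tissues)
    props_de = shared_proportions(calls_de, horn_analyses, antler_tissues)

    tau_calls = {}
    tau_props = {}
    for mode in ("strict", "relaxed"):
        calls = tau_homology(
            a.tau,
            b.tau,
            out.tau if out else None,
            mode,
            appendage_a=set(a.appendage_tissues),
            appendage_b=set(b.appendage_tissues),
        )
        tau_calls[mode] = calls
        tau_props[mode] = shared_proportions(
            calls, list(a.appendage_tissues), antler_tissues
        )

    results = {
        "taxa": by_role,
        "profiles": {"ingroup_a": prof_a, "ingroup_b": prof_b},
        "calls_de": calls_de,
        "proportions_de": props_de,
        "calls_tau": tau_calls,
        "proportions_tau": tau_props,
    }

    if include_som:
        merged, direction_profile = _merged_profiles(by_role)
        genes = som_input_genes(direction_profile)
        if len(genes) >= 4:
            model = train_som(merged.loc[genes], cfg, cfg.rng_seed)
            model = choose_k(model, cfg, cfg.rng_seed + 1)
            lcpm_all = pd.concat(
                [r.lcpm for r in by_role.values()], ignore_index=True
            )
            results["som"] = model
            results["som_summary"] = cluster_summaries(
                model, lcpm_all, sentinel=cfg.lcpm_zero_sentinel
            )

    sections = {
        "homology_de": calls_de,
        "proportions_de": props_de,
        "homology_tau_strict": tau_calls["strict"],
        "homology_tau_relaxed": tau_calls["relaxed"],
        "proportions_tau_strict": tau_props["strict"],
        "proportions_tau_relaxed": tau_props["relaxed"],
    }
    if "som_summary" in results:
        sections["som_cluster_means"] = results["som_summary"]
    results["report"] = build_report(**sections)
    return results


def _merged_profiles(by_role: dict[str, TaxonResults]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect gene universes across taxa; concatenate tissue LCPM columns
    and DE direction columns (prefixed by taxon)."""
    from .homology import assemble_profile

    wides, dir_tables = [], {}
    for role in sorted(by_role):
        r = by_role[role]
        wide = r.lcpm.pivot_table(index="gene_id", columns="tissue", values="lcpm", sort=True)
        wide.columns = [f"{r.taxon}:{c}" for c in wide.columns]
        wides.append(wide)
        for aid, table in r.de.items():
            dir_tables[f"{r.taxon}:{aid}"] = table
    common = wides[0].index
    for w in wides[1:]:
        common = common.intersection(w.index)
    merged = pd.concat([w.loc[common] for w in wides], axis=1)
    directions = assemble_profile(dir_tables, universe=list(common))
    return merged, directions
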
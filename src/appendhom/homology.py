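"""Cross-species homology calls from within-species evidence plus an outgroup.

The inference has three steps, mirrored by the functions here:

1. Within each ingroup, keep only appendage signals that are *distinct*
   from that species' own skin/bone controls: a significant appendage
   signal survives only if every within-species control is not significant
   or significant in the opposite direction
   (:func:`within_species_distinct`).
2. A gene is a homology candidate when both ingroups retain a signal in
   the same direction.
3. The candidate is called *homologous* only if every outgroup tissue is
   not significant, absent from the outgroup universe, or significant in
   the opposite direction (:func:`call_homology`).  Without outgroup data
   the call is untestable — outgroup conditioning is the point of the
   procedure, so it is never silently skipped.

The same shared-then-not-in-outgroup logic applies to tau tissue
specificity (:func:`tau_homology`), where "signal" means assignment to an
appendage tissue at the strict or relaxed threshold.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

__all__ = [
    "EvidenceProfile",
    "assemble_profile",
    "within_species_distinct",
    "decide_homology",
    "call_homology",
    "tau_homology",
    "shared_proportions",
    "build_report",
]

DIRECTIONS = ("up", "down", "ns", "absent")
_OPP = {"up": "down", "down": "up"}


@dataclasses.dataclass
class EvidenceProfile:
    """Per-gene direction map after within-species control filtering.

    ``directions``: gene x analysis frame with values in
    {up, down, ns, absent}; ``excluded``: genes whose every appendage signal
    was removed because a within-species control shared its direction,
    mapped to the offending (analysis, control) pairs; ``control_flags``:
    gene -> flags for opposite-direction control significance (kept, noted).
    """

    directions: pd.DataFrame
    excluded: dict[str, list[str]]
    control_flags: dict[str, list[str]]


def assemble_profile(tables: dict[str, pd.DataFrame], universe=None) -> pd.DataFrame:
    """Gene x analysis direction frame from DE result tables.

    Genes absent from an analysis' universe are marked ``absent`` (distinct
    from ``ns``: absent means the gene was filtered out of that taxon's
    matrix, not tested and retained).
    """
    if universe is None:
        universe = sorted(set().union(*(set(t["gene_id"]) for t in tables.values())))
    out = pd.DataFrame("absent", index=pd.Index(universe, name="gene_id"),
                       columns=sorted(tables), dtype=object)
    for aid, table in tables.items():
        s = table.set_index("gene_id")["direction"]
        common = out.index.intersection(s.index)
        out.loc[common, aid] = s.loc[common]
    return out


def within_species_distinct(
    test: dict[str, pd.DataFrame],
    controls: dict[str, pd.DataFrame],
    *,
    required_controls: tuple[str, ...] = (),
) -> EvidenceProfile:
    """Filter appendage signals against the taxon's own control tissues.

    ``test`` maps appendage analysis ids to DE tables, ``controls`` maps
    control names (e.g. ``skin``, ``bone``) to theirs.  A signal survives
    only when every control is ns/absent or significant in the opposite
    direction; a same-direction control removes it.  Opposite-direction
    control significance is kept but flagged (the MYOC/TNRC6A situation:
    underexpressed in appendages while overexpressed in control bone).
    """
    for name in required_controls:
        if name not in controls:
            raise ValueError(f"missing within-species control table: {name!r}")
    prof = assemble_profile(test)
    ctrl = assemble_profile(controls, universe=list(prof.index)) if controls else None
    excluded: dict[str, list[str]] = {}
    flags: dict[str, list[str]] = {}
    if ctrl is not None:
        for gene in prof.index:
            removed_here: list[str] = []
            gene_flags: list[str] = []
            for aid in prof.columns:
                d = prof.at[gene, aid]
                if d not in _OPP:
                    continue
                for cname in ctrl.columns:
                    cd = ctrl.at[gene, cname]
                    if cd == d:
                        prof.at[gene, aid] = "ns"
                        removed_here.append(f"{aid}~{cname}")
                        break
                    if cd == _OPP[d]:
                        gene_flags.append(f"opposite_in_{cname}")
            if gene_flags:
                flags[gene] = sorted(set(gene_flags))
            had_signal = removed_here and not prof.loc[gene].isin(["up", "down"]).any()
            if had_signal:
                excluded[gene] = removed_here
    return EvidenceProfile(directions=prof, excluded=excluded, control_flags=flags)


def decide_homology(
    signals_a: dict[str, str],
    signals_b: dict[str, str],
    outgroup: dict[str, str] | None,
) -> tuple[str, str | None, tuple[str, ...], tuple[str, ...]]:
    """Pure decision rule for one gene.

    ``signals_a``/``signals_b`` map each ingroup analysis to a direction in
    {up, down, ns, absent} (already control-filtered); ``outgroup`` maps
    outgroup tissues to directions, or is None when no outgroup data exist.

    Returns ``(status, shared_direction, support_a, support_b)``.
    """
    sup_a = {d: tuple(sorted(a for a, v in signals_a.items() if v == d)) for d in ("up", "down")}
    sup_b = {d: tuple(sorted(a for a, v in signals_b.items() if v == d)) for d in ("up", "down")}
    shared = [d for d in ("up", "down") if sup_a[d] and sup_b[d]]
    if not shared:
        return "not_shared", None, tuple(), tuple()
    if outgroup is None:
        d = shared[0]
        return "untestable_missing_outgroup", d, sup_a[d], sup_b[d]
    passing = [
        d
        for d in shared
        if all(v in ("ns", "absent", _OPP[d]) for v in outgroup.values())
    ]
    if passing:
        d = max(passing, key=lambda d: (len(sup_a[d]) + len(sup_b[d]), d))
        return "homologous", d, sup_a[d], sup_b[d]
    d = shared[0]
    return "excluded_outgroup", d, sup_a[d], sup_b[d]


def call_homology(
    profile_a: EvidenceProfile,
    profile_b: EvidenceProfile,
    outgroup: dict[str, pd.DataFrame] | None,
    *,
    evidence_mode: str = "de",
) -> pd.DataFrame:
    """Combine two ingroups' filtered evidence with outgroup conditioning.

    Candidates are genes with a surviving signal in either ingroup, plus
    genes whose signals were removed by within-species controls (these are
    reported with status ``excluded_within_species_control``).  Outgroup
    directions are taken per outgroup analysis; genes filtered out of the
    outgroup universe count as non-contradicting (``absent``).
    """
    dir_a, dir_b = profile_a.directions, profile_b.directions
    out_prof = assemble_profile(outgroup) if outgroup else None
    genes = sorted(
        {
            g
            for g in set(dir_a.index) | set(dir_b.index)
            if (g in dir_a.index and dir_a.loc[g].isin(["up", "down"]).any())
            or (g in dir_b.index and dir_b.loc[g].isin(["up", "down"]).any())
        }
        | set(profile_a.excluded)
        | set(profile_b.excluded)
    )
    rows = []
    for gene in genes:
        sa = dict(dir_a.loc[gene]) if gene in dir_a.index else {}
        sb = dict(dir_b.loc[gene]) if gene in dir_b.index else {}
        og = None
        if out_prof is not None:
            og = dict(out_prof.loc[gene]) if gene in out_prof.index else \
                {c: "absent" for c in out_prof.columns}
        status, d, sup_a, sup_b = decide_homology(sa, sb, og)
        if status == "not_shared" and (gene in profile_a.excluded or gene in profile_b.excluded):
            status = "excluded_within_species_control"
        flags = sorted(
            set(profile_a.control_flags.get(gene, [])) | set(profile_b.control_flags.get(gene, []))
        )
        rows.append(
            {
                "gene_id": gene,
                "evidence_mode": evidence_mode,
                "horn_support": sup_a,
                "antler_support": sup_b,
                "shared_direction": d,
                "status": status,
                "control_flags": ",".join(flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "evidence_mode",
            "horn_support",
            "antler_support",
            "shared_direction",
            "status",
            "control_flags",
        ],
    )


# --------------------------------------------------------------------------
# tau-based homology


def _tau_assignment(rec: pd.Series, mode: str) -> set[str]:
    if mode == "strict":
        return {rec["strict_tissue"]} if rec["strict_tissue"] else set()
    if mode == "relaxed":
        return set(rec["relaxed_tissues"])
    raise ValueError(f"unknown threshold mode {mode!r} (use 'strict' or 'relaxed')")


def tau_homology(
    tau_a: pd.DataFrame,
    tau_b: pd.DataFrame,
    tau_out: pd.DataFrame | None,
    threshold_mode: str,
    *,
    appendage_a: set[str],
    appendage_b: set[str],
) -> pd.DataFrame:
    """Homology calls from tissue-specificity assignments.

    A gene is homologous when it is specific (at the given threshold) to at
    least one appendage tissue in both ingroups, not specific to either
    ingroup's skin/bone/cartilage controls, and not specific to any
    outgroup tissue at the matching threshold.
    """
    if threshold_mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")

    def _indexed(df):
        if df is None:
            return None
        if df.empty:
            return pd.DataFrame(
                columns=["taxon", "tau", "strict_tissue", "relaxed_tissues",
                         "control_specific", "excluded"],
                index=pd.Index([], name="gene_id"),
            )
        return df.set_index("gene_id")

    a = _indexed(tau_a)
    b = _indexed(tau_b)
    out = _indexed(tau_out)
    rows = []
    for gene in sorted(set(a.index) | set(b.index)):
        assign_a = _tau_assignment(a.loc[gene], threshold_mode) if gene in a.index else set()
        assign_b = _tau_assignment(b.loc[gene], threshold_mode) if gene in b.index else set()
        sup_a = tuple(sorted(assign_a & appendage_a))
        sup_b = tuple(sorted(assign_b & appendage_b))
        if not (sup_a or sup_b):
            continue
        ctrl_a = bool(a.at[gene, "control_specific"]) if gene in a.index else False
        ctrl_b = bool(b.at[gene, "control_specific"]) if gene in b.index else False
        if ctrl_a or ctrl_b:
            status = "excluded_within_species_control"
        elif not (sup_a and sup_b):
            status = "not_shared"
        elif out is None:
            status = "untestable_missing_outgroup"
        else:
            out_specific = (
                gene in out.index and bool(_tau_assignment(out.loc[gene], threshold_mode))
            )
            status = "excluded_outgroup" if out_specific else "homologous"
        rows.append(
            {
                "gene_id": gene,
                "evidence_mode": f"tau_{threshold_mode}",
                "horn_support": sup_a,
                "antler_support": sup_b,
                "shared_direction": None,
                "status": status,
                "control_flags": "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "evidence_mode",
            "horn_support",
            "antler_support",
            "shared_direction",
            "status",
            "control_flags",
        ],
    )


# --------------------------------------------------------------------------
# summaries


def shared_proportions(
    calls: pd.DataFrame,
    horn_analyses: list[str],
    antler_tissues: list[str],
) -> pd.DataFrame:
    """Shared homologous-gene counts and proportions, horn x antler.

    For each horn analysis *h*, ``total`` counts homologous genes supported
    by *h* (a gene supported by several horn analyses counts toward each),
    ``shared_count(h, t)`` those also supported by antler tissue *t*, and
    ``proportion = shared_count / total`` (missing when total is zero).
    """
    hom = calls[calls["status"] == "homologous"]
    rows = []
    for h in horn_analyses:
        mask_h = hom["horn_support"].map(lambda s: h in s)
        total = int(mask_h.sum())
        for t in antler_tissues:
            shared = int((mask_h & hom["antler_support"].map(lambda s: t in s)).sum())
            rows.append(
                {
                    "horn_analysis": h,
                    "antler_tissue": t,
                    "shared_count": shared,
                    "total": total,
                    "proportion": shared / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        def cell(v):
            if isinstance(v, (tuple, set, frozenset)):
                return sorted(v)
            if v is None or (isinstance(v, (float, np.floating)) and np.isnan(v)):
                return None
            if isinstance(v, np.integer):
                return int(v)
            if isinstance(v, np.floating):
                return float(v)
            return v
        return [
            {k: cell(v) for k, v in rec.items()}
            for rec in obj.to_dict(orient="records")
        ]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    return obj


def build_report(**sections) -> str:
    """Serialize stage outputs into one deterministic JSON document.

    Accepts any mix of DataFrames, dicts and scalars by keyword; two runs
    on identical inputs produce byte-identical text.
    """
    if not sections:
        raise ValueError("report needs at least one section")
    payload = {k: _jsonable(v) for k, v in sorted(sections.items())}
    return json.dumps(payload, indent=2, sort_keys=True, allow_nan=False, default=str)
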
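"""Packaged worked-example tables of homologous tissue-specific genes.

Two small gene x tissue indicator matrices ship with the package: the
strict-specificity list (9 genes, each specific to a single cattle horn-bud
age and a single deer antler tissue) and the relaxed-specificity list (41
genes: 11 supported by 2-month-old horn buds only, 23 by 4-month-old only,
7 by both, with multi-tissue antler assignments).  They drive desk-scale
tests of the shared-proportion bookkeeping without any external data.

A few individual deer-column placements are not uniquely determined by the
row and column summaries these tables must satisfy; the packaged matrices
fix one completion consistent with every per-gene assignment count, the
per-age totals (18 and 30), and every shared-proportion value.  All
quantities the tests check are invariant to the undetermined choices;
single-cell deer assignments of some relaxed-list genes are reconstructions
rather than authoritative.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "CATTLE_FIXTURE_TISSUES",
    "DEER_FIXTURE_TISSUES",
    "fixture_tables",
    "fixture_homology_calls",
]

CATTLE_FIXTURE_TISSUES = ("horn_bud_2mo", "horn_bud_4mo")
DEER_FIXTURE_TISSUES = (
    "pedicle",
    "antler_tip",
    "mineralized_cartilage",
    "cartilage_zone",
    "transition_zone",
    "pre_cartilage",
    "reserve_mesenchyme",
)


def _load(name: str) -> pd.DataFrame:
    with resources.files("appendhom.data").joinpath(name).open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    df["gene_id"] = df["gene_id"].str.upper()
    return df


def fixture_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (strict fixture, relaxed fixture) indicator tables.

    Each has ``gene_id`` plus one 0/1 column per tissue; every row marks at
    least one cattle and one deer tissue (the tables list only genes that
    met the homology criteria).
    """
    return _load("strict_specificity_fixture.tsv"), _load("relaxed_specificity_fixture.tsv")


def fixture_homology_calls(fixture: pd.DataFrame, evidence_mode: str) -> pd.DataFrame:
    """Convert a fixture indicator table into a homology-call table.

    Every fixture gene is a homologous call by construction; cattle columns
    become ``horn_support`` and deer columns ``antler_support``, feeding
    :func:`appendhom.homology.shared_proportions` directly.
    """
    rows = []
    for _, rec in fixture.iterrows():
        horn = tuple(t for t in CATTLE_FIXTURE_TISSUES if rec[t] == 1)
        antler = tuple(t for t in DEER_FIXTURE_TISSUES if rec[t] == 1)
        rows.append(
            {
                "gene_id": rec["gene_id"],
                "evidence_mode": evidence_mode,
                "horn_support": horn,
                "antler_support": antler,
                "shared_direction": None,
                "status": "homologous",
                "control_flags": "",
            }
        )
    return pd.DataFrame(rows)
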
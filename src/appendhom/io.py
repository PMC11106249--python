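"""Readers, writers and the core data containers.

The pipeline starts at a gene-level count matrix (genes x samples, TSV) with
a per-sample metadata table declaring each sample's taxon, tissue and role
(appendage / control / somatic).  Gene sets arrive as GMT.  All result
tables are written as UTF-8 TSV with ``NA`` for missing values, no quoting,
rows sorted by gene then tissue/analysis so that reruns diff cleanly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GeneSet",
    "SOMATIC_ORGANS",
    "ROLES",
    "TAXON_ROLES",
    "LoadError",
    "read_counts",
    "read_gmt",
    "write_table",
    "read_table",
    "validate_meta",
]

#: The fixed pooled somatic reference organs used as the DE baseline.
SOMATIC_ORGANS = ("muscle", "kidney", "heart", "liver", "spleen", "lung")

#: Allowed sample roles.
ROLES = ("appendage", "control", "somatic")

#: Allowed taxon roles; display aliases (cattle/deer/pig) are free-form and
#: live in the metadata's ``taxon`` column, with the phylogenetic role
#: declared in ``taxon_role``.
TAXON_ROLES = ("ingroup_a", "ingroup_b", "outgroup")

META_REQUIRED = ("sample_id", "taxon", "tissue", "role", "age", "sex", "species", "replicate")


class LoadError(ValueError):
    """Raised when an input file violates the declared schema."""


@dataclasses.dataclass
class GeneSet:
    """A named collection of gene symbols (GMT line).

    Symbols are stored uppercase so sets match across genome annotations
    that differ in capitalization conventions.
    """

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(m.upper() for m in self.members))


class CountMatrix:
    """Integer gene x sample count matrix with identifiers.

    Parameters
    ----------
    gene_ids:
        Unique gene symbols (stored uppercase).
    sample_ids:
        Unique sample identifiers, in column order.
    counts:
        Nonnegative integer matrix, shape (genes, samples).
    """

    def __init__(self, gene_ids, sample_ids, counts) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x samples)")
        if np.issubdtype(counts.dtype, np.floating):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        counts = counts.astype(np.int64, copy=False)
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        gene_ids = pd.Index([str(g).upper() for g in gene_ids], name="gene_id")
        sample_ids = pd.Index([str(s) for s in sample_ids], name="sample_id")
        if gene_ids.has_duplicates:
            dups = gene_ids[gene_ids.duplicated()].unique().tolist()
            raise LoadError(f"duplicated gene ids: {dups}")
        if sample_ids.has_duplicates:
            dups = sample_ids[sample_ids.duplicated()].unique().tolist()
            raise LoadError(f"duplicated sample ids: {dups}")
        if counts.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError("counts shape does not match identifiers")
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.counts = counts

    # -- derived -----------------------------------------------------------

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample column sums of raw counts."""
        return self.counts.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    # -- helpers -----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.index, df.columns, df.to_numpy())

    def subset_genes(self, genes) -> "CountMatrix":
        idx = self.gene_ids.get_indexer([g.upper() for g in genes])
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes not present: {missing}")
        return CountMatrix(self.gene_ids[idx], self.sample_ids, self.counts[idx])

    def subset_samples(self, samples) -> "CountMatrix":
        idx = self.sample_ids.get_indexer(list(samples))
        if (idx < 0).any():
            missing = [s for s, i in zip(samples, idx) if i < 0]
            raise KeyError(f"samples not present: {missing}")
        return CountMatrix(self.gene_ids, self.sample_ids[idx], self.counts[:, idx])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"CountMatrix({g} genes x {s} samples)"


def validate_meta(meta: pd.DataFrame, *, require_replicates: bool = False) -> pd.DataFrame:
    """Validate a sample metadata table and return it in canonical order.

    Checks the required columns, the role vocabulary, the somatic-organ
    whitelist, and sample-id uniqueness.  With ``require_replicates`` every
    (taxon, tissue) group must hold at least three samples, the minimum for
    the statistical stages.
    """
    missing = [c for c in META_REQUIRED if c not in meta.columns]
    if missing:
        raise LoadError(f"metadata missing required columns: {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise LoadError(f"duplicated sample ids in metadata: {dups}")
    bad_roles = sorted(set(meta["role"]) - set(ROLES))
    if bad_roles:
        raise LoadError(f"unknown roles {bad_roles}; allowed: {list(ROLES)}")
    somatic = meta.loc[meta["role"] == "somatic", "tissue"]
    bad_organs = sorted(set(somatic) - set(SOMATIC_ORGANS))
    if bad_organs:
        raise LoadError(
            f"somatic tissues {bad_organs} outside the fixed organ list {list(SOMATIC_ORGANS)}"
        )
    if "taxon_role" in meta.columns:
        bad = sorted(set(meta["taxon_role"]) - set(TAXON_ROLES))
        if bad:
            raise LoadError(f"unknown taxon roles {bad}; allowed: {list(TAXON_ROLES)}")
    if require_replicates:
        sizes = meta.groupby(["taxon", "tissue"]).size()
        small = sizes[sizes < 3]
        if not small.empty:
            raise LoadError(f"groups with <3 replicates: {small.index.tolist()}")
    return meta.sort_values("sample_id", kind="stable").reset_index(drop=True)


def read_counts(path: str | Path, meta_path: str | Path) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a counts TSV and its metadata TSV into validated containers.

    The counts file is tab-separated with gene symbols in the first column
    and a header row of sample ids.  Every sample must appear in the
    metadata; the returned metadata is reordered to match the count columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise LoadError(f"duplicated gene rows in {path}: {dups}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise LoadError(f"missing count at gene {df.index[r]!r}, sample {df.columns[c]!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise LoadError(f"non-numeric count at gene {df.index[r]!r}, sample {df.columns[c]!r}")
    if not np.allclose(arr, np.round(arr)):
        r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise LoadError(f"non-integer count at gene {df.index[r]!r}, sample {df.columns[c]!r}")
    meta = pd.read_csv(meta_path, sep="\t", na_values=["NA"], keep_default_na=False)
    meta = validate_meta(meta)
    absent = [s for s in df.columns if s not in set(meta["sample_id"])]
    if absent:
        raise LoadError(f"samples missing from metadata: {absent}")
    meta = meta.set_index("sample_id").loc[list(df.columns)].reset_index()
    return CountMatrix.from_frame(df), meta


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise LoadError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise LoadError(f"{path}: line {lineno} has no members")
            sets.append(GeneSet(name, desc, frozenset(members)))
    return sets


_SORT_PREFERENCE = ("gene_id", "set_name", "cluster_id", "analysis_id", "taxon", "tissue", "sample_id")


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as deterministic TSV.

    Rows are sorted by gene then tissue/analysis (falling back to whichever
    identifier columns are present), missing values become ``NA``, and no
    quoting is applied.  ``read_table`` round-trips the output.
    """
    if records is None:
        raise ValueError("records must not be None")
    df = records.copy()
    keys = [c for c in _SORT_PREFERENCE if c in df.columns]
    if keys:
        df = df.sort_values(keys, kind="stable")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (``NA`` means missing)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
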
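"""Analysis configuration.

One frozen-by-convention dataclass holds every threshold the pipeline uses:
the expression filter (counts per million), the FDR cutoff, the two tau
specificity thresholds, the log-CPM zero sentinel, and the SOM / k-medoid
settings.  Defaults match the comparative design the pipeline targets; all
are overridable from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Thresholds and settings shared across pipeline stages.

    Parameters
    ----------
    fdr_alpha:
        Benjamini-Hochberg FDR cutoff for calling a gene differentially
        expressed (default 0.05).
    cpm_min:
        A gene is retained if every sample of at least one tissue reaches
        this counts-per-million level (default 10).
    cpm_total_min:
        ... and if its CPM summed over all samples reaches this level
        (default 15).
    tau_strict, tau_relaxed:
        Tissue-specificity (tau) thresholds for the strict single-tissue and
        relaxed multi-tissue specific gene lists (0.9 and 0.75).
    relaxed_assign_frac:
        Under the relaxed threshold a gene is assigned to every tissue whose
        relative expression is at least this fraction of the maximum (0.75).
    lcpm_zero_sentinel:
        Log2-CPM value recorded for a (gene, tissue) group whose summed raw
        count is zero (-21); downstream summaries treat it as "not expressed".
    som_rows, som_cols:
        Self-organizing-map grid (20 x 20).
    som_epochs:
        Full passes over the data during online SOM training.
    som_alpha_start, som_alpha_end:
        Linearly declining learning rate.
    kmedoid_k_max:
        Largest cluster count evaluated by the gap statistic.
    gap_B:
        Number of uniform reference datasets for the gap statistic.
    rng_seed:
        Master seed for every stochastic stage.
    """

    fdr_alpha: float = 0.05
    cpm_min: float = 10.0
    cpm_total_min: float = 15.0
    tau_strict: float = 0.9
    tau_relaxed: float = 0.75
    relaxed_assign_frac: float = 0.75
    lcpm_zero_sentinel: float = -21.0
    som_rows: int = 20
    som_cols: int = 20
    som_epochs: int = 100
    som_alpha_start: float = 0.05
    som_alpha_end: float = 0.01
    kmedoid_k_max: int = 8
    gap_B: int = 20
    rng_seed: int = 0
    # TMM trim fractions (published defaults of the method)
    tmm_trim_m: float = 0.30
    tmm_trim_a: float = 0.05
    # empirical-Bayes prior degrees of freedom for dispersion shrinkage
    dispersion_prior_df: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if not 0.0 < self.tau_relaxed < self.tau_strict <= 1.0:
            raise ValueError("need 0 < tau_relaxed < tau_strict <= 1")
        if self.som_rows < 1 or self.som_cols < 1:
            raise ValueError("SOM grid dimensions must be positive")
        if self.som_rows * self.som_cols > 1 and (self.som_rows < 2 and self.som_cols < 2):
            raise ValueError("SOM grid must be at least 2 units on some axis")
        if self.cpm_min < 0 or self.cpm_total_min < 0:
            raise ValueError("CPM thresholds must be nonnegative")
        if not 0.0 < self.relaxed_assign_frac <= 1.0:
            raise ValueError("relaxed_assign_frac must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
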
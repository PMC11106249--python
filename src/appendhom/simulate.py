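"""Three-taxon negative-binomial count simulator with known truth labels.

The generator emulates the target comparative design: two ingroup taxa bearing cranial
appendages (cattle with two horn-bud ages and a skin control; deer with
antler tissues plus skin and bone controls) and one outgroup without
appendages (pig skin, bone and cartilage), each with the six pooled
somatic control organs and three replicates per tissue.  Counts are drawn
as NB(mu, phi) with variance ``mu + phi mu^2``, gene-wise dispersions
log-uniform, and per-sample library-size factors log-uniform so that TMM
normalization has real work to do.

Planted gene classes give every downstream stage a measurable truth:

* ``homologous_appendage`` — shifted by ``effect_log2fc`` in the appendage
  tissues of **both** ingroups, unshifted in all controls and the outgroup.
* ``skin_shared`` — shifted in the appendage *and* skin tissues of one
  ingroup (should be excluded by the within-species control filter).
* ``bone_program`` — shifted in ingroup appendages and in every bone-like
  control of all taxa, including the outgroup (should be excluded by the
  within-species or outgroup conditioning step).
* ``taxon_specific`` — shifted in the appendage tissues of one ingroup only
  (should be classed not-shared).
* ``tissue_specific`` — enriched in a single tissue, with the enrichment
  calibrated by bisection so the tau specificity computed on expected
  log2-CPM hits ``target_tau``.
* everything else — null.

Per-taxon pseudorandom streams are derived from the master seed keyed by
the taxon name, so adding a taxon never perturbs another taxon's counts.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
import pandas as pd

from .io import CountMatrix, SOMATIC_ORGANS
from .specificity import tau as tau_index

__all__ = ["TaxonLayout", "SimConfig", "simulate_dataset", "write_dataset", "CLASS_ORDER"]

CLASS_ORDER = (
    "homologous_appendage",
    "skin_shared",
    "bone_program",
    "taxon_specific",
    "tissue_specific",
)

#: Control tissues treated as "bone-like" for the bone_program class.
BONE_LIKE = ("bone", "cartilage_control")


@dataclasses.dataclass(frozen=True)
class TaxonLayout:
    """Tissue layout of one simulated taxon."""

    name: str
    taxon_role: str                   # ingroup_a | ingroup_b | outgroup
    appendage: tuple[str, ...]
    controls: tuple[str, ...]
    species: tuple[str, ...] = ()     # cycled over samples when multi-species

    @property
    def tissues(self) -> tuple[str, ...]:
        return self.appendage + self.controls + SOMATIC_ORGANS


DEFAULT_TAXA = (
    TaxonLayout(
        "cattle", "ingroup_a", ("horn_bud_2mo", "horn_bud_4mo"), ("skin",),
        species=("bos_taurus",),
    ),
    TaxonLayout(
        "deer", "ingroup_b", ("pedicle", "antler_tip", "transition_zone"), ("skin", "bone"),
        species=("cervus_nippon", "capreolus_capreolus", "odocoileus_virginianus"),
    ),
    TaxonLayout(
        "pig", "outgroup", (), ("skin", "bone", "cartilage_control"),
        species=("sus_scrofa",),
    ),
)


@dataclasses.dataclass
class SimConfig:
    """Simulation parameters (defaults are the conditions the tests assume).

    ``class_proportions`` fractions are converted to gene counts by floor;
    the remainder are null genes.
    """

    n_genes: int = 2000
    replicates_per_tissue: int = 3
    baseline_log2_mean_range: tuple[float, float] = (3.0, 9.0)
    dispersion_range: tuple[float, float] = (0.05, 0.4)
    libsize_factor_range: tuple[float, float] = (0.5, 2.0)
    effect_log2fc: float = 2.0
    class_proportions: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "homologous_appendage": 0.05,
            "skin_shared": 0.05,
            "bone_program": 0.05,
            "taxon_specific": 0.05,
            "tissue_specific": 0.05,
        }
    )
    target_tau: float = 0.95
    covariate_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    taxa: tuple[TaxonLayout, ...] = DEFAULT_TAXA
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.replicates_per_tissue < 3:
            raise ValueError("need n_genes >= 1 and >= 3 replicates per tissue")
        unknown = set(self.class_proportions) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if sum(self.class_proportions.values()) > 1.0 + 1e-12:
            raise ValueError("class proportions must sum to at most 1")
        for rng_name in ("baseline_log2_mean_range", "dispersion_range", "libsize_factor_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 < hi and lo <= hi) or (rng_name != "baseline_log2_mean_range" and lo <= 0):
                raise ValueError(f"invalid {rng_name}: {(lo, hi)}")
        if not 0.0 < self.target_tau < 1.0:
            raise ValueError("target_tau must be in (0, 1)")

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.floor(self.n_genes * self.class_proportions.get(c, 0.0)))
                for c in CLASS_ORDER}


def _stream(seed: int, key: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(key.encode())])


def _expected_lcpm(mu_by_tissue: np.ndarray, reps: int, total_rel: float) -> np.ndarray:
    """Expected grouped log2-CPM (with the 0.5 prior), clipped at zero."""
    lcpm = np.log2((reps * mu_by_tissue + 0.5) / (reps * total_rel) * 1e6)
    return np.clip(lcpm, 0.0, None)


def _calibrate_enrichment(mu0: float, n_tissues: int, reps: int, total_rel: float,
                          target: float) -> float:
    """Bisection on log2 fold enrichment so expected-LCPM tau hits target."""

    def realized(log2f: float) -> float:
        mus = np.full(n_tissues, mu0)
        mus[0] = mu0 * 2.0**log2f
        return tau_index(_expected_lcpm(mus, reps, total_rel))

    lo, hi = 0.0, 40.0
    if realized(hi) < target:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[dict[str, tuple[CountMatrix, pd.DataFrame]], pd.DataFrame]:
    """Generate counts, metadata and truth labels for every taxon.

    Returns ``({taxon: (CountMatrix, metadata)}, truth)``; identical
    configurations produce bit-identical output.
    """
    G = cfg.n_genes
    reps = cfg.replicates_per_tissue
    width = len(str(max(G, 1)))
    gene_ids = pd.Index([f"G{i:0{width}d}" for i in range(1, G + 1)], name="gene_id")

    grng = _stream(cfg.rng_seed, "genes")
    baseline = grng.uniform(*cfg.baseline_log2_mean_range, size=G)
    lo_d, hi_d = cfg.dispersion_range
    phi = np.exp(grng.uniform(np.log(lo_d), np.log(hi_d), size=G))

    counts_by_class = cfg.class_counts()
    gene_class = np.array(["null"] * G, dtype=object)
    pos = 0
    for cls in CLASS_ORDER:
        k = counts_by_class[cls]
        gene_class[pos:pos + k] = cls
        pos += k

    direction = np.where(np.arange(G) % 2 == 0, "up", "down").astype(object)
    direction[gene_class == "null"] = ""
    signed = np.where(direction == "down", -1.0, 1.0)

    ingroups = [t for t in cfg.taxa if t.taxon_role in ("ingroup_a", "ingroup_b")]
    needs_ingroups = any(
        counts_by_class[c] > 0
        for c in ("homologous_appendage", "skin_shared", "bone_program", "taxon_specific")
    )
    if needs_ingroups and len(ingroups) < 2:
        raise ValueError("layout needs two ingroup taxa for the planted gene classes")

    # tissue-specific genes: low baseline + calibrated single-tissue enrichment
    ts_idx = np.flatnonzero(gene_class == "tissue_specific")
    targets = [
        (t.name, tis)
        for t in cfg.taxa
        for tis in (t.appendage + t.controls)
    ]
    ts_target = {g: targets[j % len(targets)] for j, g in enumerate(ts_idx)}
    baseline = baseline.copy()
    # relative abundance chosen so non-target tissues sit just above the
    # log-CPM clip point, keeping the calibrated enrichment finite
    total_rel_rough = float(np.sum(2.0**baseline))
    mu0_ts = 0.35 * total_rel_rough / 1e6 * 3.0  # ~= 1 count per group of 3
    baseline[ts_idx] = np.log2(mu0_ts)

    enrich = {}
    for t in cfg.taxa:
        n_tis = len(t.tissues)
        for g in ts_idx:
            if ts_target[g][0] != t.name:
                continue
            enrich[g] = _calibrate_enrichment(
                2.0 ** baseline[g], n_tis, reps, total_rel_rough, cfg.target_tau
            )

    planted_tissues: dict[int, set[str]] = {g: set() for g in range(G)}

    datasets: dict[str, tuple[CountMatrix, pd.DataFrame]] = {}
    for t in cfg.taxa:
        trng = _stream(cfg.rng_seed, f"taxon:{t.name}")
        tissues = t.tissues
        n_samples = len(tissues) * reps

        # per-tissue log2 effect matrix
        E = np.zeros((G, len(tissues)))
        for j, tis in enumerate(tissues):
            is_app = tis in t.appendage
            is_skin = tis == "skin"
            is_bone_like = tis in BONE_LIKE
            for i in range(G):
                cls = gene_class[i]
                eff = 0.0
                if cls == "homologous_appendage" and t.taxon_role != "outgroup" and is_app:
                    eff = signed[i] * cfg.effect_log2fc
                elif cls == "skin_shared":
                    owner = ingroups[i % 2].name
                    if t.name == owner and (is_app or is_skin):
                        eff = signed[i] * cfg.effect_log2fc
                elif cls == "bone_program":
                    if (t.taxon_role != "outgroup" and is_app) or is_bone_like:
                        eff = signed[i] * cfg.effect_log2fc
                elif cls == "taxon_specific":
                    owner = ingroups[i % 2].name
                    if t.name == owner and is_app:
                        eff = signed[i] * cfg.effect_log2fc
                elif cls == "tissue_specific":
                    if ts_target[i] == (t.name, tis):
                        eff = enrich[i]
                if eff != 0.0:
                    E[i, j] = eff
                    planted_tissues[i].add(f"{t.name}:{tis}")

        lo_f, hi_f = cfg.libsize_factor_range
        lib_factor = np.exp(trng.uniform(np.log(lo_f), np.log(hi_f), size=n_samples))

        sample_ids, meta_rows = [], []
        col = 0
        mu = np.empty((G, n_samples))
        sex_shift = cfg.covariate_effects.get("sex", 0.0)
        species_shift = cfg.covariate_effects.get("species", 0.0)
        for j, tis in enumerate(tissues):
            if tis in ("horn_bud_2mo", "horn_bud_4mo"):
                age_of = lambda r, tis=tis: tis.rsplit("_", 1)[1]
            elif tis in t.appendage or tis in t.controls:
                age_of = lambda r: ("juvenile", "adult")[r % 2]
            else:
                age_of = lambda r: ("2mo", "4mo", "adult")[r % 3]
            role = (
                "appendage" if tis in t.appendage
                else "control" if tis in t.controls
                else "somatic"
            )
            for r in range(reps):
                sid = f"{t.name}_{tis}_{r + 1}"
                # offset the sex and species cycles by tissue index so the
                # two covariates are never collinear with each other
                sex = ("m", "f")[(r + j) % 2]
                sp_i = (r + j) % len(t.species) if t.species else 0
                species = t.species[sp_i] if t.species else t.name
                shift = (sex_shift if sex == "f" else 0.0) + (
                    species_shift * sp_i if len(t.species) > 1 else 0.0
                )
                mu[:, col] = 2.0 ** (baseline + E[:, j] + shift) * lib_factor[col]
                sample_ids.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "taxon": t.name,
                        "taxon_role": t.taxon_role,
                        "tissue": tis,
                        "role": role,
                        "age": age_of(r),
                        "sex": sex,
                        "species": species,
                        "replicate": r + 1,
                    }
                )
                col += 1

        p = 1.0 / (1.0 + phi[:, None] * mu)
        counts = trng.negative_binomial(1.0 / phi[:, None], p, size=(G, n_samples))
        cm = CountMatrix(gene_ids, sample_ids, counts)
        datasets[t.name] = (cm, pd.DataFrame(meta_rows))

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_class": gene_class,
            "planted_direction": direction,
            "planted_tissues": [
                ";".join(sorted(planted_tissues[i])) for i in range(G)
            ],
            "target_tau": [
                cfg.target_tau if gene_class[i] == "tissue_specific" else np.nan
                for i in range(G)
            ],
        }
    )
    return datasets, truth


def write_dataset(datasets, truth, out_dir) -> None:
    """Write counts_<taxon>.tsv, meta_<taxon>.tsv and truth.tsv to a directory."""
    from pathlib import Path

    from .io import write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for taxon, (cm, meta) in datasets.items():
        cm.to_frame().to_csv(out / f"counts_{taxon}.tsv", sep="\t")
        write_table(meta, out / f"meta_{taxon}.tsv")
    write_table(truth, out / "truth.tsv")
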
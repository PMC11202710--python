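"""Synthetic-data generators with known ground truth.

The wet-lab layers of the study - digestion assays, faecal fermentations
with 16S sequencing, and SCFA quantitation - deposited no raw data, so
every analysis stage is exercised against generators whose truth is known:

* ``simulate_digestion``: pellet/supernatant quantities from a true
  per-amino-acid digestibility vector plus multiplicative truncated
  Gaussian noise.
* ``simulate_community``: Dirichlet-multinomial sample-by-taxon counts
  around group-level proportions, with per-taxon fold-change effects.
* ``simulate_scfa``: per-acid 24 h concentrations as truncated Gaussians
  around group means, plus a shared baseline.

All generators are bit-for-bit reproducible under a fixed seed. Default
shapes mirror the study: products measured in duplicate, two donor groups,
a handful of flasks per product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aa import AminoAcidProfile
from .digestibility import DigestionRecord
from .microbiome import AbundanceTable
from .scfa import ACIDS, ScfaRecord

__all__ = [
    "CommunitySimSpec",
    "DigestionSimSpec",
    "ScfaSimSpec",
    "simulate_community",
    "simulate_digestion",
    "simulate_scfa",
]


def _truncated_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise factors (1 + eps), eps ~ N(0, cv), floored at 0."""
    return np.maximum(1.0 + rng.normal(0.0, cv, size=size), 0.0)


# ---------------------------------------------------------------------------
# Digestion

@dataclass
class DigestionSimSpec:
    """Specification of a synthetic digestion experiment.

    ``true_digestibility`` maps amino-acid codes to the true digested
    fraction in [0, 1]; ``noise_cv`` is the coefficient of variation of the
    multiplicative measurement noise on each fraction quantity.
    """

    profile: AminoAcidProfile
    true_digestibility: Mapping[str, float]
    noise_cv: float = 0.05
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for code, d in self.true_digestibility.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"true digestibility for {code} must be in [0, 1], got {d}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_digestion(spec: DigestionSimSpec) -> list[DigestionRecord]:
    """Generate per-replicate digestion records on the food basis.

    Food content comes from the profile (g/100 g -> mg/100 g); the pellet
    retains food * (1 - d) and the tryptophan supernatant receives
    food * d, each perturbed by multiplicative truncated Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    codes = [c for c in spec.true_digestibility if c in spec.profile.contents]
    records = []
    for rep in range(spec.n_replicates):
        food: dict[str, float] = {}
        pellet: dict[str, float] = {}
        trp_sup = None
        for code in codes:
            mg = spec.profile.contents[code].mean * 1000.0
            d = spec.true_digestibility[code]
            food[code] = mg
            if code == "Trp":
                trp_sup = mg * d * float(_truncated_noise(rng, spec.noise_cv, ()))
            else:
                pellet[code] = mg * (1.0 - d) * float(_truncated_noise(rng, spec.noise_cv, ()))
        records.append(
            DigestionRecord(
                product_id=spec.profile.product_id,
                food_content=food,
                pellet_content=pellet,
                trp_supernatant=trp_sup,
                replicate_id=f"r{rep + 1}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Community

@dataclass
class CommunitySimSpec:
    """Specification of a two-group Dirichlet-multinomial community.

    Baseline proportions default to a log-normal abundance profile (a
    realistic long-tailed rank-abundance curve). Group effects multiply a
    taxon's baseline proportion in the second group before renormalising.
    ``concentration`` is the Dirichlet precision: larger means less
    between-replicate overdispersion.
    """

    n_taxa: int = 60
    baseline_proportions: Sequence[float] | None = None
    group_effects: Mapping[str, float] = field(default_factory=dict)
    depth: int = 20_000
    n_samples_per_group: int = 2
    concentration: float = 200.0
    group_labels: tuple[str, str] = ("standard", "reformulated")
    n_phyla: int = 4
    n_genera: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.concentration <= 0:
            raise ValueError("Dirichlet concentration must be > 0")
        for taxon, fold in self.group_effects.items():
            if fold <= 0:
                raise ValueError(f"fold change for {taxon} must be > 0")
        if self.baseline_proportions is not None:
            p = np.asarray(self.baseline_proportions, dtype=float)
            if len(p) != self.n_taxa:
                raise ValueError("baseline_proportions length must equal n_taxa")
            if not math.isclose(float(p.sum()), 1.0, rel_tol=1e-9):
                raise ValueError("baseline proportions must sum to 1")

    def taxon_ids(self) -> list[str]:
        return [f"Otu_{i + 1}" for i in range(self.n_taxa)]


def simulate_community(spec: CommunitySimSpec) -> AbundanceTable:
    """Generate a sample-by-taxon count table for two groups.

    Per sample: proportions ~ Dirichlet(concentration * p_group), counts ~
    Multinomial(depth). Group proportions are the baseline renormalised
    after fold-change multiplication. Taxonomy labels (phylum, genus) are
    assigned cyclically so rank aggregation has structure to work with.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = spec.taxon_ids()
    if spec.baseline_proportions is None:
        raw = rng.lognormal(mean=0.0, sigma=1.5, size=spec.n_taxa)
        baseline = raw / raw.sum()
    else:
        baseline = np.asarray(spec.baseline_proportions, dtype=float)

    folds = np.ones(spec.n_taxa)
    for taxon, fold in spec.group_effects.items():
        if taxon not in taxa:
            raise ValueError(f"group effect names unknown taxon {taxon!r}")
        folds[taxa.index(taxon)] = fold
    p_by_group = {
        spec.group_labels[0]: baseline,
        spec.group_labels[1]: (baseline * folds) / (baseline * folds).sum(),
    }

    counts, samples, meta_rows = [], [], []
    for group in spec.group_labels:
        p = p_by_group[group]
        for rep in range(spec.n_samples_per_group):
            theta = rng.dirichlet(spec.concentration * p)
            counts.append(rng.multinomial(spec.depth, theta))
            sample = f"{group}_r{rep + 1}"
            samples.append(sample)
            meta_rows.append({"sample": sample, "group": group, "replicate": f"r{rep + 1}",
                              "product": group})

    taxonomy = pd.DataFrame(
        {
            "phylum": [f"Phylum_{i % spec.n_phyla + 1}" for i in range(spec.n_taxa)],
            "genus": [f"Genus_{i % spec.n_genera + 1}" for i in range(spec.n_taxa)],
            "species": [f"Species_{i + 1}" for i in range(spec.n_taxa)],
        },
        index=pd.Index(taxa, name="taxon"),
    )
    return AbundanceTable(
        counts=pd.DataFrame(np.array(counts), index=samples, columns=taxa),
        taxonomy=taxonomy,
        sample_meta=pd.DataFrame(meta_rows).set_index("sample"),
    )


# ---------------------------------------------------------------------------
# SCFA

@dataclass
class ScfaSimSpec:
    """Specification of synthetic SCFA measurements for one donor group.

    ``product_means``/``product_sds`` map product -> acid -> 24 h mean/sd;
    ``baseline`` gives the shared pre-incubation level per acid.
    """

    group: str
    product_means: Mapping[str, Mapping[str, float]]
    product_sds: Mapping[str, Mapping[str, float]]
    baseline: Mapping[str, float] = field(default_factory=lambda: dict.fromkeys(ACIDS, 0.0))
    n_replicates: int = 2
    unit: str = "mM"
    seed: int = 0

    def __post_init__(self) -> None:
        for product, means in self.product_means.items():
            for acid, m in means.items():
                if m < 0:
                    raise ValueError(f"mean for {product}/{acid} must be >= 0")


def simulate_scfa(spec: ScfaSimSpec) -> list[ScfaRecord]:
    """Generate baseline + 24 h SCFA records for one donor group.

    24 h values are Gaussian around the product/acid mean, truncated at
    zero; the baseline records are exact (one per acid, from the control
    flask before incubation).
    """
    rng = np.random.default_rng(spec.seed)
    records = [
        ScfaRecord(
            sample_id=f"{spec.group}_baseline",
            group=spec.group,
            product="Control",
            acid=acid,
            concentration=float(spec.baseline.get(acid, 0.0)),
            unit=spec.unit,
            timepoint="baseline",
        )
        for acid in ACIDS
    ]
    for product, means in spec.product_means.items():
        sds = spec.product_sds.get(product, {})
        for rep in range(spec.n_replicates):
            for acid in ACIDS:
                if acid not in means:
                    continue
                value = max(rng.normal(means[acid], sds.get(acid, 0.0)), 0.0)
                records.append(
                    ScfaRecord(
                        sample_id=f"{spec.group}_{product}_r{rep + 1}",
                        group=spec.group,
                        product=product,
                        acid=acid,
                        concentration=float(value),
                        unit=spec.unit,
                        timepoint="h24",
                        replicate=f"r{rep + 1}",
                    )
                )
    return records
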
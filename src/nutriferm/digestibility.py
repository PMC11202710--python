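"""Per-amino-acid in vitro digestibility from digestion-fraction measurements.

Digestibility of an amino acid is the share of it released by simulated
gastric + intestinal digestion. For every amino acid except tryptophan it
is inferred from what stays in the insoluble pellet:

    digestibility (%) = (food - pellet) / food * 100

Tryptophan is quantified in the soluble supernatant instead (its assay is
incompatible with the pellet workup), so its accounting is inverted:

    digestibility (%) = supernatant / food * 100

All quantities must be expressed on the same food-mass basis (mg/100 g of
food) after applying the dilution steps of the analysis; records carry the
named dilution factors used in that back-calculation for audit. Values
outside [0, 100] can arise from measurement noise and are retained with a
warning unless clamping is requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aa import AA_CODES, AminoAcidProfile

__all__ = [
    "DigestionRecord",
    "DigestibilityResult",
    "aa_digestibility",
    "apply_dilutions",
    "composite_digestibility",
    "mean_digestibility",
    "read_digestion_long",
    "trp_digestibility",
]


def apply_dilutions(value: float, factors: Mapping[str, float]) -> float:
    """Back-calculate a measured quantity to the food basis.

    ``factors`` maps step names (e.g. ``tca_volume_ml``-derived ratios) to
    multiplicative factors; all must be positive.
    """
    out = value
    for name, f in factors.items():
        if f <= 0:
            raise ValueError(f"dilution factor {name!r} must be > 0, got {f}")
        out *= f
    return out


@dataclass
class DigestionRecord:
    """One replicate of a digestion experiment, on a common food basis.

    ``food_content`` and ``pellet_content`` are mg/100 g food;
    ``trp_supernatant`` is the tryptophan recovered in the supernatant on
    the same basis. ``dilution`` records the named factors already applied
    during back-calculation (audit trail, not re-applied); ``basis`` names
    the common mass basis and mixing bases across records is refused
    downstream.
    """

    product_id: str
    food_content: dict[str, float]
    pellet_content: dict[str, float]
    trp_supernatant: float | None = None
    dilution: dict[str, float] = field(default_factory=dict)
    replicate_id: str = "r1"
    basis: str = "food"

    def __post_init__(self) -> None:
        for name, value in self.dilution.items():
            if value <= 0:
                raise ValueError(f"dilution factor {name!r} must be > 0")
        for label, table in (("food", self.food_content), ("pellet", self.pellet_content)):
            for code, v in table.items():
                if code not in AA_CODES:
                    raise ValueError(f"unknown amino-acid code {code!r} in {label} content")
                if v < 0:
                    raise ValueError(f"negative {label} content for {code}: {v}")
        if self.trp_supernatant is not None and self.trp_supernatant < 0:
            raise ValueError("negative tryptophan supernatant content")


@dataclass
class DigestibilityResult:
    """Per-amino-acid digestibility percentages aggregated over replicates."""

    product_id: str
    per_aa: dict[str, tuple[float, float, int]]  # code -> (mean %, sd %, n)
    warnings: list[str] = field(default_factory=list)

    def value(self, code: str) -> float:
        return self.per_aa[code][0]

    @property
    def defined(self) -> dict[str, float]:
        return {code: v[0] for code, v in self.per_aa.items()}


def trp_digestibility(record: DigestionRecord) -> float | None:
    """Supernatant-based tryptophan digestibility (%), or None when the
    supernatant was not measured."""
    food = record.food_content.get("Trp")
    if record.trp_supernatant is None or food is None:
        return None
    if food == 0:
        return None
    return record.trp_supernatant / food * 100.0


def _single_record_values(record: DigestionRecord, warnings: list[str]) -> dict[str, float]:
    values: dict[str, float] = {}
    for code, food in record.food_content.items():
        if code == "Trp":
            continue
        if food == 0:
            warnings.append(
                f"{record.product_id}/{record.replicate_id}: {code} food content is 0; "
                "digestibility undefined"
            )
            continue
        if code not in record.pellet_content:
            continue
        values[code] = (food - record.pellet_content[code]) / food * 100.0
    trp = trp_digestibility(record)
    if trp is not None:
        values["Trp"] = trp
    elif "Trp" in record.food_content:
        warnings.append(
            f"{record.product_id}/{record.replicate_id}: tryptophan supernatant missing; "
            "Trp digestibility undefined"
        )
    return values


def aa_digestibility(
    records: DigestionRecord | Iterable[DigestionRecord],
    clamp: bool = False,
) -> DigestibilityResult:
    """Per-amino-acid digestibility, pellet-based (supernatant-based for Trp).

    Accepts one record or the replicate set of one product; replicates are
    aggregated to mean ± sd (ddof=1). Values outside [0, 100] — possible
    when noise puts pellet above food — are retained and flagged, or
    truncated into [0, 100] when ``clamp`` is set.
    """
    if isinstance(records, DigestionRecord):
        records = [records]
    records = list(records)
    if not records:
        raise ValueError("no digestion records given")
    product = records[0].product_id
    basis = records[0].basis
    for r in records:
        if r.product_id != product:
            raise ValueError("aa_digestibility aggregates replicates of a single product")
        if r.basis != basis:
            raise ValueError(f"mixed mass bases: {r.basis!r} vs {basis!r}")

    warnings: list[str] = []
    per_rep = [_single_record_values(r, warnings) for r in records]
    codes = sorted(set().union(*per_rep), key=AA_CODES.index)

    per_aa: dict[str, tuple[float, float, int]] = {}
    for code in codes:
        vals = np.array([rep[code] for rep in per_rep if code in rep], dtype=float)
        for v in vals:
            if not 0.0 <= v <= 100.0:
                warnings.append(
                    f"{product}: {code} digestibility {v:.2f}% outside [0, 100]"
                    + (" (clamped)" if clamp else "")
                )
        if clamp:
            vals = np.clip(vals, 0.0, 100.0)
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        per_aa[code] = (float(vals.mean()), sd, int(vals.size))
    return DigestibilityResult(product_id=product, per_aa=per_aa, warnings=warnings)


def composite_digestibility(
    result: DigestibilityResult,
    profile: AminoAcidProfile,
    members: Iterable[str],
) -> float:
    """Content-weighted mean digestibility of a composite scoring unit.

    Used for SAA (Met + Cys) and AAA (Phe + Tyr), which are scored jointly:
    the composite digestibility is sum(content_a * d_a) / sum(content_a).
    """
    members = list(members)
    missing = [a for a in members if a not in result.per_aa or a not in profile.contents]
    if missing:
        raise ValueError(f"composite members lack digestibility or content: {sorted(missing)}")
    weights = np.array([profile.contents[a].mean for a in members], dtype=float)
    if weights.sum() == 0:
        raise ValueError("composite digestibility undefined: all member contents are zero")
    values = np.array([result.value(a) for a in members], dtype=float)
    return float(np.average(values, weights=weights))


def mean_digestibility(
    result: DigestibilityResult,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Summary digestibility averaged over the scored amino acids.

    Unweighted by default; pass per-amino-acid contents as ``weights`` for
    a content-weighted variant.
    """
    if not result.per_aa:
        raise ValueError("no defined per-amino-acid digestibility values")
    if weights is None:
        return float(np.mean([v[0] for v in result.per_aa.values()]))
    codes = [c for c in result.per_aa if c in weights]
    if not codes:
        raise ValueError("no overlap between digestibility values and weights")
    w = np.array([weights[c] for c in codes], dtype=float)
    v = np.array([result.value(c) for c in codes], dtype=float)
    return float(np.average(v, weights=w))


def read_digestion_long(path: str | Path) -> dict[str, list[DigestionRecord]]:
    """Read a long-format digestion CSV into per-product replicate records.

    Expected columns: product_id, replicate, fraction (food | pellet |
    supernatant), amino_acid, value, unit. Supernatant rows are only
    meaningful for Trp. Values must already be on a common food basis.
    """
    df = pd.read_csv(path)
    required = {"product_id", "replicate", "fraction", "amino_acid", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"digestion file {path} lacks columns: {sorted(missing)}")
    out: dict[str, list[DigestionRecord]] = {}
    for (product, rep), sub in df.groupby(["product_id", "replicate"], sort=True):
        food: dict[str, float] = {}
        pellet: dict[str, float] = {}
        trp_sup: float | None = None
        for _, row in sub.iterrows():
            code, fraction, value = row["amino_acid"], row["fraction"], float(row["value"])
            if fraction == "food":
                food[code] = value
            elif fraction == "pellet":
                pellet[code] = value
            elif fraction == "supernatant":
                if code != "Trp":
                    raise ValueError(f"supernatant fraction only applies to Trp, got {code}")
                trp_sup = value
            else:
                raise ValueError(f"unknown fraction {fraction!r}")
        out.setdefault(str(product), []).append(
            DigestionRecord(
                product_id=str(product),
                food_content=food,
                pellet_content=pellet,
                trp_supernatant=trp_sup,
                replicate_id=str(rep),
            )
        )
    return out
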
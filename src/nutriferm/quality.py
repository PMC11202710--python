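"""DIAAR / DIAAS protein-quality scoring against FAO reference patterns.

For each of the nine scoring units (His, Ile, Leu, Lys, SAA, AAA, Thr, Trp,
Val — SAA and AAA being the Met+Cys and Phe+Tyr composites) the digestible
indispensable amino acid ratio is

    DIAAR (%) = content (mg/g protein) * digestibility / requirement * 100

with digestibility as a fraction and the requirement in mg per g of the
age-group reference protein. The DIAAS of a food is the lowest DIAAR; the
unit attaining it is the limiting amino acid.

The FAO 2013 scoring patterns ship as an editable YAML config; DIAAS is
reported untruncated by default (a truncate flag caps it at 100, the FAO
convention for mixed diets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .aa import DEFAULT_GROUPS, AaGroups, AminoAcidProfile, to_mg_per_g_protein
from .digestibility import DigestibilityResult, composite_digestibility

__all__ = [
    "AGE_GROUPS",
    "SCORING_UNITS",
    "ProteinQualityResult",
    "ReferencePattern",
    "compare_products",
    "diaar",
    "diaas",
    "load_reference_pattern",
    "score_product",
    "scoring_unit_digestibility",
]

#: Fixed scoring-unit order; also the tie-break order for the limiting unit.
SCORING_UNITS: tuple[str, ...] = ("His", "Ile", "Leu", "Lys", "SAA", "AAA", "Thr", "Trp", "Val")

AGE_GROUPS: tuple[str, ...] = ("infant", "child_6mo_3y", "older_child_adolescent_adult")


@dataclass(frozen=True)
class ReferencePattern:
    """Age-group amino-acid requirements (mg per g of reference protein)."""

    age_group: str
    requirements: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.requirements) != set(SCORING_UNITS):
            raise ValueError(
                f"reference pattern must cover exactly the scoring units {SCORING_UNITS}"
            )
        for unit, req in self.requirements.items():
            if req <= 0:
                raise ValueError(f"requirement for {unit} must be > 0, got {req}")


def load_reference_pattern(
    age_group: str = "older_child_adolescent_adult",
    path: str | Path | None = None,
) -> ReferencePattern:
    """Load a scoring pattern from YAML (bundled FAO 2013 file by default)."""
    if path is None:
        text = resources.files("nutriferm.data").joinpath("fao_reference_patterns.yaml").read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"reference pattern file not found: {p}")
        text = p.read_text()
    patterns = yaml.safe_load(text)
    if age_group not in patterns:
        raise ValueError(f"age group {age_group!r} not in pattern file (have {sorted(patterns)})")
    return ReferencePattern(
        age_group=age_group,
        requirements={u: float(v) for u, v in patterns[age_group].items()},
    )


@dataclass
class ProteinQualityResult:
    """Per-unit DIAAR (mean, sd), DIAAS and the limiting amino acid."""

    product_id: str
    diaar: dict[str, tuple[float, float]]
    diaas: float
    limiting: str
    age_group: str
    tie: bool = False
    diaas_sd: float = 0.0


def scoring_unit_digestibility(
    result: DigestibilityResult,
    profile: AminoAcidProfile,
    groups: AaGroups = DEFAULT_GROUPS,
) -> dict[str, float]:
    """Digestibility (%) per scoring unit, with content-weighted composites
    for SAA and AAA."""
    out: dict[str, float] = {}
    for unit in SCORING_UNITS:
        if unit == "SAA":
            out[unit] = composite_digestibility(result, profile, sorted(groups.saa))
        elif unit == "AAA":
            out[unit] = composite_digestibility(result, profile, sorted(groups.aaa))
        else:
            if unit not in result.per_aa:
                raise ValueError(f"no digestibility for scoring unit {unit}")
            out[unit] = result.value(unit)
    return out


def diaar(
    mg_per_g_protein: Mapping[str, float],
    digestibility: Mapping[str, float],
    pattern: ReferencePattern,
) -> dict[str, float]:
    """DIAAR (%) per scoring unit.

    ``digestibility`` is percent (fraction of 100) per scoring unit;
    composite units use the content-weighted composite digestibility.
    """
    out: dict[str, float] = {}
    for unit in SCORING_UNITS:
        if unit not in mg_per_g_protein:
            raise ValueError(f"missing content for scoring unit {unit}")
        if unit not in digestibility:
            raise ValueError(f"missing digestibility for scoring unit {unit}")
        req = pattern.requirements[unit]
        out[unit] = mg_per_g_protein[unit] * (digestibility[unit] / 100.0) / req * 100.0
    return out


def diaas(diaar_map: Mapping[str, float]) -> tuple[float, str, bool]:
    """Minimum DIAAR, its scoring unit, and whether the minimum is tied.

    Ties are broken by the fixed scoring-unit order.
    """
    if not diaar_map:
        raise ValueError("empty DIAAR map")
    order = [u for u in SCORING_UNITS if u in diaar_map] + [
        u for u in diaar_map if u not in SCORING_UNITS
    ]
    value = min(diaar_map[u] for u in order)
    argmins = [u for u in order if diaar_map[u] == value]
    return value, argmins[0], len(argmins) > 1


def score_product(
    profile: AminoAcidProfile,
    digestibility_results: DigestibilityResult | Sequence[DigestibilityResult],
    pattern: ReferencePattern,
    basis: str = "declared_protein",
    truncate: bool = False,
) -> ProteinQualityResult:
    """Full scoring chain for one product.

    Pass one aggregated digestibility result, or a sequence of per-replicate
    results: with replicates the DIAAR/DIAAS spread is propagated by
    rescoring each replicate and taking mean ± sd of the scores (not by a
    delta-method approximation).
    """
    if isinstance(digestibility_results, DigestibilityResult):
        digestibility_results = [digestibility_results]
    content = to_mg_per_g_protein(profile, basis=basis)
    per_rep_diaar = []
    for res in digestibility_results:
        unit_dig = scoring_unit_digestibility(res, profile)
        per_rep_diaar.append(diaar(content, unit_dig, pattern))

    mean_diaar: dict[str, tuple[float, float]] = {}
    for unit in SCORING_UNITS:
        vals = np.array([d[unit] for d in per_rep_diaar], dtype=float)
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        mean_diaar[unit] = (float(vals.mean()), sd)

    score, limiting, tie = diaas({u: m for u, (m, _) in mean_diaar.items()})
    rep_scores = np.array([diaas(d)[0] for d in per_rep_diaar], dtype=float)
    diaas_sd = float(rep_scores.std(ddof=1)) if rep_scores.size > 1 else 0.0
    if truncate:
        score = min(score, 100.0)
        mean_diaar = {u: (min(m, 100.0), s) for u, (m, s) in mean_diaar.items()}
    return ProteinQualityResult(
        product_id=profile.product_id,
        diaar=mean_diaar,
        diaas=score,
        limiting=limiting,
        age_group=pattern.age_group,
        tie=tie,
        diaas_sd=diaas_sd,
    )


def compare_products(a: ProteinQualityResult, b: ProteinQualityResult) -> dict:
    """Reformulation effect of ``b`` relative to ``a`` in percentage points.

    Returns per-unit DIAAR differences (b - a), the DIAAS difference, and
    whether the limiting amino acid shifted.
    """
    if a.age_group != b.age_group:
        raise ValueError(f"age-group mismatch: {a.age_group!r} vs {b.age_group!r}")
    units = [u for u in a.diaar if u in b.diaar]
    return {
        "product_a": a.product_id,
        "product_b": b.product_id,
        "diaar_diff": {u: b.diaar[u][0] - a.diaar[u][0] for u in units},
        "diaas_diff": b.diaas - a.diaas,
        "limiting_a": a.limiting,
        "limiting_b": b.limiting,
        "limiting_shifted": a.limiting != b.limiting,
    }
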
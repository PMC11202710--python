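"""Amino-acid composition profiles of meat products.

A profile holds the per-amino-acid content of one product in g per 100 g of
product, as measured by acid hydrolysis / HPLC, together with the product's
declared protein content. The 18-amino-acid vocabulary is fixed: it is the
set quantifiable by the standard hydrolysis workflow (Asn/Gln are recovered
as Asp/Glu).

Profiles are read from a wide CSV (one column per product, cells formatted
``mean ± sd``), summed into group totals (dispensable, indispensable, BCAA)
and converted to the mg-per-g-protein basis on which protein-quality
scoring operates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AA_CODES",
    "AaGroups",
    "AaMeasurement",
    "AminoAcidProfile",
    "DEFAULT_GROUPS",
    "parse_cell",
    "read_profile_table",
    "read_product_metadata",
    "totals",
    "to_mg_per_g_protein",
]

#: Fixed amino-acid vocabulary (order follows the composition table layout).
AA_CODES: tuple[str, ...] = (
    "Asp", "Ser", "Glu", "Gly", "Arg", "Ala", "Pro",
    "His", "Thr", "Lys", "Phe", "Tyr", "Met", "Cys", "Trp",
    "Ile", "Leu", "Val",
)


@dataclass(frozen=True)
class AaMeasurement:
    """One measured amino-acid content: mean ± sd over ``n`` replicates."""

    mean: float
    sd: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError(f"negative amino-acid content: {self.mean}")
        if self.sd < 0:
            raise ValueError(f"negative sd: {self.sd}")
        if self.n < 1:
            raise ValueError(f"replicate count must be >= 1, got {self.n}")


@dataclass(frozen=True)
class AaGroups:
    """Partition of the vocabulary into dispensable / indispensable amino
    acids, plus the composite groups used in scoring and reporting.

    SAA (sulphur amino acids, Met + Cys) and AAA (aromatic amino acids,
    Phe + Tyr) are scored jointly; BCAA (Ile, Leu, Val) is a reporting
    total only.
    """

    dispensable: frozenset[str] = frozenset({"Asp", "Ser", "Glu", "Gly", "Arg", "Ala", "Pro"})
    indispensable: frozenset[str] = frozenset(
        {"His", "Thr", "Lys", "Phe", "Tyr", "Met", "Cys", "Trp", "Ile", "Leu", "Val"}
    )
    bcaa: frozenset[str] = frozenset({"Ile", "Leu", "Val"})
    saa: frozenset[str] = frozenset({"Met", "Cys"})
    aaa: frozenset[str] = frozenset({"Phe", "Tyr"})

    def __post_init__(self) -> None:
        if self.dispensable | self.indispensable != set(AA_CODES):
            raise ValueError("dispensable and indispensable must partition the vocabulary")
        if self.dispensable & self.indispensable:
            raise ValueError("dispensable and indispensable overlap")
        if not self.bcaa <= self.indispensable:
            raise ValueError("BCAA must be indispensable amino acids")
        if self.saa & self.aaa:
            raise ValueError("SAA and AAA must be disjoint")


DEFAULT_GROUPS = AaGroups()


@dataclass
class AminoAcidProfile:
    """Per-amino-acid content of one product (g / 100 g product)."""

    product_id: str
    contents: dict[str, AaMeasurement]
    protein_pct: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        for code in self.contents:
            if code not in AA_CODES:
                raise ValueError(f"unknown amino-acid code {code!r} in profile {self.product_id}")
        if self.protein_pct is not None and self.protein_pct < 0:
            raise ValueError("protein_pct must be non-negative")

    def mean(self, code: str) -> float:
        return self.contents[code].mean

    def aa_total(self) -> float:
        """Total amino-acid content (g/100 g), summed over unrounded means."""
        return sum(m.mean for m in self.contents.values())


_CELL_RE = re.compile(
    r"^\s*(?P<mean>[0-9]*\.?[0-9]+)\s*(?:(?:±|\+/-)\s*(?P<sd>[0-9]*\.?[0-9]+))?\s*$"
)


def parse_cell(text: str | float) -> tuple[float, float]:
    """Parse a ``mean ± sd`` table cell; a bare number means sd = 0.

    Accepts both the typographic "±" and ASCII "+/-"; whitespace-tolerant.
    """
    if isinstance(text, (int, float)):
        value = float(text)
        if value < 0:
            raise ValueError(f"negative value: {value}")
        return value, 0.0
    m = _CELL_RE.match(str(text))
    if m is None:
        raise ValueError(f"cannot parse table cell {text!r} as 'mean ± sd'")
    return float(m.group("mean")), float(m.group("sd") or 0.0)


def read_product_metadata(path: str | Path) -> dict[str, float]:
    """Read product metadata CSV (columns ``product_id``, ``protein_pct``)."""
    df = pd.read_csv(path)
    missing = {"product_id", "protein_pct"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata file {path} lacks columns: {sorted(missing)}")
    return dict(zip(df["product_id"].astype(str), df["protein_pct"].astype(float)))


def read_profile_table(
    path: str | Path,
    metadata: str | Path | Mapping[str, float] | None = None,
    n_replicates: int = 2,
) -> list[AminoAcidProfile]:
    """Read a wide composition CSV into one profile per product column.

    The first column ("amino_acid") names the rows; every other column is a
    product. Cells are ``mean ± sd`` in g/100 g product; empty cells are
    recorded as absent, not zero. ``metadata`` optionally supplies declared
    protein percentages, either as a mapping or a companion CSV path.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    aa_col = df.columns[0]
    products = [c for c in df.columns if c != aa_col]
    if not products:
        raise ValueError(f"no product columns in {path}")

    protein: Mapping[str, float] = {}
    if metadata is not None:
        protein = metadata if isinstance(metadata, Mapping) else read_product_metadata(metadata)

    profiles = []
    for product in products:
        contents: dict[str, AaMeasurement] = {}
        for _, row in df.iterrows():
            code = str(row[aa_col]).strip()
            if code not in AA_CODES:
                raise ValueError(f"unknown amino-acid code {code!r} in row of {path}")
            cell = row[product]
            if pd.isna(cell) or str(cell).strip() == "":
                continue  # absent measurement, not zero
            mean, sd = parse_cell(cell)
            contents[code] = AaMeasurement(mean=mean, sd=sd, n=n_replicates)
        profiles.append(
            AminoAcidProfile(
                product_id=product,
                contents=contents,
                protein_pct=protein.get(product),
            )
        )
    return profiles


def _group_sum(profile: AminoAcidProfile, members: Iterable[str]) -> float:
    missing = [a for a in members if a not in profile.contents]
    if missing:
        raise ValueError(
            f"profile {profile.product_id} is missing amino acids: {sorted(missing)}"
        )
    return sum(profile.contents[a].mean for a in members)


def totals(profile: AminoAcidProfile, groups: AaGroups = DEFAULT_GROUPS) -> dict[str, float]:
    """Group totals (g/100 g) and their share of the total amino-acid content.

    Totals are arithmetic sums of the stored (unrounded) means; percentages
    are relative to the grand total.
    """
    dispensable = _group_sum(profile, groups.dispensable)
    iaa = _group_sum(profile, groups.indispensable)
    bcaa = _group_sum(profile, groups.bcaa)
    aa_total = dispensable + iaa
    return {
        "dispensable_total": dispensable,
        "iaa_total": iaa,
        "bcaa_total": bcaa,
        "aa_total": aa_total,
        "iaa_pct": iaa / aa_total * 100.0,
        "bcaa_pct": bcaa / aa_total * 100.0,
    }


def to_mg_per_g_protein(
    profile: AminoAcidProfile,
    basis: str = "declared_protein",
    groups: AaGroups = DEFAULT_GROUPS,
) -> dict[str, float]:
    """Convert contents to mg per g of protein, plus SAA/AAA composites.

    ``basis="declared_protein"`` divides by the product's declared protein
    content (the FAO convention); ``basis="total_aa"`` divides by the summed
    amino-acid content. Either way the arithmetic is
    ``g/100 g × 1000 / (basis g/100 g)``.
    """
    if basis == "declared_protein":
        if profile.protein_pct is None or profile.protein_pct <= 0:
            raise ValueError(
                f"profile {profile.product_id}: declared_protein basis needs protein_pct > 0"
            )
        denom = profile.protein_pct
    elif basis == "total_aa":
        denom = profile.aa_total()
        if denom <= 0:
            raise ValueError(f"profile {profile.product_id}: total_aa basis needs aa_total > 0")
    else:
        raise ValueError(f"unknown basis {basis!r}")

    out = {code: m.mean * 1000.0 / denom for code, m in profile.contents.items()}
    if groups.saa <= out.keys():
        out["SAA"] = sum(out[a] for a in groups.saa)
    if groups.aaa <= out.keys():
        out["AAA"] = sum(out[a] for a in groups.aaa)
    return out
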
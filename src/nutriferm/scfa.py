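"""Short-chain fatty acid accounting for in vitro colonic fermentations.

Concentrations of acetic, propionic and butyric acid measured by HPLC in
ppm (mg/L of fermentation fluid) are converted to mmol per kg of faeces,
24 h production is expressed as the increase over the shared pre-incubation
baseline, and group tables are rendered with per-acid ANOVA/Tukey
compact letters.

The ppm -> mmol/kg conversion needs the faecal load of the fermentation
fluid (kg faeces per L). The default derives from the fermentation recipe
used here: 16 g faeces homogenised in 70 mL buffer, of which 2 mL of slurry
enters a flask of roughly 10 mL working volume, i.e. 16/70 * 2/10 ~ 0.0457
kg/L. It is a documented default, not a constant: pass your own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import GroupSummary, anova_oneway, compact_letters, tukey_hsd

__all__ = [
    "ACIDS",
    "DEFAULT_FAECAL_DILUTION_KG_PER_L",
    "MOLAR_MASS_G_PER_MOL",
    "ScfaRecord",
    "delta_24h",
    "ppm_to_mmol_per_kg",
    "read_scfa_long",
    "scfa_table",
    "summary_letters",
]

ACIDS = ("acetic", "propionic", "butyric")

MOLAR_MASS_G_PER_MOL = {"acetic": 60.05, "propionic": 74.08, "butyric": 88.11}

#: 16 g faeces / 70 mL buffer, 2 mL slurry in a ~10 mL flask.
DEFAULT_FAECAL_DILUTION_KG_PER_L = 16.0 / 70.0 * 2.0 / 10.0

UNITS = ("ppm", "mM", "mmol_per_kg_faeces")
TIMEPOINTS = ("baseline", "h24")


@dataclass(frozen=True)
class ScfaRecord:
    """One SCFA concentration measurement."""

    sample_id: str
    group: str
    product: str
    acid: str
    concentration: float
    unit: str
    timepoint: str
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if self.acid not in ACIDS:
            raise ValueError(f"unknown acid {self.acid!r} (expected one of {ACIDS})")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")


def ppm_to_mmol_per_kg(
    value: float,
    acid: str,
    dilution: float = DEFAULT_FAECAL_DILUTION_KG_PER_L,
) -> float:
    """Convert ppm (mg per L of fluid) to mmol per kg of faeces.

    mmol/L = ppm / molar mass; mmol/kg = (mmol/L) / (kg faeces per L).
    """
    if acid not in MOLAR_MASS_G_PER_MOL:
        raise ValueError(f"unknown acid {acid!r}")
    if dilution <= 0:
        raise ValueError("dilution (kg faeces per L) must be > 0")
    return value / MOLAR_MASS_G_PER_MOL[acid] / dilution


def _records_df(records: Iterable[ScfaRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise ValueError("no SCFA records")
    if df["unit"].nunique() > 1:
        raise ValueError(f"mixed units in SCFA records: {sorted(df['unit'].unique())}")
    return df


def delta_24h(records: Iterable[ScfaRecord]) -> pd.DataFrame:
    """Per sample/acid 24 h increase over the shared control baseline.

    A single pre-incubation baseline (taken from the control flask) serves
    every sample within a donor group. Negative increases are kept and
    flagged in the ``negative`` column. The input unit is carried through
    unchanged.
    """
    df = _records_df(records)
    base = df[df["timepoint"] == "baseline"]
    h24 = df[df["timepoint"] == "h24"]
    baselines = base.groupby(["group", "acid"])["concentration"].mean()
    rows = []
    for _, row in h24.iterrows():
        key = (row["group"], row["acid"])
        if key not in baselines.index:
            raise ValueError(f"missing baseline for group/acid {key}")
        inc = row["concentration"] - baselines.loc[key]
        rows.append(
            {
                "sample_id": row["sample_id"],
                "group": row["group"],
                "product": row["product"],
                "acid": row["acid"],
                "replicate": row["replicate"],
                "increase": inc,
                "unit": row["unit"],
                "negative": inc < 0,
            }
        )
    return pd.DataFrame(rows)


def scfa_table(
    records: Iterable[ScfaRecord],
    group: str,
    alpha: float = 0.05,
    use_delta: bool = False,
) -> pd.DataFrame:
    """Production table for one donor group: per-acid and total SCFA
    mean ± sd by product, with compact letters from ANOVA/Tukey.

    ``use_delta`` analyses baseline-subtracted 24 h increases instead of
    raw 24 h concentrations (both views are meaningful when a baseline
    exists). The concentration unit of the inputs is carried through and
    never relabelled.
    """
    df = _records_df(records)
    unit = df["unit"].iloc[0]
    if use_delta:
        long = delta_24h(records).rename(columns={"increase": "value"})
    else:
        long = df[df["timepoint"] == "h24"].rename(columns={"concentration": "value"})
    long = long[long["group"] == group]
    if long.empty:
        raise ValueError(f"no records for group {group!r}")

    wide = long.pivot_table(
        index=["product", "replicate"], columns="acid", values="value"
    ).reset_index()
    wide["total"] = wide[list(ACIDS)].sum(axis=1)

    products = list(dict.fromkeys(long["product"]))
    rows = []
    letters_by_col: dict[str, dict[str, str]] = {}
    for col in list(ACIDS) + ["total"]:
        by_product = {p: wide.loc[wide["product"] == p, col].to_numpy() for p in products}
        if any(v.size < 2 for v in by_product.values()):
            raise ValueError("need >= 2 replicates per product for the group table")
        summary = GroupSummary.from_raw({p: list(v) for p, v in by_product.items()})
        tukey = tukey_hsd(summary, alpha=alpha)
        letters_by_col[col] = compact_letters(
            tukey.significance_matrix(), labels=list(summary.labels), means=list(summary.means)
        )
    for p in products:
        row: dict[str, object] = {"product": p, "unit": unit}
        for col in list(ACIDS) + ["total"]:
            vals = wide.loc[wide["product"] == p, col].to_numpy()
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_sd"] = float(vals.std(ddof=1))
            row[f"{col}_letters"] = letters_by_col[col][p]
        rows.append(row)
    return pd.DataFrame(rows).set_index("product")


def summary_letters(
    summary_df: pd.DataFrame,
    value_prefix: str = "",
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letters re-derived from published summary statistics.

    ``summary_df`` must have columns ``mean``, ``sd``, ``n`` indexed by
    product; useful for checking a printed table's letter pattern.
    """
    summary = GroupSummary(
        labels=tuple(str(i) for i in summary_df.index),
        ns=tuple(int(n) for n in summary_df["n"]),
        means=tuple(float(m) for m in summary_df["mean"]),
        sds=tuple(float(s) for s in summary_df["sd"]),
    )
    tukey = tukey_hsd(summary, alpha=alpha)
    return compact_letters(
        tukey.significance_matrix(), labels=list(summary.labels), means=list(summary.means)
    )


def read_scfa_long(path: str | Path) -> list[ScfaRecord]:
    """Read a long-format SCFA CSV (sample, group, product, acid, timepoint,
    value, unit, replicate)."""
    df = pd.read_csv(path)
    required = {"sample", "group", "product", "acid", "timepoint", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SCFA file {path} lacks columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            ScfaRecord(
                sample_id=str(row["sample"]),
                group=str(row["group"]),
                product=str(row["product"]),
                acid=str(row["acid"]),
                concentration=float(row["value"]),
                unit=str(row["unit"]),
                timepoint=str(row["timepoint"]),
                replicate=str(row["replicate"])
                if "replicate" in df.columns and pd.notna(row["replicate"])
                else "r1",
            )
        )
    return records
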
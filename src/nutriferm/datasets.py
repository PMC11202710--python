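"""Loaders for the bundled published summary tables.

The study deposited no raw data; what it printed - amino-acid composition
of the four products, product protein percentages, DIAAS summaries, and
SCFA group means - ships with the package as transcribed CSV inputs.
Products are ST/RT (standard/reformulated cooked turkey breast) and SH/RH
(standard/reformulated cooked ham).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .aa import AminoAcidProfile, read_product_metadata, read_profile_table

__all__ = [
    "load_published_diaas",
    "load_published_profiles",
    "load_published_scfa_summaries",
    "load_published_scfa_totals",
]


def _data_path(name: str):
    return resources.files("nutriferm.data").joinpath(name)


def load_published_profiles() -> dict[str, AminoAcidProfile]:
    """Amino-acid profiles of the four products (g/100 g), with declared
    protein percentages attached."""
    with resources.as_file(_data_path("aa_composition_published.csv")) as comp, \
            resources.as_file(_data_path("product_metadata.csv")) as meta:
        profiles = read_profile_table(comp, metadata=read_product_metadata(meta))
    return {p.product_id: p for p in profiles}


def load_published_diaas() -> pd.DataFrame:
    """Published DIAAS summaries (mean, sd, limiting unit) per product."""
    with resources.as_file(_data_path("diaas_published.csv")) as path:
        return pd.read_csv(path, index_col="product_id")


def load_published_scfa_summaries() -> pd.DataFrame:
    """Published per-acid SCFA summaries (mean, sd, n) by cohort/product."""
    with resources.as_file(_data_path("scfa_published.csv")) as path:
        return pd.read_csv(path)


def load_published_scfa_totals() -> pd.DataFrame:
    """Published total-SCFA summaries by cohort/product."""
    with resources.as_file(_data_path("scfa_totals_published.csv")) as path:
        return pd.read_csv(path)
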
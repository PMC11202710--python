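"""Post-sequencing community statistics for fermentation samples.

Works on a sample-by-taxon count table with taxonomy labels and group
metadata: relative abundance at a taxonomy rank, alpha-diversity indices
(observed richness, Chao1, ACE, Shannon, Simpson, inverse Simpson,
Fisher's alpha), Bray-Curtis distances, principal-coordinates analysis,
PERMANOVA, and per-taxon group comparisons.

Upstream read processing (denoising, OTU clustering, taxonomy assignment)
is out of scope: counts enter here already tabulated. Phylogenetic metrics
(UniFrac) need a tree and are not computed, but any externally computed
square distance matrix can be supplied to the ordination and PERMANOVA
stages in place of Bray-Curtis.
"""

from __future__ import annotations

import itertools
import math
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .stats import anova_oneway

__all__ = [
    "AbundanceTable",
    "PcoaResult",
    "PermanovaResult",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
    "read_abundance_table",
    "read_distance_matrix",
    "relative_abundance",
    "taxon_group_tests",
]

RANKS = ("phylum", "genus", "otu")


@dataclass
class AbundanceTable:
    """Sample-by-taxon counts with taxonomy and sample metadata.

    ``counts`` is samples x taxa (non-negative); ``taxonomy`` maps each
    taxon to phylum/genus/species labels (missing entries are treated as
    unclassified); ``sample_meta`` carries at least a ``group`` column.
    Taxa observed in no sample are permitted but listed in ``zero_taxa``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    sample_meta: pd.DataFrame
    zero_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing_meta = set(self.counts.index) - set(self.sample_meta.index)
        if missing_meta:
            raise ValueError(f"samples lack metadata: {sorted(missing_meta)}")
        if "group" not in self.sample_meta.columns:
            raise ValueError("sample_meta needs a 'group' column")
        totals = self.counts.sum(axis=1)
        self.zero_taxa = list(self.counts.columns[(self.counts.sum(axis=0) == 0)])
        self._sample_totals = totals

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def groups(self) -> pd.Series:
        return self.sample_meta.loc[self.counts.index, "group"]


def read_abundance_table(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    meta_path: str | Path,
) -> AbundanceTable:
    """Read taxa-as-rows counts TSV + taxonomy TSV + sample metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0).T  # to samples x taxa
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return AbundanceTable(counts=counts, taxonomy=taxonomy, sample_meta=meta)


def _rank_matrix(table: AbundanceTable, rank: str) -> pd.DataFrame:
    """Counts aggregated to a taxonomy rank (samples x rank labels)."""
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    if rank == "otu":
        return table.counts
    labels = []
    for taxon in table.counts.columns:
        if taxon in table.taxonomy.index:
            value = table.taxonomy.loc[taxon].get(rank)
            labels.append("Unclassified" if pd.isna(value) or value == "" else str(value))
        else:
            labels.append("Unclassified")
    return table.counts.T.groupby(pd.Index(labels, name=rank)).sum().T


def relative_abundance(table: AbundanceTable, rank: str = "otu") -> pd.DataFrame:
    """Percent relative abundance per sample at a taxonomy rank.

    Rows sum to 100. Taxa without an assignment at the rank pool into
    "Unclassified". A sample with zero total count has no composition and
    is an error.
    """
    mat = _rank_matrix(table, rank)
    totals = mat.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total count: {list(zero.index)}")
    return mat.div(totals, axis=0) * 100.0


# ---------------------------------------------------------------------------
# Alpha diversity

def _require_integer(counts: np.ndarray, index: str) -> np.ndarray:
    if not np.allclose(counts, np.round(counts)):
        raise ValueError(f"{index} requires integer counts")
    return np.round(counts).astype(np.int64)


def _chao1(counts: np.ndarray) -> float:
    c = _require_integer(counts, "chao1")
    c = c[c > 0]
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _ace(counts: np.ndarray, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator (Chao & Lee), rare cutoff 10."""
    c = _require_integer(counts, "ace")
    c = c[c > 0]
    rare = c[c <= rare_threshold]
    abund = c[c > rare_threshold]
    s_rare, s_abund = rare.size, abund.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if n_rare == f1:
        # all rare species are singletons: sample coverage is zero
        raise ValueError("ace undefined: every rare taxon is a singleton")
    coverage = 1.0 - f1 / n_rare
    fis = np.array([(rare == i).sum() for i in range(1, rare_threshold + 1)], dtype=float)
    i = np.arange(1, rare_threshold + 1, dtype=float)
    gamma = max(
        (s_rare / coverage) * (i * (i - 1) * fis).sum() / (n_rare * (n_rare - 1)) - 1.0,
        0.0,
    ) if n_rare > 1 else 0.0
    return s_abund + s_rare / coverage + (f1 / coverage) * gamma


def _fisher_alpha(counts: np.ndarray, rtol: float = 1e-10) -> float:
    """Fisher's alpha: solve S = alpha * ln(1 + N/alpha) by bracketed root."""
    c = _require_integer(counts, "fisher")
    c = c[c > 0]
    s, n = c.size, int(c.sum())
    if s == n:
        raise ValueError("fisher alpha undefined: every taxon is a singleton")

    def f(alpha: float) -> float:
        return alpha * math.log1p(n / alpha) - s

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e18:  # pragma: no cover - unreachable for s < n
            raise RuntimeError("fisher alpha bracketing failed")
    return float(optimize.brentq(f, lo, hi, rtol=rtol))


def _sample_alpha(counts: np.ndarray) -> dict[str, float]:
    nonzero = counts[counts > 0].astype(float)
    if nonzero.size == 0:
        raise ValueError("alpha diversity undefined for an empty sample")
    _require_integer(counts, "chao1/ace/fisher")  # hard error; NaNs below are degenerate cases
    p = nonzero / nonzero.sum()
    sum_p2 = float((p**2).sum())
    out = {
        "observed": float(nonzero.size),
        "chao1": _chao1(counts),
        "shannon": float(-(p * np.log(p)).sum()),
        "simpson": 1.0 - sum_p2,
        "invsimpson": 1.0 / sum_p2,
    }
    for name, fn in (("ace", _ace), ("fisher", _fisher_alpha)):
        try:
            out[name] = fn(counts)
        except ValueError:
            out[name] = math.nan  # estimator undefined for this configuration
    return out


def alpha_diversity(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha-diversity indices.

    Shannon uses natural log on the proportions of observed taxa. Chao1
    uses the classic F1^2/(2 F2) form with the bias-corrected
    F1(F1-1)/(2(F2+1)) fallback when no doubletons exist; ACE follows
    Chao & Lee with rare-species threshold 10; Fisher's alpha solves
    S = alpha ln(1 + N/alpha) to 1e-10 relative tolerance. The
    richness-style estimators require integer counts.
    """
    counts = table.counts if isinstance(table, AbundanceTable) else table
    rows = {sample: _sample_alpha(counts.loc[sample].to_numpy()) for sample in counts.index}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Beta diversity

def bray_curtis(table: AbundanceTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix between samples.

    d(i,j) = sum |x_i - x_j| / sum (x_i + x_j), in [0, 1]. A pair of
    all-zero samples has no defined dissimilarity and is an error.
    """
    counts = table.counts if isinstance(table, AbundanceTable) else table
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    data = counts.to_numpy(dtype=float)
    empty = counts.index[data.sum(axis=1) == 0]
    if len(empty) >= 2:
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {list(empty)}")
    return DistanceMatrix(squareform(pdist(data, metric="braycurtis")), ids=list(counts.index))


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read an externally computed square distance matrix (TSV, labelled)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix rows and columns must carry the same labels")
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame          # samples x retained axes (positive eigenvalues)
    eigenvalues: np.ndarray            # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray   # per retained axis


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centres -d^2/2, eigendecomposes, and keeps coordinates for the
    positive eigenvalues, ordered by eigenvalue. Negative eigenvalues (a
    non-Euclidean metric's signature) are reported, not silently dropped.
    """
    if not isinstance(d, DistanceMatrix):
        d = DistanceMatrix(np.asarray(d))  # validates symmetry / zero diagonal
    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message=".*negative eigenvalues.*")
        res = _skbio_pcoa(d, method="eigh", number_of_dimensions=0)
    eigvals = res.eigvals.to_numpy()
    positive = eigvals > 1e-12 * max(eigvals.max(), 1.0)
    coords = res.samples.loc[:, positive].copy()
    coords.index = list(d.ids)
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    prop = res.proportion_explained.to_numpy()[positive]
    return PcoaResult(coordinates=coords, eigenvalues=eigvals, proportion_explained=prop)


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    method: str
    degenerate: bool = False  # zero within-group variation


def _group_codes(labels: Sequence[str]) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(labels))
    if len(uniques) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(codes)
    if (counts == 0).any():
        raise ValueError("every group must contain at least one sample")
    return codes, len(uniques)


def _pseudo_f_many(d2: np.ndarray, labelings: np.ndarray, n_groups: int) -> np.ndarray:
    """Pseudo-F for each row of ``labelings`` (vectorised over labelings).

    SS_total = sum_{i<j} d^2 / n; SS_within = sum_g sum_{i<j in g} d^2/n_g;
    F = (SS_between/(a-1)) / (SS_within/(n-a)).
    """
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = np.zeros(labelings.shape[0])
    for g in range(n_groups):
        mask = (labelings == g).astype(float)
        n_g = mask[0].sum()  # group sizes invariant under permutation
        ss_within += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2.0 * n_g)
    a = n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "sampled",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``method="sampled"`` draws ``n_perm`` label permutations from the RNG
    seeded with ``seed`` and reports p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm). ``method="exact"`` enumerates every distinct assignment
    of labels to samples and reports the exact permutation p (the share of
    assignments, observed included, with F >= F_obs).

    When the within-group sum of squares is zero the pseudo-F is infinite;
    the p-value is then reported at its 1/(1 + n_perm) lower bound and the
    result flagged degenerate.
    """
    codes, n_groups = _group_codes(groups)
    n = len(codes)
    if d.shape[0] != n:
        raise ValueError("distance matrix and group labels disagree in length")
    d2 = np.asarray(d.data, dtype=float) ** 2

    f_obs = float(_pseudo_f_many(d2, codes[None, :], n_groups)[0])
    if not np.isfinite(f_obs):
        return PermanovaResult(
            pseudo_F=math.inf,
            p_value=1.0 / (1.0 + n_perm),
            n_permutations=n_perm,
            method=method,
            degenerate=True,
        )

    if method == "exact":
        perms = np.array(sorted({p for p in itertools.permutations(codes)}), dtype=codes.dtype)
        f_perm = _pseudo_f_many(d2, perms, n_groups)
        p = float((f_perm >= f_obs).sum()) / len(perms)
        return PermanovaResult(pseudo_F=f_obs, p_value=p, n_permutations=len(perms), method=method)
    if method != "sampled":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("sampled PERMANOVA requires a seed for reproducibility")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    f_perm = _pseudo_f_many(d2, perms, n_groups)
    p = (1.0 + float((f_perm >= f_obs).sum())) / (1.0 + n_perm)
    return PermanovaResult(pseudo_F=f_obs, p_value=p, n_permutations=n_perm, method=method)


# ---------------------------------------------------------------------------
# Per-taxon group comparisons

def taxon_group_tests(
    table: AbundanceTable,
    rank: str = "genus",
    groups: Sequence[str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-taxon group comparison of relative abundances (one-way ANOVA).

    Returns, per taxon at the rank: group means ± sd of percent relative
    abundance and the ANOVA p-value, sorted by p. Taxa where a group has a
    single replicate, or where all groups are constant and equal, get an
    undefined (NaN) p. ``bh_correct`` adds a Benjamini-Hochberg adjusted
    column (off by default).
    """
    rel = relative_abundance(table, rank)
    labels = table.groups()
    if groups is not None:
        keep = labels.isin(groups)
        rel, labels = rel.loc[keep], labels[keep]
    group_names = sorted(labels.unique())
    if len(group_names) < 2:
        raise ValueError("need at least 2 groups")

    rows = []
    for taxon in rel.columns:
        row: dict[str, object] = {"taxon": taxon}
        by_group = {g: rel.loc[labels == g, taxon].to_numpy() for g in group_names}
        for g, vals in by_group.items():
            row[f"mean_{g}"] = float(vals.mean())
            row[f"sd_{g}"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            row[f"n_{g}"] = int(vals.size)
        if any(v.size < 2 for v in by_group.values()):
            row["p_value"] = math.nan
        else:
            res = anova_oneway({g: list(v) for g, v in by_group.items()})
            row["p_value"] = math.nan if res.undefined else res.p
        rows.append(row)
    out = pd.DataFrame(rows).set_index("taxon").sort_values("p_value")
    if bh_correct:
        mask = out["p_value"].notna()
        adjusted = np.full(len(out), math.nan)
        if mask.any():
            adjusted[mask.to_numpy()] = sps.false_discovery_control(
                out.loc[mask, "p_value"].to_numpy(), method="bh"
            )
        out["p_bh"] = adjusted
    return out
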
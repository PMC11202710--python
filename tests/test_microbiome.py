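"""Community statistics: relative abundance, alpha/beta diversity,
ordination, PERMANOVA, per-taxon tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import alpha as skbio_alpha
from skbio.stats.distance import permanova as skbio_permanova

from nutriferm.microbiome import (
    AbundanceTable,
    alpha_diversity,
    bray_curtis,
    pcoa,
    permanova,
    relative_abundance,
    taxon_group_tests,
)
from nutriferm.simulate import CommunitySimSpec, simulate_community


def small_table(counts, groups=None, taxonomy=None):
    samples = [f"s{i}" for i in range(len(counts))]
    taxa = [f"t{j}" for j in range(len(counts[0]))]
    if taxonomy is None:
        taxonomy = pd.DataFrame(
            {"phylum": ["P1"] * len(taxa), "genus": taxa, "species": taxa}, index=taxa
        )
    meta = pd.DataFrame(
        {"group": groups or ["g"] * len(samples)}, index=samples
    )
    return AbundanceTable(
        counts=pd.DataFrame(counts, index=samples, columns=taxa),
        taxonomy=taxonomy,
        sample_meta=meta,
    )


# ---------------------------------------------------------------------------
# relative abundance

def test_relative_abundance_normalisation():
    table = small_table([[3, 1]])
    rel = relative_abundance(table, "otu")
    assert rel.loc["s0", "t0"] == pytest.approx(75.0)
    assert rel.loc["s0", "t1"] == pytest.approx(25.0)


def test_relative_abundance_phylum_aggregation():
    taxa = ["t0", "t1", "t2"]
    taxonomy = pd.DataFrame(
        {"phylum": ["A", "A", "B"], "genus": taxa, "species": taxa}, index=taxa
    )
    table = small_table([[2, 3, 5]], taxonomy=taxonomy)
    rel = relative_abundance(table, "phylum")
    assert rel.loc["s0", "A"] == pytest.approx(50.0)
    assert rel.loc["s0", "B"] == pytest.approx(50.0)


def test_relative_abundance_rows_sum_to_100_and_unclassified():
    taxa = ["t0", "t1"]
    taxonomy = pd.DataFrame(
        {"phylum": ["A", None], "genus": ["g", None], "species": [None, None]}, index=taxa
    )
    table = small_table([[4, 6], [1, 1]], taxonomy=taxonomy)
    rel = relative_abundance(table, "phylum")
    assert "Unclassified" in rel.columns
    assert np.allclose(rel.sum(axis=1), 100.0)


def test_relative_abundance_zero_sample_error():
    table = small_table([[0, 0], [1, 2]])
    with pytest.raises(ValueError, match="zero total count"):
        relative_abundance(table, "otu")


def test_relative_abundance_recovers_simulated_proportions():
    """At large depth and tight Dirichlet the sampled relative abundances
    sit within 3 multinomial SEs of the generating proportions."""
    base = np.array([0.5, 0.3, 0.15, 0.05])
    spec = CommunitySimSpec(
        n_taxa=4, baseline_proportions=base, depth=200_000,
        concentration=1e7, n_samples_per_group=1, seed=11,
    )
    table = simulate_community(spec)
    rel = relative_abundance(table, "otu").iloc[0].to_numpy() / 100.0
    se = np.sqrt(base * (1 - base) / spec.depth)
    assert (np.abs(rel - base) <= 3 * se + 1e-4).all()


# ---------------------------------------------------------------------------
# alpha diversity

def test_alpha_closed_forms_two_equal_taxa():
    row = alpha_diversity(small_table([[10, 10]]).counts).iloc[0]
    assert row["shannon"] == pytest.approx(math.log(2))
    assert row["simpson"] == pytest.approx(0.5)
    assert row["invsimpson"] == pytest.approx(2.0)
    assert row["observed"] == 2


def test_alpha_single_taxon_no_diversity():
    row = alpha_diversity(small_table([[42]]).counts).iloc[0]
    assert row["shannon"] == pytest.approx(0.0)
    assert row["invsimpson"] == pytest.approx(1.0)


def test_chao1_closed_form_and_f2_zero_fallback():
    # S_obs 5, F1 2, F2 1 -> 5 + 4/2 = 7
    row = alpha_diversity(pd.DataFrame([[1, 1, 2, 3, 4]])).iloc[0]
    assert row["chao1"] == pytest.approx(7.0)
    # F2 = 0 -> bias-corrected form S + F1(F1-1)/2
    row2 = alpha_diversity(pd.DataFrame([[1, 1, 3, 4]])).iloc[0]
    assert row2["chao1"] == pytest.approx(4 + 2 * 1 / 2)


def test_invsimpson_equals_richness_for_even_community():
    for s in (2, 5, 9):
        row = alpha_diversity(pd.DataFrame([[7] * s])).iloc[0]
        assert row["invsimpson"] == pytest.approx(float(s))


def test_shannon_maximal_iff_even_and_zero_taxa_ignored():
    even = alpha_diversity(pd.DataFrame([[5, 5, 5]])).iloc[0]["shannon"]
    uneven = alpha_diversity(pd.DataFrame([[12, 2, 1]])).iloc[0]["shannon"]
    assert even == pytest.approx(math.log(3))
    assert uneven < even
    padded = alpha_diversity(pd.DataFrame([[5, 5, 5, 0]])).iloc[0]
    assert padded["shannon"] == pytest.approx(even)
    assert padded["observed"] == 3


def test_richness_estimators_require_integer_counts():
    with pytest.raises(ValueError, match="integer counts"):
        alpha_diversity(pd.DataFrame([[1.5, 2.2]]))


def test_alpha_matches_skbio(rng):
    counts = rng.integers(0, 60, size=40)
    counts[rng.integers(0, 40, size=8)] = 1  # ensure singletons
    row = alpha_diversity(pd.DataFrame([counts])).iloc[0]
    nz = counts[counts > 0]
    assert row["shannon"] == pytest.approx(float(skbio_alpha.shannon(nz, base=math.e)))
    assert row["simpson"] == pytest.approx(float(skbio_alpha.simpson(nz)))
    assert row["invsimpson"] == pytest.approx(float(skbio_alpha.enspie(nz)))
    assert row["chao1"] == pytest.approx(float(skbio_alpha.chao1(nz, bias_corrected=False)))
    assert row["ace"] == pytest.approx(float(skbio_alpha.ace(nz)), rel=1e-6)
    assert row["fisher"] == pytest.approx(float(skbio_alpha.fisher_alpha(nz)), rel=1e-6)


def test_chao1_at_least_observed(rng):
    for _ in range(20):
        counts = rng.integers(0, 20, size=30)
        if counts.sum() == 0 or (counts[counts > 0] == 1).all():
            continue
        row = alpha_diversity(pd.DataFrame([counts])).iloc[0]
        assert row["chao1"] >= row["observed"]


# ---------------------------------------------------------------------------
# Bray-Curtis and PCoA

def test_bray_curtis_cases():
    dm = bray_curtis(pd.DataFrame([[2, 0], [1, 1], [2, 0], [0, 5]]))
    assert dm[0, 2] == pytest.approx(0.0)    # identical samples
    assert dm[0, 3] == pytest.approx(1.0)    # disjoint supports
    assert dm[0, 1] == pytest.approx(0.5)    # (1+1)/4
    assert (np.asarray(dm.data) <= 1.0).all() and (np.asarray(dm.data) >= 0.0).all()


def test_bray_curtis_all_zero_pair_error():
    with pytest.raises(ValueError, match="all-zero"):
        bray_curtis(pd.DataFrame([[0, 0], [0, 0], [1, 2]]))


def test_pcoa_recovers_line_geometry():
    points = np.array([0.0, 3.0, 5.0])
    d = np.abs(points[:, None] - points[None, :])
    res = pcoa(DistanceMatrix(d, ids=["a", "b", "c"]))
    axis1 = res.coordinates.iloc[:, 0].to_numpy()
    recon = np.abs(axis1[:, None] - axis1[None, :])
    assert np.allclose(recon, d, atol=1e-8)


def test_pcoa_equidistant_simplex_eigenvalues():
    d = np.full((4, 4), 1.0) - np.eye(4)
    res = pcoa(DistanceMatrix(d))
    positive = res.eigenvalues[res.eigenvalues > 1e-12]
    assert len(positive) == 3
    assert np.allclose(positive, positive[0])


def test_pcoa_duplicate_samples_identical_coordinates(rng):
    pts = rng.normal(size=(4, 3))
    pts = np.vstack([pts, pts[0]])
    d = squareform(pdist(pts))
    res = pcoa(DistanceMatrix(d))
    assert np.allclose(res.coordinates.iloc[0], res.coordinates.iloc[-1], atol=1e-8)


def test_pcoa_euclidean_reconstruction(rng):
    pts = rng.normal(size=(7, 4))
    d = squareform(pdist(pts))
    res = pcoa(DistanceMatrix(d))
    coords = res.coordinates.to_numpy()
    recon = squareform(pdist(coords))
    assert np.allclose(recon, d, atol=1e-8)
    assert (res.eigenvalues >= -1e-8).all()


def test_pcoa_rejects_asymmetric_input():
    with pytest.raises(Exception):
        pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


# ---------------------------------------------------------------------------
# PERMANOVA

def brute_force_permanova_p(d, labels):
    """Independent oracle: full enumeration with explicit loops."""
    n = len(labels)
    uniq = sorted(set(labels))

    def pseudo_f(lab):
        ss_total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                ss_total += d[i][j] ** 2
        ss_total /= n
        ss_within = 0.0
        for g in uniq:
            idx = [i for i in range(n) if lab[i] == g]
            acc = 0.0
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    acc += d[idx[a]][idx[b]] ** 2
            ss_within += acc / len(idx)
        a_groups = len(uniq)
        return ((ss_total - ss_within) / (a_groups - 1)) / (ss_within / (n - a_groups))

    f_obs = pseudo_f(labels)
    assignments = sorted(set(itertools.permutations(labels)))
    hits = sum(1 for lab in assignments if pseudo_f(lab) >= f_obs)
    return f_obs, hits / len(assignments)


@pytest.mark.parametrize("sizes", [(3, 3), (2, 4), (2, 2)])
def test_permanova_exact_matches_brute_force(sizes, rng):
    n = sum(sizes)
    pts = rng.normal(size=(n, 3))
    d = squareform(pdist(pts))
    labels = ["a"] * sizes[0] + ["b"] * sizes[1]
    res = permanova(DistanceMatrix(d), labels, method="exact")
    f_ref, p_ref = brute_force_permanova_p(d, labels)
    assert res.pseudo_F == pytest.approx(f_ref, rel=1e-10)
    assert res.p_value == pytest.approx(p_ref, abs=1e-12)


def test_permanova_matches_skbio_pseudo_f(rng):
    pts = rng.normal(size=(8, 3))
    d = DistanceMatrix(squareform(pdist(pts)))
    labels = ["a"] * 4 + ["b"] * 4
    ours = permanova(d, labels, n_perm=999, seed=1)
    ref = skbio_permanova(d, grouping=labels, permutations=999)
    assert ours.pseudo_F == pytest.approx(float(ref["test statistic"]), rel=1e-10)


def test_permanova_seeded_reproducibility(rng):
    pts = rng.normal(size=(10, 2))
    d = DistanceMatrix(squareform(pdist(pts)))
    labels = ["a"] * 5 + ["b"] * 5
    r1 = permanova(d, labels, n_perm=499, seed=42)
    r2 = permanova(d, labels, n_perm=499, seed=42)
    assert r1 == r2
    with pytest.raises(ValueError, match="seed"):
        permanova(d, labels, n_perm=499)


def test_permanova_degenerate_duplicated_rows():
    pts = np.array([[0.0, 0.0], [1.0, 1.0]])
    d = squareform(pdist(np.vstack([pts[0], pts[0], pts[1], pts[1]])))
    res = permanova(DistanceMatrix(d), ["a", "a", "b", "b"], n_perm=999, seed=0)
    assert res.degenerate
    assert res.p_value == pytest.approx(1.0 / 1000.0)


def test_permanova_group_size_validation():
    d = DistanceMatrix(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        permanova(d, ["a", "a", "a"], n_perm=9, seed=0)


# ---------------------------------------------------------------------------
# per-taxon tests

def test_taxon_group_tests_spiked_genus_ranks_first():
    base = np.full(24, 1 / 24)
    spec = CommunitySimSpec(
        n_taxa=24, baseline_proportions=base,
        group_effects={"Otu_1": 2.0}, depth=50_000, concentration=20_000,
        n_samples_per_group=3, n_genera=24, seed=5,
    )
    table = simulate_community(spec)
    res = taxon_group_tests(table, rank="otu")
    assert res.index[0] == "Otu_1"
    assert res["p_value"].iloc[0] < 0.05


def test_taxon_group_tests_no_variance_is_undefined():
    table = small_table(
        [[10, 10], [10, 10], [10, 10], [10, 10]],
        groups=["a", "a", "b", "b"],
    )
    res = taxon_group_tests(table, rank="otu")
    assert res["p_value"].isna().all()


def test_taxon_group_tests_single_replicate_undefined():
    table = small_table([[10, 5], [8, 2]], groups=["a", "b"])
    res = taxon_group_tests(table, rank="otu")
    assert res["p_value"].isna().all()


def test_taxon_group_tests_bh_flag(rng):
    spec = CommunitySimSpec(n_taxa=12, depth=5000, n_samples_per_group=3, seed=9)
    table = simulate_community(spec)
    res = taxon_group_tests(table, rank="otu", bh_correct=True)
    ok = res["p_value"].notna()
    assert (res.loc[ok, "p_bh"] >= res.loc[ok, "p_value"] - 1e-12).all()
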
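"""Per-locus diversity statistics, band-sharing similarity and UPGMA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from ssrkit.diversity import (
    GenotypeMatrix,
    UndefinedPairError,
    locus_stats,
    locus_stats_table,
    pic_from_freqs,
    similarity_matrix,
    upgma_tree,
)
from ssrkit.synthetic import pear44_preset, simulate_genotypes


def matrix_from_calls(calls, n_loci=1):
    """Build a GenotypeMatrix from [(a, b) or None per individual] per locus."""
    if not isinstance(calls[0], list):
        calls = [calls]
    n_ind = len(calls[0])
    arr = np.full((n_ind, len(calls), 2), -1, dtype=np.int64)
    for j, locus_calls in enumerate(calls):
        for i, cell in enumerate(locus_calls):
            if cell is not None:
                arr[i, j] = sorted(cell)
    return GenotypeMatrix(
        individuals=[f"i{i}" for i in range(n_ind)],
        loci=[f"L{j}" for j in range(len(calls))],
        calls=arr,
    )


def brute_force_stats(locus_calls):
    """Independent enumeration over gene copies for <= 6 individuals:
    He as the probability that two copies drawn with replacement differ,
    PIC via the explicit double loop over allele frequencies."""
    scored = [c for c in locus_calls if c is not None]
    copies = [a for pair in scored for a in pair]
    n = len(copies)
    he = sum(1 for x in copies for y in copies if x != y) / n**2
    alleles = sorted(set(copies))
    freqs = [copies.count(a) / n for a in alleles]
    pic = 1.0 - sum(p * p for p in freqs)
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            pic -= 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    ho = sum(1 for a, b in scored if a != b) / len(scored)
    ng = len({tuple(sorted(c)) for c in scored})
    return {"na": len(alleles), "ng": ng, "major_freq": max(freqs), "ho": ho, "he": he, "pic": pic}


class TestLocusStats:
    def test_hand_worked_two_allele_example(self):
        m = matrix_from_calls([(100, 100), (100, 120), (120, 120), (100, 120)])
        s = locus_stats(m, "L0")
        assert (s.na, s.ng) == (2, 3)
        assert s.major_freq == pytest.approx(0.5)
        assert s.ho == pytest.approx(0.5)
        assert s.he == pytest.approx(0.5)
        assert s.pic == pytest.approx(0.375)

    def test_monomorphic_locus(self):
        m = matrix_from_calls([(100, 100), (100, 100)])
        s = locus_stats(m, "L0")
        assert (s.na, s.ng, s.ho, s.he, s.pic) == (1, 1, 0.0, 0.0, 0.0)

    def test_equifrequent_alleles_closed_form(self):
        # 4 alleles at frequency 1/4 each: He = 3/4, PIC = 0.703125
        m = matrix_from_calls([(100, 102), (104, 106), (100, 102), (104, 106)])
        s = locus_stats(m, "L0")
        assert s.he == pytest.approx(0.75)
        assert s.pic == pytest.approx(0.703125)
        k = 4
        closed = 1 - 1 / k - 2 * (k - 1) / (2 * k**3)
        assert s.pic == pytest.approx(closed)

    def test_missing_cells_excluded(self):
        m = matrix_from_calls([(100, 100), None, (100, 120)])
        s = locus_stats(m, "L0")
        assert s.n_scored == 2
        assert s.major_freq == pytest.approx(0.75)

    def test_all_missing_locus_raises(self):
        m = matrix_from_calls([[None, (100, 100)], [(1, 2), (3, 4)]][0:1] * 1)
        m2 = matrix_from_calls([[None, None], [(100, 102), (100, 100)]])
        with pytest.raises(ValueError):
            locus_stats(m2, "L0")

    def test_matches_bruteforce_enumeration_on_small_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            n_ind = int(rng.integers(2, 7))
            sizes = (100 + 2 * rng.integers(0, 5, size=(n_ind, 2))).tolist()
            calls = [tuple(pair) for pair in sizes]
            if rng.random() < 0.3:
                calls[int(rng.integers(0, n_ind))] = None
            if all(c is None for c in calls):
                continue
            m = matrix_from_calls(calls)
            s = locus_stats(m, "L0")
            expected = brute_force_stats(calls)
            for key, value in expected.items():
                assert getattr(s, key) == pytest.approx(value), key

    def test_pic_he_inequalities(self):
        matrix, _ = simulate_genotypes(pear44_preset(seed=1))
        table = locus_stats_table(matrix)
        assert ((table.pic <= table.he + 1e-12).all())
        assert ((table.he <= 1 - 1 / table.na + 1e-12).all())
        assert table[["major_freq", "ho", "he", "pic"]].ge(0).all().all()
        assert table[["major_freq", "ho", "he", "pic"]].le(1).all().all()
        assert (table.ng <= table.na * (table.na + 1) / 2).all()

    def test_unbiased_correction_scales(self):
        m = matrix_from_calls([(100, 102), (104, 106), (100, 102), (104, 106)])
        plain = locus_stats(m, "L0").he
        corrected = locus_stats(m, "L0", unbiased_he=True).he
        assert corrected == pytest.approx(plain * 8 / 7)


class TestSimilarityMatrix:
    def test_identical_rows_similarity_one(self):
        m = matrix_from_calls([[(100, 102), (100, 102)], [(140, 140), (140, 140)]])
        sim = similarity_matrix(m)
        assert sim.iloc[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(sim), 1.0)

    def test_disjoint_alleles_similarity_zero(self):
        m = matrix_from_calls([[(100, 102), (104, 106)], [(140, 142), (144, 146)]])
        assert similarity_matrix(m).iloc[0, 1] == pytest.approx(0.0)

    def test_hand_worked_dice_example(self):
        # locus 1: bands {100,102} vs {100,104} -> shared 1, only-i 1, only-j 1
        # locus 2: bands {140} vs {140,142}     -> shared 1, only-j 1
        m = matrix_from_calls([[(100, 102), (100, 104)], [(140, 140), (140, 142)]])
        sim = similarity_matrix(m)
        assert sim.iloc[0, 1] == pytest.approx(2 * 2 / (2 * 2 + 1 + 2))

    def test_pairwise_deletion_of_missing_loci(self):
        m = matrix_from_calls([[(100, 102), (100, 102)], [None, (140, 140)]])
        assert similarity_matrix(m).iloc[0, 1] == pytest.approx(1.0)

    def test_no_jointly_scored_locus_raises(self):
        m = matrix_from_calls([[(100, 102), None], [None, (140, 140)]])
        with pytest.raises(UndefinedPairError):
            similarity_matrix(m)

    def test_symmetry_and_range(self):
        matrix, _ = simulate_genotypes(pear44_preset(seed=6))
        sim = similarity_matrix(matrix)
        arr = sim.to_numpy()
        assert np.allclose(arr, arr.T)
        assert arr.min() >= 0.0 and arr.max() <= 1.0


def random_ultrametric(rng, n):
    """Distance matrix from a random ultrametric tree built by random merges
    at strictly increasing heights."""
    clusters = [[i] for i in range(n)]
    dist = np.zeros((n, n))
    height = 0.0
    while len(clusters) > 1:
        height += float(rng.uniform(0.02, 0.1))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                dist[a, b] = dist[b, a] = 2 * height
        clusters[i] = clusters[i] + clusters.pop(j)
    return dist


class TestUpgma:
    def test_hand_agglomeration(self):
        sim = pd.DataFrame(
            1 - np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.4], [0.4, 0.4, 0.0]]),
            index=list("ABC"),
            columns=list("ABC"),
        )
        tree = upgma_tree(sim)
        dists = tree.tip_tip_distances()
        assert dists["A", "B"] == pytest.approx(0.2)
        assert dists["A", "C"] == pytest.approx(0.4)
        assert dists["B", "C"] == pytest.approx(0.4)
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"}

    def test_two_taxa_root_height_half_distance(self):
        sim = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]], index=["A", "B"], columns=["A", "B"])
        tree = upgma_tree(sim)
        assert all(tip.length == pytest.approx(0.3) for tip in tree.tips())

    def test_ultrametric_output(self):
        matrix, _ = simulate_genotypes(pear44_preset(seed=9))
        tree = upgma_tree(similarity_matrix(matrix))
        depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
        assert np.allclose(depths, depths[0], atol=1e-9)

    def test_cophenetic_round_trip_on_ultrametric_inputs(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            dist = random_ultrametric(rng, n)
            labels = [f"t{i}" for i in range(n)]
            sim = pd.DataFrame(1 - dist, index=labels, columns=labels)
            tree = upgma_tree(sim)
            coph = tree.tip_tip_distances(endpoints=labels)
            for a in range(n):
                for b in range(a + 1, n):
                    assert coph[labels[a], labels[b]] == pytest.approx(dist[a, b], abs=1e-9)

    def test_agrees_with_scipy_average_linkage(self, rng):
        """Cophenetic distances must match scipy's UPGMA on generic data."""
        for _ in range(5):
            n = 8
            raw = rng.random((n, n)) * 0.8
            dist = (raw + raw.T) / 2
            np.fill_diagonal(dist, 0.0)
            labels = [f"t{i}" for i in range(n)]
            tree = upgma_tree(pd.DataFrame(1 - dist, index=labels, columns=labels))
            expected = squareform(cophenet(linkage(squareform(dist), method="average")))
            coph = tree.tip_tip_distances(endpoints=labels)
            for a in range(n):
                for b in range(a + 1, n):
                    assert coph[labels[a], labels[b]] == pytest.approx(expected[a, b], abs=1e-9)

    def test_label_permutation_gives_isomorphic_tree(self):
        matrix, _ = simulate_genotypes(pear44_preset(seed=4))
        sim = similarity_matrix(matrix)
        perm = list(reversed(sim.index))
        tree_a = upgma_tree(sim)
        tree_b = upgma_tree(sim.loc[perm, perm])
        da = tree_a.tip_tip_distances(endpoints=list(sim.index))
        db = tree_b.tip_tip_distances(endpoints=list(sim.index))
        assert np.allclose(da.data, db.data, atol=1e-9)

    def test_outlier_attaches_above_population_clades(self):
        """The single outlier individual joins the dendrogram above the two
        population clades in at least 90% of seeded replicates."""
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            matrix, labels = simulate_genotypes(pear44_preset(seed=seed))
            (outlier,) = labels.index[labels == "outlier"]
            tree = upgma_tree(similarity_matrix(matrix))
            root_clades = [
                {t.name for t in child.tips()} or {child.name} for child in tree.children
            ]
            hits += {outlier} in root_clades
        assert hits >= 0.9 * n_rep
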
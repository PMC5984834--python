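import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gcfkit.model import ValidationError
from gcfkit.profiles import (
    dice_distance_matrix,
    dice_similarity,
    presence_absence,
    rarefaction,
    upgma,
)


class TestPresenceAbsence:
    def test_shared_family_column_of_ones(self, truth_partition, default_dataset):
        genomes, truth = default_dataset
        strains = [g.genome_id for g in genomes]
        m = presence_absence(truth_partition, strains)
        core = [f for f, t in truth.tier_of.items() if t == "core"]
        assert (m[core].to_numpy() == 1).all()

    def test_binary_and_row_sums_match_truth(self, truth_partition, default_dataset):
        genomes, truth = default_dataset
        strains = [g.genome_id for g in genomes]
        m = presence_absence(truth_partition, strains)
        assert set(np.unique(m.to_numpy())) <= {0, 1}
        for g in genomes:
            expected = len({truth.gcf_of[b.bgc_id] for b in g.bgcs})
            assert m.loc[g.genome_id].sum() == expected
        # every family column has at least one presence
        assert (m.sum(axis=0) >= 1).all()

    def test_multicopy_family_binarized(self):
        from gcfkit.families import GcfPartition, categorize_gcfs

        part = categorize_gcfs(GcfPartition(
            family_of={"b1": "f", "b2": "f"}, members={"f": ["b1", "b2"]},
            strains={"f": {"s1"}}, consensus_class={"f": "PKS"},
        ))
        m = presence_absence(part, ["s1", "s2"])
        assert m.loc["s1", "f"] == 1 and m.loc["s2", "f"] == 0


class TestDice:
    def test_identical_rows(self):
        assert dice_similarity([1, 1, 0], [1, 1, 0]) == 1.0

    def test_half_shared(self):
        assert dice_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_disjoint_and_empty(self):
        assert dice_similarity([1, 0], [0, 1]) == 0.0
        assert dice_similarity([0, 0], [0, 0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dice_similarity([1, 0], [1, 0, 1])

    def test_symmetric_bounded_on_random_rows(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b = rng.integers(0, 2, 12), rng.integers(0, 2, 12)
            s, t = dice_similarity(a, b), dice_similarity(b, a)
            assert s == t and 0.0 <= s <= 1.0
            if s == 1.0:
                assert (a == b).all() and a.sum() > 0


# ---------------------------------------------------------------- UPGMA


def upgma_oracle(d):
    """Naive UPGMA recomputing every cluster-average from the original
    matrix at each step; ties to the lowest-index pair."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    nxt = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, j in itertools.combinations(keys, 2):
            avg = np.mean([d[x, y] for x in clusters[i] for y in clusters[j]])
            if best is None or (avg, i, j) < best:
                best = (avg, i, j)
        avg, i, j = best
        clusters[nxt] = clusters.pop(i) + clusters.pop(j)
        merges.append((i, j, avg / 2.0, nxt))
        nxt += 1
    return merges


class TestUpgma:
    def test_three_taxa_worked_example(self):
        d = pd.DataFrame([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]],
                         index=list("ABC"), columns=list("ABC"))
        assert upgma(d).newick == "((A:0.1,B:0.1):0.2,C:0.3);"

    def test_two_taxa(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=list("AB"), columns=list("AB"))
        assert upgma(d).newick == "(A:0.2,B:0.2);"

    def test_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            m = rng.uniform(0.05, 1.0, size=(n, n))
            d = np.triu(m, 1)
            d = d + d.T
            tree = upgma(d)
            oracle = upgma_oracle(d)
            assert len(tree.merges) == len(oracle)
            for (i, j, h, x), (oi, oj, oh, ox) in zip(tree.merges, oracle):
                assert (i, j, x) == (oi, oj, ox)
                assert h == pytest.approx(oh, abs=1e-9)

    def test_ultrametric_on_random_matrices(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            m = rng.uniform(0.05, 1.0, size=(n, n))
            d = np.triu(m, 1)
            d = d + d.T
            tree = upgma(d)
            # parse the emitted Newick and check root-to-leaf depths agree
            import skbio

            t = skbio.TreeNode.read([tree.newick])
            depths = {tip.name: t.distance(tip) for tip in t.tips()}
            root_h = tree.merges[-1][2]
            for v in depths.values():
                assert v == pytest.approx(root_h, abs=1e-9)

    def test_nan_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValidationError):
            upgma(d)

    def test_cut_recovers_planted_clades(self, truth_partition, default_dataset):
        genomes, truth = default_dataset
        strains = [g.genome_id for g in genomes]
        m = presence_absence(truth_partition, strains)
        tree = upgma(dice_distance_matrix(m))
        k = len(set(truth.clade_of.values()) - {"singleton"}) + sum(
            c == "singleton" for c in truth.clade_of.values())
        groups = tree.cut(k)
        clade_sets = {}
        for s, c in truth.clade_of.items():
            if c != "singleton":
                clade_sets.setdefault(c, set()).add(s)
        for members in clade_sets.values():
            assert members in groups


# ------------------------------------------------------------ rarefaction


def rarefaction_enumeration_oracle(inc, k):
    """Mean richness over all C(n, k) strain subsets, by enumeration."""
    n = inc.shape[0]
    rich = [
        int(inc[list(rows)].any(axis=0).sum())
        for rows in itertools.combinations(range(n), k)
    ]
    return float(np.mean(rich))


class TestRarefaction:
    def test_three_strain_worked_example(self):
        # family1 in all 3 strains, family2 in one: S(1) = 2 - 2/3 = 4/3
        m = pd.DataFrame([[1, 1], [1, 0], [1, 0]])
        curve = rarefaction(m)
        assert curve.expected[0] == pytest.approx(4 / 3)
        assert curve.expected[-1] == 2.0  # k = n gives observed richness

    def test_analytic_equals_enumeration_small_n(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            inc = rng.integers(0, 2, size=(n, int(rng.integers(3, 10))))
            curve = rarefaction(pd.DataFrame(inc))
            for idx, k in enumerate(curve.k):
                oracle = rarefaction_enumeration_oracle(inc.astype(bool), int(k))
                assert curve.expected[idx] == pytest.approx(oracle, abs=1e-12)

    def test_monte_carlo_agrees_with_analytic(self):
        rng = np.random.default_rng(5)
        inc = rng.integers(0, 2, size=(20, 40))
        curve = rarefaction(pd.DataFrame(inc), n_resamples=2000,
                            rng=np.random.default_rng(99))
        for idx in range(len(curve.k)):
            # SE can collapse to 0 near k = n where every subset already
            # contains all families; allow a small absolute floor there
            assert abs(curve.resample_mean[idx] - curve.expected[idx]) <= max(
                3 * curve.resample_se[idx], 0.01)

    def test_monotone_and_concave(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(2, 12))
            inc = rng.integers(0, 2, size=(n, int(rng.integers(2, 25))))
            s = rarefaction(pd.DataFrame(inc)).expected
            assert (np.diff(s) >= -1e-12).all()
            if len(s) >= 3:
                assert (np.diff(s, 2) <= 1e-12).all()
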
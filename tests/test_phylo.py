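import itertools

import numpy as np
import pytest

from conftest import random_additive_instance
from polytax.core_io import Alignment
from polytax.phylo import (
    BootstrapSpec,
    DistanceModel,
    bootstrap_support,
    build_tree,
    exhaustive_minimum_evolution,
    load_empirical_model,
    me_tree_length,
    minimum_evolution,
    neighbor_joining,
    pairwise_distance,
    upgma,
)
from polytax.synthetic import child_seed, evolve_protein_pair, mutate_protein, _random_protein


class TestDistances:
    def test_identical_rows_zero_under_every_model(self):
        aln = Alignment(["a", "b"], ["MKLVW" * 40, "MKLVW" * 40])
        for name in ("p", "poisson", "jtt", "dayhoff"):
            _, d = pairwise_distance(aln, DistanceModel(name))
            assert d[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_poisson_closed_form(self):
        # p = 0.1 -> -ln(0.9)
        aln = Alignment(["a", "b"], ["A" * 90 + "C" * 10, "A" * 90 + "G" * 10])
        _, d = pairwise_distance(aln, DistanceModel("poisson"))
        assert d[0, 1] == pytest.approx(-np.log(0.9), abs=1e-12)

    def test_poisson_saturation_error(self):
        aln = Alignment(["a", "b"], ["AAAA", "CCCC"])
        with pytest.raises(ValueError, match="saturated"):
            pairwise_distance(aln, DistanceModel("poisson"))

    @pytest.mark.parametrize("model", ["jtt", "dayhoff"])
    def test_ml_distance_recovers_planted_t(self, model):
        rng = child_seed(17, f"ml_{model}")
        a, b = evolve_protein_pair(2000, 0.175, rng, model=model)
        aln = Alignment(["a", "b"], [a, b])
        _, d = pairwise_distance(aln, DistanceModel(model))
        assert d[0, 1] == pytest.approx(0.175, abs=0.02)

    def test_jensen_ordering_p_poisson_jtt(self):
        rng = child_seed(23, "ordering")
        a, b = evolve_protein_pair(1500, 0.4, rng)
        aln = Alignment(["a", "b"], [a, b])
        dp = pairwise_distance(aln, DistanceModel("p"))[1][0, 1]
        dpo = pairwise_distance(aln, DistanceModel("poisson"))[1][0, 1]
        djtt = pairwise_distance(aln, DistanceModel("jtt"))[1][0, 1]
        assert dp < dpo < djtt

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            DistanceModel("wag")

    def test_gap_columns_removed_first(self):
        aln = Alignment(["a", "b"], ["AC-A", "ACCC"])
        _, d = pairwise_distance(aln, DistanceModel("p"))
        assert d[0, 1] == pytest.approx(1 / 3)


class TestEmpiricalModels:
    @pytest.mark.parametrize("name", ["jtt", "dayhoff"])
    def test_stationary_and_scaled(self, name):
        m = load_empirical_model(name)
        assert m.freqs.sum() == pytest.approx(1.0)
        assert -np.dot(m.freqs, np.diag(m.q)) == pytest.approx(1.0)
        # detailed balance: pi_i q_ij = pi_j q_ji
        prod = m.freqs[:, None] * m.q
        assert np.allclose(prod, prod.T, atol=1e-12)
        p = m.transition(0.5)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.allclose(m.freqs @ p, m.freqs)


class TestUpgma:
    def test_two_taxa_root_height(self):
        t = upgma(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert t.path_distance("a", "b") == pytest.approx(2.0)
        assert t.root.children[0].length == pytest.approx(1.0)

    def test_ultrametric_recovery(self):
        # tree ((a:1,b:1):2,(c:2,d:2):1) -> cophenetic matrix
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0.0, 2.0, 6.0, 6.0],
                [2.0, 0.0, 6.0, 6.0],
                [6.0, 6.0, 0.0, 4.0],
                [6.0, 6.0, 4.0, 0.0],
            ]
        )
        t = upgma(labels, d)
        assert t.bipartitions() == {frozenset({"c", "d"})}
        for i, j in itertools.combinations(range(4), 2):
            assert t.path_distance(labels[i], labels[j]) == pytest.approx(d[i, j])

    def test_tie_broken_by_lowest_label_pair(self):
        labels = ["a", "b", "c"]
        d = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        t = upgma(labels, d)
        # (a,b) must merge first under the documented tie rule
        first = min(
            (n for n in t.root.non_tips(include_self=False)),
            key=lambda n: len(list(n.tips())),
        )
        assert sorted(x.name for x in first.tips()) == ["a", "b"]

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            upgma(["a", "b"], np.array([[0.0, np.nan], [np.nan, 0.0]]))


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # ((a:1,b:2):1,(c:3,d:4))
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ]
        )
        t = neighbor_joining(labels, d)
        assert t.bipartitions() == {frozenset({"c", "d"})}
        for i, j in itertools.combinations(range(4), 2):
            assert t.path_distance(labels[i], labels[j]) == pytest.approx(
                d[i, j], abs=1e-9
            )

    def test_three_taxa_three_point_formulas(self):
        labels = ["a", "b", "c"]
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        t = neighbor_joining(labels, d)
        # la = (dab+dac-dbc)/2 = 1, lb = 2, lc = 3
        assert t.path_distance("a", "b") == pytest.approx(3.0)
        assert t.path_distance("a", "c") == pytest.approx(4.0)
        assert t.path_distance("b", "c") == pytest.approx(5.0)

    def test_random_8_taxon_additive_paths(self, rng):
        labels, d, _, _ = random_additive_instance(8, rng)
        t = neighbor_joining(labels, d)
        for i, j in itertools.combinations(range(8), 2):
            assert t.path_distance(labels[i], labels[j]) == pytest.approx(
                d[i, j], abs=1e-9
            )

    def test_needs_three_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(["a", "b"], np.zeros((2, 2)))

    def test_branch_lengths_nonnegative(self, rng):
        labels, d, _, _ = random_additive_instance(6, rng)
        noisy = d + rng.uniform(0, 0.3, size=d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        t = neighbor_joining(labels, noisy)
        assert all(
            (n.length or 0.0) >= 0 for n in t.root.traverse(include_self=False)
        )


class TestMinimumEvolution:
    def test_ols_lengths_equal_truth_on_additive(self, rng):
        labels, d, topo, lengths = random_additive_instance(6, rng)
        total = me_tree_length(topo, labels, d)
        assert total == pytest.approx(sum(lengths.values()), abs=1e-9)

    def test_three_point_star(self):
        from polytax.phylo import UnrootedTopology, _ols_lengths

        topo = UnrootedTopology(["a", "b", "c"], {0: {3}, 1: {3}, 2: {3}, 3: {0, 1, 2}})
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        lengths, total = _ols_lengths(topo, d)
        assert total == pytest.approx(6.0)
        assert lengths[(0, 3)] == pytest.approx(1.0)

    def test_generating_topology_beats_random_on_perturbed(self, rng):
        labels, d, topo, _ = random_additive_instance(6, rng)
        noisy = d + rng.normal(0, 0.05, size=d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        true_len = me_tree_length(topo, labels, noisy)
        alt = topo.nni_neighbors()[0]
        assert true_len <= me_tree_length(alt, labels, noisy) + 1e-9

    def test_additive_me_equals_nj_equals_truth(self, rng):
        labels, d, topo, _ = random_additive_instance(6, rng)
        nj = neighbor_joining(labels, d)
        me = minimum_evolution(labels, d)
        assert me.bipartitions() == nj.bipartitions() == topo.to_phylotree().bipartitions()

    @pytest.mark.parametrize("n_taxa,seed", [(5, 1), (5, 2), (6, 3), (6, 4)])
    def test_equals_exhaustive_on_perturbed_instances(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        labels, d, _, _ = random_additive_instance(n_taxa, rng)
        noisy = d + rng.normal(0, 0.1 * d.mean(), size=d.shape)
        noisy = np.abs((noisy + noisy.T) / 2)
        np.fill_diagonal(noisy, 0.0)
        me = minimum_evolution(labels, noisy)
        exh, exh_len = exhaustive_minimum_evolution(labels, noisy)
        assert me.bipartitions() == exh.bipartitions()
        assert me_tree_length(me, labels, noisy) == pytest.approx(exh_len, abs=1e-9)

    def test_search_never_worse_than_nj(self, rng):
        for _ in range(5):
            labels, d, _, _ = random_additive_instance(6, rng)
            noisy = np.abs(d + rng.normal(0, 0.2, size=d.shape))
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            nj_len = me_tree_length(neighbor_joining(labels, noisy), labels, noisy)
            me_len = me_tree_length(minimum_evolution(labels, noisy), labels, noisy)
            assert me_len <= nj_len + 1e-9


def _separable_alignment(n_cols=1000):
    """Columns perfectly partition {a,b} from {c,d}."""
    half = n_cols
    rows = {
        "a": "A" * half,
        "b": "A" * half,
        "c": "C" * half,
        "d": "C" * half,
    }
    # add distinguishing noise so distances are finite and distinct
    rows = {
        "a": "A" * half,
        "b": "A" * (half - 10) + "G" * 10,
        "c": "C" * half,
        "d": "C" * (half - 10) + "T" * 10,
    }
    labels = sorted(rows)
    return Alignment(labels, [rows[k] for k in labels])


class TestBootstrap:
    def test_central_edge_support_100(self):
        aln = _separable_alignment()
        tree = bootstrap_support(
            aln, DistanceModel("p"), "nj", BootstrapSpec(replicates=200, seed=5)
        )
        support = tree.support_values()
        assert support[frozenset({"c", "d"})] == pytest.approx(100.0)

    def test_reproducible_for_fixed_seed(self):
        rng = child_seed(3, "boot_repro")
        freqs = load_empirical_model("jtt").freqs
        anc = _random_protein(200, rng, freqs)
        rows = {
            lab: mutate_protein(anc, 0.15, rng) for lab in ("a", "b", "c", "d", "e")
        }
        aln = Alignment(sorted(rows), [rows[k] for k in sorted(rows)])
        spec = BootstrapSpec(replicates=50, seed=11)
        t1 = bootstrap_support(aln, DistanceModel("p"), "nj", spec)
        t2 = bootstrap_support(aln, DistanceModel("p"), "nj", spec)
        assert t1.support_values() == t2.support_values()
        assert all(0 <= v <= 100 for v in t1.support_values().values())

    def test_column_shuffle_leaves_separable_support(self, rng):
        aln = _separable_alignment()
        perm = rng.permutation(aln.n_cols)
        shuffled = aln.take_columns(perm)
        spec = BootstrapSpec(replicates=100, seed=7)
        s1 = bootstrap_support(aln, DistanceModel("p"), "nj", spec).support_values()
        s2 = bootstrap_support(shuffled, DistanceModel("p"), "nj", spec).support_values()
        assert s1[frozenset({"c", "d"})] == s2[frozenset({"c", "d"})] == 100.0

    def test_support_converges_with_columns(self):
        # no conflicting signal: support must reach 100 as columns grow
        for n_cols in (50, 2000):
            aln = _separable_alignment(n_cols)
            tree = bootstrap_support(
                aln, DistanceModel("p"), "nj", BootstrapSpec(replicates=100, seed=2)
            )
            if n_cols >= 2000:
                assert tree.support_values()[frozenset({"c", "d"})] == 100.0


class TestBuildTree:
    def test_methods_dispatch(self):
        aln = _separable_alignment(200)
        for method in ("nj", "upgma", "me"):
            t = build_tree(aln, DistanceModel("p"), method)
            assert set(t.leaf_names) == {"a", "b", "c", "d"}
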
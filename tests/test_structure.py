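"""AMOVA, neighbor joining, genealogical sorting index, Mantel test."""

import dendropy
import numpy as np
import pytest

from codiv.errors import ValidationError
from codiv.structure import (
    amova,
    expand_tips,
    gsi_test,
    mantel_test,
    midpoint_root,
    nj_tree,
)

# ---------------------------------------------------------------------------
# AMOVA


def brute_force_amova(dist, locales, region_of):
    """Independent nested-ANOVA oracle: explicit pair loops + linear solve."""
    d2 = np.asarray(dist, dtype=float) ** 2
    locales = list(locales)
    N = len(locales)
    loc_names = sorted(set(locales))
    reg_names = sorted({region_of[l] for l in loc_names})
    by_loc = {l: [i for i, x in enumerate(locales) if x == l] for l in loc_names}
    by_reg = {
        g: [i for i, x in enumerate(locales) if region_of[x] == g] for g in reg_names
    }

    def ssd(indices):
        total = 0.0
        for i in indices:
            for j in indices:
                total += d2[i, j]
        return total / (2.0 * len(indices))

    ssd_total = ssd(range(N))
    ssd_wp = sum(ssd(ix) for ix in by_loc.values())
    ssd_wg = sum(ssd(ix) for ix in by_reg.values())
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg
    P, G = len(loc_names), len(reg_names)
    sizes = {l: len(ix) for l, ix in by_loc.items()}
    Ng = {g: len(ix) for g, ix in by_reg.items()}
    sum_np2 = sum(n * n for n in sizes.values())
    sum_np2_g = sum(
        sum(sizes[l] ** 2 for l in loc_names if region_of[l] == g) / Ng[g]
        for g in reg_names
    )
    n1 = (N - sum_np2_g) / (P - G)
    n2 = (sum_np2_g - sum_np2 / N) / (G - 1)
    n3 = (N - sum(n * n for n in Ng.values()) / N) / (G - 1)
    ms = np.array([ssd_ag / (G - 1), ssd_ap / (P - G), ssd_wp / (N - P)])
    coeff = np.array([[n3, n2, 1.0], [0.0, n1, 1.0], [0.0, 0.0, 1.0]])
    sa, sb, sc = np.linalg.solve(coeff, ms)
    return (ssd_ag, ssd_ap, ssd_wp), (sa, sb, sc)


def _random_instance(rng, plan):
    locales = [l for l, n in plan for _ in range(n)]
    N = len(locales)
    d = rng.random((N, N)) * 3
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d, np.array(locales)


REGION_OF = {"K": "west", "C": "west", "L": "east", "A": "east", "T": "east"}


class TestAmova:
    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for plan in [
            [("K", 3), ("L", 3), ("A", 2)],
            [("K", 2), ("C", 3), ("L", 4)],
            [("K", 4), ("C", 2), ("L", 2), ("A", 2)],
        ]:
            d, locales = _random_instance(rng, plan)
            res = amova(d, locales, REGION_OF, B=9, seed=0)
            (ag, ap, wp), (sa, sb, sc) = brute_force_amova(d, locales, REGION_OF)
            assert res.ssd_among_regions == pytest.approx(ag, abs=1e-10)
            assert res.ssd_among_locales_within_regions == pytest.approx(ap, abs=1e-10)
            assert res.ssd_within_locales == pytest.approx(wp, abs=1e-10)
            assert res.sigma2_a == pytest.approx(sa, abs=1e-10)
            assert res.sigma2_b == pytest.approx(sb, abs=1e-10)
            assert res.sigma2_c == pytest.approx(sc, abs=1e-10)

    def test_ssd_additivity_is_exact(self, rng):
        d, locales = _random_instance(rng, [("K", 5), ("C", 3), ("L", 4), ("A", 2)])
        res = amova(d, locales, REGION_OF, B=9, seed=0)
        d2 = d**2
        total = d2.sum() / (2 * len(locales))
        assert (
            res.ssd_among_regions
            + res.ssd_among_locales_within_regions
            + res.ssd_within_locales
        ) == pytest.approx(total, abs=1e-10)

    def test_phi_st_one_for_fixed_differences(self):
        # two locales, one per region, internally identical, delta = 1 between
        d = np.zeros((6, 6))
        d[:3, 3:] = 1.0
        d[3:, :3] = 1.0
        locales = np.array(["K"] * 3 + ["L"] * 3)
        res = amova(d, locales, REGION_OF, B=99, seed=0)
        assert res.sigma2_c == pytest.approx(0.0, abs=1e-12)
        assert res.phi_st == pytest.approx(1.0)

    def test_phi_identity(self, rng):
        d, locales = _random_instance(rng, [("K", 4), ("C", 3), ("L", 4), ("A", 3)])
        res = amova(d, locales, REGION_OF, B=9, seed=1)
        tot = res.sigma2_a + res.sigma2_b + res.sigma2_c
        assert res.phi_st == pytest.approx((res.sigma2_a + res.sigma2_b) / tot)

    def test_haplotype_weighting_equals_individual_expansion(self, rng):
        hap_d = rng.random((4, 4)) * 2
        hap_d = (hap_d + hap_d.T) / 2
        np.fill_diagonal(hap_d, 0)
        hap_idx = np.array([0, 0, 1, 2, 2, 3, 3, 3, 1, 0])
        locales = np.array(["K"] * 3 + ["C"] * 3 + ["L"] * 4)
        expanded = hap_d[np.ix_(hap_idx, hap_idx)]
        res_h = amova(hap_d, locales, REGION_OF, B=49, seed=3, hap_idx=hap_idx)
        res_e = amova(expanded, locales, REGION_OF, B=49, seed=3)
        assert res_h.sigma2_a == pytest.approx(res_e.sigma2_a, abs=1e-12)
        assert res_h.phi_st == pytest.approx(res_e.phi_st, abs=1e-12)
        # permutation p may differ by a step or two where a permuted Phi ties
        # the observed value to within float error of the two code paths
        assert abs(res_h.p_st - res_e.p_st) <= 2 / (49 + 1)

    def test_seeded_determinism(self, rng):
        d, locales = _random_instance(rng, [("K", 4), ("C", 3), ("L", 5)])
        r1 = amova(d, locales, REGION_OF, B=199, seed=7)
        r2 = amova(d, locales, REGION_OF, B=199, seed=7)
        assert (r1.p_st, r1.p_sc, r1.p_ct) == (r2.p_st, r2.p_sc, r2.p_ct)

    def test_type_one_error_rates_panmictic(self, rng):
        # distances independent of labels: each Phi's rejection rate should
        # sit near alpha (exact binomial 95% band for 150 reps: ~[0.017, 0.09])
        reps, hits = 150, {"st": 0, "sc": 0, "ct": 0}
        for _ in range(reps):
            d, locales = _random_instance(
                rng, [("K", 4), ("C", 4), ("L", 4), ("A", 4), ("T", 4)]
            )
            res = amova(d, locales, REGION_OF, B=99, seed=rng)
            for key, p in [("st", res.p_st), ("sc", res.p_sc), ("ct", res.p_ct)]:
                if p is not None and p < 0.05:
                    hits[key] += 1
        for key in ("st", "sc"):
            assert 0.01 <= hits[key] / reps <= 0.11, (key, hits)
        # Phi_CT permutes whole locales (only 10 distinct splits of 5 locales
        # into 2+3), so its attainable p-values are coarse; just require it
        # not to be anticonservative
        assert hits["ct"] / reps <= 0.11


# ---------------------------------------------------------------------------
# neighbor joining


def _tip_path_lengths(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[i], taxa[j])
    return [t.label for t in taxa], out


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = nj_tree(["A", "B", "C"], d)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    @pytest.mark.parametrize("n_tips", [4, 6, 10])
    def test_recovers_random_additive_matrices(self, n_tips, rng):
        # build a random binary tree with positive branch lengths, take its
        # path-length matrix, and require NJ to reproduce it exactly
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
        ref = dendropy.simulate.treesim.pure_kingman_tree(
            taxon_namespace=taxa, pop_size=1, rng=__import__("random").Random(int(rng.integers(1 << 30)))
        )
        for edge in ref.preorder_edge_iter():
            if edge.length is not None:
                edge.length = float(rng.uniform(0.05, 1.0))
        labels, d = _tip_path_lengths(ref)
        tree = nj_tree(labels, d)
        labels2, d2 = _tip_path_lengths(tree)
        assert labels2 == labels
        assert np.allclose(d2, d, atol=1e-9)

    def test_agrees_with_skbio_on_additive_matrix(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(6)])
        ref = dendropy.simulate.treesim.pure_kingman_tree(
            taxon_namespace=taxa, pop_size=1, rng=__import__("random").Random(5)
        )
        for edge in ref.preorder_edge_iter():
            if edge.length is not None:
                edge.length = float(rng.uniform(0.1, 1.0))
        labels, d = _tip_path_lengths(ref)
        ours = nj_tree(labels, d)
        theirs = dendropy.Tree.get(
            data=str(skbio_nj(DistanceMatrix(d, labels))),
            schema="newick",
            taxon_namespace=ours.taxon_namespace,
        )
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        assert (
            dendropy.calculate.treecompare.symmetric_difference(ours, theirs) == 0
        )

    def test_equal_distances_resolve_deterministically(self):
        d = np.ones((5, 5)) - np.eye(5)
        t1 = nj_tree(list("ABCDE"), d)
        t2 = nj_tree(list("ABCDE"), d)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_fewer_than_three_tips_rejected(self):
        with pytest.raises(ValidationError):
            nj_tree(["A", "B"], np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# GSI


def _random_binary_tree(labels, rng):
    """Random sequential joins with random branch lengths."""
    nodes = [dendropy.Node(taxon=dendropy.Taxon(label=l)) for l in labels]
    for node in nodes:
        node.edge.length = float(rng.uniform(0.1, 1.0))
    active = list(nodes)
    while len(active) > 1:
        i = int(rng.integers(len(active)))
        a = active.pop(i)
        j = int(rng.integers(len(active)))
        b = active.pop(j)
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.1, 1.0))
        parent.add_child(a)
        parent.add_child(b)
        active.append(parent)
    tns = dendropy.TaxonNamespace([n.taxon for n in nodes])
    return dendropy.Tree(seed_node=active[0], taxon_namespace=tns)


def _caterpillar(labels):
    root = dendropy.Node()
    node = root
    taxa = []
    for k, label in enumerate(labels):
        taxon = dendropy.Taxon(label=label)
        taxa.append(taxon)
        tip = dendropy.Node(taxon=taxon)
        tip.edge.length = 1.0
        if k < len(labels) - 2:
            inner = dendropy.Node()
            inner.edge.length = 1.0
            node.add_child(tip)
            node.add_child(inner)
            node = inner
        elif k == len(labels) - 2:
            node.add_child(tip)
        else:
            node.add_child(tip)
    return dendropy.Tree(seed_node=root, taxon_namespace=dendropy.TaxonNamespace(taxa))


class TestGsi:
    def test_monophyletic_group_scores_one(self, rng):
        tree = _random_binary_tree([f"t{i}" for i in range(16)], rng)
        # pick a clade with >= 2 tips as the focal group
        for node in tree.postorder_internal_node_iter():
            tips = [l.taxon.label for l in node.leaf_iter()]
            if 3 <= len(tips) <= 8 and node.parent_node is not None:
                break
        groups = {l.taxon.label: ("in" if l.taxon.label in tips else "out")
                  for l in tree.leaf_node_iter()}
        res = gsi_test(tree, groups, "in", B=99, seed=1)
        assert res.gsi == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_maximally_dispersed_group_scores_zero(self):
        labels = [f"t{i}" for i in range(16)]
        tree = _caterpillar(labels)
        groups = {l: ("in" if i % 2 == 0 else "out") for i, l in enumerate(labels)}
        res = gsi_test(tree, groups, "in", B=99, seed=1)
        assert res.gsi == pytest.approx(0.0)

    def test_branch_length_invariance(self, rng):
        tree = _random_binary_tree([f"t{i}" for i in range(12)], rng)
        groups = {f"t{i}": ("in" if i < 6 else "out") for i in range(12)}
        base = gsi_test(tree, groups, "in", B=49, seed=9)
        perturbed = tree.clone(depth=1)
        for edge in perturbed.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * 7.7 + 0.1
        again = gsi_test(perturbed, groups, "in", B=49, seed=9)
        assert base.gsi == again.gsi
        assert base.p_value == again.p_value

    def test_random_labels_give_uniformish_p(self, rng):
        tree = _random_binary_tree([f"t{i}" for i in range(32)], rng)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        ps = []
        for _ in range(60):
            chosen = set(rng.choice(labels, size=10, replace=False))
            groups = {l: ("in" if l in chosen else "out") for l in labels}
            ps.append(gsi_test(tree, groups, "in", B=99, seed=rng).p_value)
        assert 0.3 < np.mean(ps) < 0.75

    def test_expand_tips_builds_individual_level_tree(self, rng):
        tree = _random_binary_tree(["h0", "h1", "h2"], rng)
        expanded = expand_tips(
            midpoint_root(tree), {"h0": ["h0_0", "h0_1", "h0_2"], "h1": ["h1_0"], "h2": ["h2_0", "h2_1"]}
        )
        labels = sorted(l.taxon.label for l in expanded.leaf_node_iter())
        assert labels == ["h0_0", "h0_1", "h0_2", "h1_0", "h2_0", "h2_1"]
        for node in expanded.preorder_internal_node_iter():
            assert len(node.child_nodes()) == 2

    def test_group_too_small_rejected(self, rng):
        tree = _random_binary_tree([f"t{i}" for i in range(6)], rng)
        groups = {f"t{i}": ("in" if i == 0 else "out") for i in range(6)}
        with pytest.raises(ValidationError):
            gsi_test(tree, groups, "in", B=9)


# ---------------------------------------------------------------------------
# Mantel


class TestMantel:
    def _geo(self, rng, k=5):
        m = rng.random((k, k)) * 100
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_identical_matrices_give_r_one(self, rng):
        geo = self._geo(rng)
        res = mantel_test(geo, geo, B=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        geo = self._geo(rng)
        gen = 3.0 * geo + 2.0
        np.fill_diagonal(gen, 0)
        res = mantel_test(gen, geo, B=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_p_uniform_under_independence(self, rng):
        from scipy import stats as sps

        ps = [
            mantel_test(self._geo(rng), self._geo(rng), B=99, seed=rng).p_value
            for _ in range(200)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_two_locales_rejected(self, rng):
        with pytest.raises(ValidationError):
            mantel_test(np.zeros((2, 2)), np.zeros((2, 2)), B=9)

    def test_agrees_with_skbio_r(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        gen, geo = self._geo(rng), self._geo(rng)
        ours = mantel_test(gen, geo, B=99, seed=0)
        r, _, _ = skbio_mantel(
            DistanceMatrix(gen), DistanceMatrix(geo), permutations=0, alternative="greater"
        )
        assert ours.r == pytest.approx(float(r))
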
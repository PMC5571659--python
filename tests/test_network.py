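import numpy as np
import pytest

import assocnet as an
from assocnet.genotypes import _r2_vectors
from assocnet.network import pmax_ld, inter_ld, build_network, key_nodes, allele_stacking

from conftest import make_matrix


def brute_force_inter_ld(members_a, members_b, G):
    """Independent double-loop implementation of the Inter-LD statistic."""

    def pmax(members):
        best = -np.inf
        for v in members:
            vals = [_r2_vectors(G.dosage(v), G.dosage(w)) for w in members]
            best = max(best, sum(vals) / len(vals))
        return best

    cross = np.mean(
        [_r2_vectors(G.dosage(a), G.dosage(b)) for a in members_a for b in members_b]
    )
    pa, pb = pmax(members_a), pmax(members_b)
    return 0.5 * (cross / pa + cross / pb), cross, pa, pb


def make_sal(G, idx, trait="t", tier="primary", min_p=1e-9):
    members = [G.ids[j] for j in idx]
    return an.Sal(
        trait, tier, members[0], members, G.variants[idx[0]].chrom,
        G.variants[idx[0]].pos, G.variants[idx[-1]].pos, min_p,
    )


@pytest.fixture(scope="module")
def ld_panel():
    return an.simulate_panel(
        an.PanelConfig(n_accessions=250, n_variants=120, n_chromosomes=3,
                       ld_block_length=4, seed=33)
    )


class TestPmaxLd:
    def test_single_member_is_one(self, ld_panel):
        s = make_sal(ld_panel, [0])
        assert pmax_ld(s, ld_panel) == pytest.approx(1.0)

    def test_two_member_hand_value(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 200).astype(float) * 2
        b = a.copy()
        flip = rng.random(200) < 0.15
        b[flip] = 2 - b[flip]
        G = make_matrix(np.column_stack([a, b]))
        r2 = _r2_vectors(a, b)
        s = make_sal(G, [0, 1])
        assert pmax_ld(s, G) == pytest.approx((1 + r2) / 2, abs=1e-12)

    def test_matches_bruteforce(self, ld_panel):
        s = make_sal(ld_panel, [4, 5, 6, 7])
        _, _, pa, _ = brute_force_inter_ld(s.members, s.members, ld_panel)
        assert pmax_ld(s, ld_panel) == pytest.approx(pa, abs=1e-12)

    def test_empty_rejected(self, ld_panel):
        s = make_sal(ld_panel, [0])
        s.members = []
        s.peak = None
        with pytest.raises(an.GenotypeError):
            pmax_ld(s, ld_panel)


class TestInterLd:
    def test_single_snp_collapse_to_r2(self, ld_panel):
        a = make_sal(ld_panel, [0])
        b = make_sal(ld_panel, [50])
        r2 = an.ld_r2(ld_panel, a.peak, b.peak).r2
        edge = inter_ld(a, b, ld_panel)
        assert edge.inter_ld == pytest.approx(r2, abs=1e-12)
        assert edge.pmax_a == pytest.approx(1.0) and edge.pmax_b == pytest.approx(1.0)

    def test_symmetry_and_component_identity(self, ld_panel):
        a = make_sal(ld_panel, [0, 1, 2])
        b = make_sal(ld_panel, [40, 41])
        e1 = inter_ld(a, b, ld_panel)
        e2 = inter_ld(b, a, ld_panel)
        assert e1.inter_ld == pytest.approx(e2.inter_ld, abs=1e-12)
        expect = 0.5 * (e1.cross_ld / e1.pmax_a + e1.cross_ld / e1.pmax_b)
        assert e1.inter_ld == pytest.approx(expect, abs=1e-12)

    def test_matches_bruteforce_on_random_pairs(self, ld_panel):
        rng = np.random.default_rng(2)
        for _ in range(100):
            i = rng.integers(0, ld_panel.n_variants - 3)
            j = rng.integers(0, ld_panel.n_variants - 3)
            a = make_sal(ld_panel, list(range(i, i + rng.integers(1, 4))))
            b = make_sal(ld_panel, list(range(j, j + rng.integers(1, 4))))
            edge = inter_ld(a, b, ld_panel)
            expect, cross, pa, pb = brute_force_inter_ld(a.members, b.members, ld_panel)
            assert edge.inter_ld == pytest.approx(expect, abs=1e-12)
            assert edge.cross_ld == pytest.approx(cross, abs=1e-12)

    def test_self_inter_ld_at_most_one(self, ld_panel):
        s = make_sal(ld_panel, [8, 9, 10, 11])
        edge = inter_ld(s, s, ld_panel)
        assert edge.inter_ld <= 1.0 + 1e-12


class TestNetwork:
    @pytest.fixture()
    def two_trait_sals(self, ld_panel):
        # the same locus found by two traits (overlapping intervals), plus an
        # unlinked locus for a third trait
        s1 = make_sal(ld_panel, [4, 5, 6], trait="PH", min_p=1e-10)
        s2 = make_sal(ld_panel, [5, 6, 7], trait="BBD", min_p=1e-8)
        s3 = make_sal(ld_panel, [80], trait="SW", min_p=1e-9)
        return [s1, s2, s3]

    def test_pleiotropic_merge(self, ld_panel, two_trait_sals):
        net = build_network(two_trait_sals, ld_panel, edge_min=0.4)
        sal_nodes = [n for n, d in net.nodes(data=True) if d.get("kind") == "sal"]
        merged = [
            n for n in sal_nodes
            if {t for t in net.neighbors(n) if net.nodes[t]["kind"] == "trait"}
            == {"PH", "BBD"}
        ]
        assert len(merged) == 1
        assert net.nodes[merged[0]]["score"] == pytest.approx(1e-10)

    def test_key_nodes_rank_pleiotropic_first(self, ld_panel, two_trait_sals):
        net = build_network(two_trait_sals, ld_panel, edge_min=0.4)
        keys = key_nodes(net, min_traits=2)
        assert len(keys) == 1
        assert set(net.neighbors(keys[0])) >= {"PH", "BBD"}

    def test_star_network_no_key_nodes(self, ld_panel):
        sals = [make_sal(ld_panel, [0], trait="A"), make_sal(ld_panel, [90], trait="B")]
        net = build_network(sals, ld_panel, edge_min=0.99)
        assert key_nodes(net, min_traits=2) == []

    def test_edge_min_monotone(self, ld_panel):
        sals = [
            make_sal(ld_panel, [0, 1], trait="A"),
            make_sal(ld_panel, [40, 41], trait="B"),
            make_sal(ld_panel, [80, 81], trait="C"),
        ]
        lo = build_network(sals, ld_panel, edge_min=0.0)
        hi = build_network(sals, ld_panel, edge_min=0.5)
        assert set(hi.edges) <= set(lo.edges)

    def test_input_order_invariance(self, ld_panel, two_trait_sals):
        n1 = build_network(two_trait_sals, ld_panel)
        n2 = build_network(two_trait_sals[::-1], ld_panel)
        assert set(n1.nodes) == set(n2.nodes)
        assert set(map(frozenset, n1.edges)) == set(map(frozenset, n2.edges))

    def test_exports(self, ld_panel, two_trait_sals, tmp_path):
        from assocnet.network import write_graphml, write_sif
        import networkx as nx

        net = build_network(two_trait_sals, ld_panel)
        gpath = tmp_path / "net.graphml"
        write_graphml(net, gpath)
        back = nx.read_graphml(gpath)
        assert back.number_of_nodes() == net.number_of_nodes()
        spath = tmp_path / "net.sif"
        write_sif(net, spath)
        assert len(spath.read_text().splitlines()) == net.number_of_edges()


class TestStacking:
    def test_single_locus_two_point_curve(self, ld_panel):
        g = ld_panel.dosage(ld_panel.ids[0])
        rng = np.random.default_rng(3)
        y = g + rng.standard_normal(g.size) * 0.1
        curve = allele_stacking(ld_panel, [(ld_panel.ids[0], "alt")], y)
        hom = g == 2
        other = ~hom
        assert curve.table.loc[1, "mean"] == pytest.approx(y[hom].mean())
        assert curve.table.loc[0, "mean"] == pytest.approx(y[other].mean())

    def test_additive_trait_increasing_curve(self, panel809):
        y, truth = an.simulate_additive_trait(
            panel809, 6, 0.6, effect_model="equal", seed=17
        )
        loci = [
            (vid, "alt" if b > 0 else "ref")
            for vid, b in zip(truth.causal_ids, truth.effects)
        ]
        curve = allele_stacking(panel809, loci, y)
        assert curve.slope > 0
        assert curve.slope_p < 0.01
        means = curve.table.dropna()["mean"]
        assert means.iloc[-1] > means.iloc[0]
        assert curve.table["n_accessions"].sum() == curve.n_used

    def test_shuffled_labels_flat_slope(self, panel809):
        rng = np.random.default_rng(4)
        y, truth = an.simulate_additive_trait(
            panel809, 6, 0.6, effect_model="equal", seed=17
        )
        tstats = []
        for s in range(20):
            loci = [
                (vid, rng.choice(["alt", "ref"]))
                for vid in rng.permutation(panel809.ids[:200])[:6]
            ]
            curve = allele_stacking(panel809, list(loci), y)
            if np.isfinite(curve.slope):
                tstats.append(curve.slope / curve.slope_se)
        assert np.mean(np.abs(np.array(tstats)) < 2.5) >= 0.8

    def test_empty_loci_rejected(self, ld_panel):
        with pytest.raises(an.GenotypeError):
            allele_stacking(ld_panel, [], np.zeros(ld_panel.n_accessions))
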
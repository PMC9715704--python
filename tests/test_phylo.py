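import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from ydna.core import MISSING
from ydna.phylo import (
    apply_bias_filter,
    build_perfect_phylogeny,
    four_gamete_test,
    reference_bias_screen,
    resolve_bundle,
    snp_missingness_filter,
)
from ydna.simulate import simulate_from_tree, simulate_star
from ydna.tree import HaplogroupTree

from conftest import mk_matrix


class TestFourGamete:
    def test_nested_carriers_compatible(self):
        m = mk_matrix([[1, 1], [1, 0], [0, 0], [0, 0]])
        assert four_gamete_test(0, 1, m) == "compatible"

    def test_all_four_gametes_incompatible(self):
        m = mk_matrix([[1, 1], [1, 0], [0, 1], [0, 0]])
        assert four_gamete_test(0, 1, m) == "incompatible"

    def test_no_overlapping_calls_indeterminate(self):
        m = mk_matrix([[1, MISSING], [MISSING, 1]])
        assert four_gamete_test(0, 1, m) == "indeterminate"

    def test_symmetric_in_site_order(self):
        m = mk_matrix([[1, 1], [1, 0], [0, 1], [0, 0]])
        assert four_gamete_test(0, 1, m) == four_gamete_test(1, 0, m)


class TestPerfectPhylogeny:
    def test_hand_derived_four_sample_tree(self):
        # sites: A carried by {0,1}, B by {0}, C by {2}; sample 3 unmutated
        m = mk_matrix(
            [[1, 1, 0], [1, 0, 0], [0, 0, 1], [0, 0, 0]],
            snp_names=["A", "B", "C"],
        )
        pp = build_perfect_phylogeny(m)
        assert len(pp.quarantined) == 0
        clades = pp.clades()
        assert clades == {frozenset({0, 1}), frozenset({0}), frozenset({2})}
        # B nests under A
        a_node = next(c for c in pp.root.children if c.snps == ["A"])
        assert [c.snps for c in a_node.children] == [["B"]]
        assert pp.n_root_branches == 3  # A-branch, C-branch, unmutated lineage
        assert pp.n_singleton_branches == 2

    def test_single_sample_single_edge(self):
        m = mk_matrix([[1, 1, 1]])
        pp = build_perfect_phylogeny(m)
        assert pp.n_root_branches == 1
        assert pp.clades() == {frozenset({0})}

    def test_star_fixture_census(self, rate):
        n = 12
        m, _ = simulate_star(n, 3000, rate, seed=4)
        pp = build_perfect_phylogeny(m)
        assert pp.n_root_branches == n
        assert pp.n_singleton_branches == n

    def test_incompatible_site_quarantined_with_bookkeeping(self):
        m = mk_matrix(
            [[1, 1, 1], [1, 0, 0], [0, 1, 0], [0, 0, 0]],
            snp_names=["A", "B", "X"],
        )
        # X={0} nests in A={0,1}; B={0,2} overlaps A without nesting
        pp = build_perfect_phylogeny(m)
        assert "B" in pp.quarantined["snp"].tolist() or "A" in pp.quarantined["snp"].tolist()
        assert len(pp.snp_edge) + len(pp.quarantined) == m.n_snps

    def test_matches_unique_solution_on_random_compatible_instances(self, df27_tree):
        """On fully compatible matrices the perfect phylogeny is unique: its
        clades must equal the observed carrier sets exactly (checked by an
        independent brute-force over the carrier-set family)."""
        rng = np.random.default_rng(0)
        for seed in range(10):
            counts = {n: int(rng.integers(0, 2)) for n in df27_tree.nodes}
            counts["DF27"] = 2
            m, _ = simulate_from_tree(df27_tree, counts, 1.0, seed=seed)
            pp = build_perfect_phylogeny(m)
            # tree SNPs of unsampled nodes have no carriers -> uninformative
            assert (pp.quarantined["reason"] == "no derived carriers").all()
            carrier_sets = set()
            for k in range(m.n_snps):
                c = frozenset(np.flatnonzero(m.calls[:, k] == 1).tolist())
                if c:
                    carrier_sets.add(c)
            # brute-force laminarity check (oracle for "a tree exists")
            for c1 in carrier_sets:
                for c2 in carrier_sets:
                    assert not c1 & c2 or c1 <= c2 or c2 <= c1
            assert pp.clades() == carrier_sets


class TestResolveBundle:
    def _bundle_tree(self):
        # parent P with bundle node B~ (nine SNPs) and named sibling S1
        nine = [
            "CTS6519.1", "CTS11567", "DF79", "DF81", "DF83",
            "DF84", "S453", "Z222", "S360",
        ]
        return (
            HaplogroupTree.from_dicts(
                [
                    {"name": "P", "parent": None},
                    {"name": "B", "parent": "P", "snps": nine, "bundle": True},
                    {"name": "S1", "parent": "P"},
                ]
            ),
            nine,
        )

    def test_nine_snp_bundle_resolves_to_four_basal_branches(self):
        tree, nine = self._bundle_tree()
        found = ["CTS6519.1", "CTS11567", "DF81", "Z222"]
        n = 10
        calls = np.zeros((n, len(nine) + 2), dtype=np.int8)
        names = nine + ["P", "S1"]
        calls[:, names.index("P")] = 1
        for i, snp in enumerate(found):
            calls[i, names.index(snp)] = 1  # one disjoint carrier each
        m = mk_matrix(calls, snp_names=names)
        rep = resolve_bundle(nine, m, tree)
        by = dict(zip(rep["snp"], rep["classification"]))
        for snp in found:
            assert by[snp] == "new basal branch"
        unresolved = [s for s in nine if s not in found]
        assert all(by[s] == "unresolved" for s in unresolved)
        assert len(unresolved) == 5

    def test_nested_carriers_form_chain_with_same_branch_pair(self, df27_tree):
        # carriers: Z205 > {Z208 = CTS8289} > CTS4299
        bundle = ["Z205", "Z208", "CTS8289", "CTS4299"]
        names = bundle + ["M167"]
        calls = np.zeros((6, 5), dtype=np.int8)
        calls[:, 4] = 1  # all derived at M167
        calls[0:4, 0] = 1  # Z205 carriers
        calls[0:2, 1] = 1  # Z208
        calls[0:2, 2] = 1  # CTS8289 (same branch)
        calls[0:1, 3] = 1  # CTS4299
        m = mk_matrix(calls, snp_names=names)
        tree = HaplogroupTree.from_dicts(
            [
                {"name": "M167", "parent": None},
                {"name": "B", "parent": "M167", "snps": bundle, "bundle": True},
            ]
        )
        rep = resolve_bundle(bundle, m, tree)
        by = dict(zip(rep["snp"], rep["classification"]))
        assert by["Z205"] == "chain position 1"
        assert by["Z208"] == "chain position 2"
        assert by["CTS8289"] == "chain position 2"
        assert by["CTS4299"] == "chain position 3"
        detail = dict(zip(rep["snp"], rep["detail"]))
        assert "CTS8289" in detail["Z208"]

    def test_identical_carriers_all_same_branch(self):
        tree = HaplogroupTree.from_dicts(
            [
                {"name": "P", "parent": None},
                {"name": "B", "parent": "P", "snps": ["x", "y", "z"], "bundle": True},
            ]
        )
        calls = np.zeros((4, 4), dtype=np.int8)
        calls[:, 3] = 1  # P
        calls[0:2, 0:3] = 1
        m = mk_matrix(calls, snp_names=["x", "y", "z", "P"])
        rep = resolve_bundle(["x", "y", "z"], m, tree)
        assert (rep["classification"] == "same-branch").all()
        assert all("same branch as" in d for d in rep["detail"])

    def test_conclusions_invariant_to_sample_and_snp_order(self, df27_tree):
        bundle = ["Z205", "Z208", "CTS8289", "CTS4299"]
        names = bundle + ["M167"]
        calls = np.zeros((6, 5), dtype=np.int8)
        calls[:, 4] = 1
        calls[0:4, 0] = 1
        calls[0:2, 1] = 1
        calls[0:2, 2] = 1
        calls[0:1, 3] = 1
        tree = HaplogroupTree.from_dicts(
            [
                {"name": "M167", "parent": None},
                {"name": "B", "parent": "M167", "snps": bundle, "bundle": True},
            ]
        )
        m1 = mk_matrix(calls, snp_names=names)
        rng = np.random.default_rng(3)
        perm = rng.permutation(6)
        m2 = mk_matrix(calls[perm], snp_names=names)
        r1 = resolve_bundle(bundle, m1, tree).set_index("snp")["classification"]
        r2 = resolve_bundle(bundle, m2, tree).set_index("snp")["classification"]
        assert r1.equals(r2)
        r3 = resolve_bundle(list(reversed(bundle)), m1, tree).set_index("snp")[
            "classification"
        ]
        assert r1.sort_index().equals(r3.sort_index())


class TestReferenceBias:
    def _platforms(self, n_cap, n_wgs):
        ids = [f"S{i}" for i in range(n_cap + n_wgs)]
        return ids, pd.Series(
            ["capture"] * n_cap + ["wgs"] * n_wgs, index=ids
        )

    def test_identical_rates_flag_nothing(self):
        ids, plat = self._platforms(20, 20)
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, size=(40, 30)).astype(np.int8)
        m = mk_matrix(calls, sample_ids=ids)
        rep = reference_bias_screen(m, plat)
        assert len(rep.fragments) == 0
        assert rep.n_snps_removed == 0

    def test_planted_fragment_flagged_and_p_matches_enumeration(self):
        """Capture derived rate 0.5 vs WGS 0.0 at n=80 vs 75: the Fisher p
        equals the hypergeometric tail computed independently."""
        ids, plat = self._platforms(80, 75)
        calls = np.zeros((155, 5), dtype=np.int8)
        calls[0:40, 2] = 1  # 40/80 capture derived at snp2; 0/75 wgs
        m = mk_matrix(calls, sample_ids=ids, positions=[100, 200, 300, 400, 500])
        rep = reference_bias_screen(m, plat)
        assert rep.flagged_snps == ["snp2"]
        assert len(rep.fragments) == 1
        p_fisher = rep.per_snp.set_index("snp").loc["snp2", "p"]
        # two-sided exact p by direct enumeration over the hypergeometric
        rv = hypergeom(155, 40, 80)
        probs = rv.pmf(np.arange(0, 41))
        p_enum = probs[probs <= rv.pmf(40) * (1 + 1e-9)].sum()
        assert p_fisher == pytest.approx(p_enum, rel=1e-6)

    def test_flagged_snps_removed_with_count_conservation(self):
        ids, plat = self._platforms(40, 40)
        calls = np.zeros((80, 6), dtype=np.int8)
        calls[0:40, 1] = 1
        calls[0:40, 2] = 1
        m = mk_matrix(calls, sample_ids=ids)
        rep = reference_bias_screen(m, plat)
        filtered = apply_bias_filter(m, rep)
        assert filtered.n_snps == m.n_snps - rep.n_snps_removed
        assert set(filtered.snp_names) | set(rep.flagged_snps) == set(m.snp_names)

    def test_single_platform_skips_screen(self):
        ids, plat = self._platforms(10, 0)
        m = mk_matrix(np.zeros((10, 3), dtype=np.int8), sample_ids=ids)
        rep = reference_bias_screen(m, plat)
        assert rep.n_snps_removed == 0

    def test_nearby_flagged_snps_merge_into_one_fragment(self):
        ids, plat = self._platforms(60, 60)
        calls = np.zeros((120, 4), dtype=np.int8)
        calls[0:60, 0] = 1
        calls[0:60, 1] = 1
        calls[0:60, 3] = 1
        m = mk_matrix(
            calls, sample_ids=ids, positions=[1000, 2000, 50_000, 100_000]
        )
        rep = reference_bias_screen(m, plat, merge_distance=5_000)
        assert len(rep.fragments) == 2
        assert rep.fragments.iloc[0]["n_snps"] == 2
        assert rep.bp_removed == (2000 - 1000 + 1) + 1


class TestMissingnessFilter:
    def test_boundary_exactly_five_percent_removed(self):
        n = 40
        calls = np.zeros((n, 2), dtype=np.int8)
        calls[0:2, 0] = MISSING  # 5.0% missing -> removed (strict)
        calls[0:1, 1] = MISSING  # 2.5% -> kept
        m = mk_matrix(calls)
        filtered, removed = snp_missingness_filter(m, 0.05)
        assert removed == ["snp0"]
        assert filtered.snp_names == ["snp1"]

    def test_complete_snp_kept(self):
        m = mk_matrix(np.zeros((10, 1), dtype=np.int8))
        filtered, removed = snp_missingness_filter(m)
        assert removed == []
        assert filtered.n_snps == 1

    def test_planted_high_missing_count_removed_exactly(self):
        rng = np.random.default_rng(1)
        n, m_snps, planted = 60, 500, 292
        calls = rng.integers(0, 2, size=(n, m_snps + planted)).astype(np.int8)
        bad = rng.choice(m_snps + planted, size=planted, replace=False)
        for j in bad:
            k = rng.integers(3, 10)
            calls[rng.choice(n, size=k, replace=False), j] = MISSING
        m = mk_matrix(calls)
        filtered, removed = snp_missingness_filter(m, 0.05)
        assert len(removed) == planted
        assert filtered.n_snps == m_snps
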
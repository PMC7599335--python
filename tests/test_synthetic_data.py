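"""Ground-truth generators: conservation, determinism, noise calibration."""

import math

import numpy as np
import pytest

from haloflux.composition import composition_stats
from haloflux.formats_io import species_tree_from_string
from haloflux.synthetic_data import (
    DtlParams,
    emit_rec_summaries,
    make_fusion_proteins,
    make_placement_scenarios,
    default_edge_taxonomy,
    random_protein_pool,
    random_species_tree,
    simulate_biased_alignment,
    simulate_dtl,
    split_singletons,
)


class TestSimulateDtl:
    def test_no_events_means_single_copy_everywhere(self, four_leaf_tree):
        params = DtlParams(p_dup=0, p_trans=0, p_loss=0, p_orig_root=1.0, n_families=5, seed=1)
        for h in simulate_dtl(four_leaf_tree, params):
            assert h.origin_node == "root"
            assert all(h.copies.get(b, 0) == 1 for b in four_leaf_tree.nodes)
            assert h.extant_leaves(four_leaf_tree) == {"A", "B", "C", "D"}

    def test_leaf_absence_rate_matches_binomial(self):
        tree = species_tree_from_string("(A,B)root;")
        params = DtlParams(
            p_dup=0, p_trans=0, p_loss=0.5, p_orig_root=1.0, n_families=1000, seed=2
        )
        hists = simulate_dtl(tree, params)
        absent = sum(1 for h in hists if h.copies.get("A", 0) == 0)
        se = math.sqrt(0.5 * 0.5 / 1000)
        assert abs(absent / 1000 - 0.5) <= 3 * se

    def test_same_seed_identical_histories(self):
        tree = random_species_tree(8, 3)
        params = DtlParams(n_families=20, seed=42)
        a = simulate_dtl(tree, params)
        b = simulate_dtl(tree, params)
        for ha, hb in zip(a, b):
            assert ha == hb

    def test_conservation_exact_on_all_branches(self):
        tree = random_species_tree(12, 5)
        for h in simulate_dtl(tree, DtlParams(n_families=100, seed=6, p_trans=0.08)):
            h.check_conservation(tree)

    def test_transfers_land_outside_donor_subtree(self):
        tree = random_species_tree(10, 7)
        hists = simulate_dtl(
            tree, DtlParams(n_families=100, seed=8, p_trans=0.15, p_loss=0.05)
        )
        seen = 0
        for h in hists:
            for (donor, recipient), c in h.transfer_pairs.items():
                seen += c
                assert recipient not in tree.subtree_ids(donor)
                assert recipient != tree.root_id
        assert seen > 0

    def test_non_binary_tree_rejected(self):
        from haloflux.formats_io import SpeciesTree, SpeciesTreeNode

        nodes = {
            "r": SpeciesTreeNode("r", None, ("a", "b", "c"), False),
            "a": SpeciesTreeNode("a", "r", (), True, "a"),
            "b": SpeciesTreeNode("b", "r", (), True, "b"),
            "c": SpeciesTreeNode("c", "r", (), True, "c"),
        }
        tree = SpeciesTree(nodes=nodes, root_id="r")
        with pytest.raises(ValueError):
            simulate_dtl(tree, DtlParams(n_families=1, seed=0))

    def test_split_singletons_detects_leaf_only_families(self, four_leaf_tree):
        params = DtlParams(p_dup=0, p_trans=0, p_loss=0, p_orig_root=0.0, n_families=50, seed=9)
        hists = simulate_dtl(four_leaf_tree, params)
        rest, singles = split_singletons(hists, four_leaf_tree)
        for fam, leaf in singles.items():
            assert four_leaf_tree.nodes[leaf].is_leaf
        # families originating at internal nodes are never singletons
        for h in rest:
            assert not (
                four_leaf_tree.nodes[h.origin_node].is_leaf and h.copies == {h.origin_node: 1}
            )


class TestEmitRecSummaries:
    def test_perturb_zero_gives_exact_multiplicities(self):
        tree = random_species_tree(8, 11)
        hists = simulate_dtl(tree, DtlParams(n_families=30, seed=12, p_dup=0.1))
        for h, s in zip(hists, emit_rec_summaries(hists, tree, 50, 0.0, seed=13)):
            for b, row in s.branch_rows.items():
                assert row.duplications == h.duplications[b]
                assert row.losses == h.losses[b]
                assert row.originations == h.originations[b]
                assert row.copies == h.copies.get(b, 0)

    def test_perturbation_keeps_frequencies_near_truth(self):
        tree = random_species_tree(8, 14)
        hists = simulate_dtl(tree, DtlParams(n_families=50, seed=15))
        summaries = emit_rec_summaries(hists, tree, r_samples=100, perturb=0.2, seed=16)
        true_freqs, spurious = [], []
        for h, s in zip(hists, summaries):
            for b, row in s.branch_rows.items():
                for attr, counter in (
                    ("duplications", h.duplications),
                    ("losses", h.losses),
                    ("originations", h.originations),
                ):
                    f = getattr(row, attr)
                    if counter[b] > 0:
                        true_freqs.append(f / counter[b])
                    elif f > 0:
                        spurious.append(f)
        assert np.mean(true_freqs) >= 0.8 - 0.05
        assert all(f <= 0.2 + 0.1 for f in spurious)

    def test_transfer_pairs_consistent_with_marginals(self):
        tree = random_species_tree(8, 17)
        hists = simulate_dtl(tree, DtlParams(n_families=40, seed=18, p_trans=0.1))
        for s in emit_rec_summaries(hists, tree, 30, 0.3, seed=19):
            s.validate(tree)  # includes the pair-sum == marginal-sum invariant

    def test_zero_samples_rejected(self, four_leaf_tree):
        with pytest.raises(ValueError):
            emit_rec_summaries([], four_leaf_tree, r_samples=0)

    def test_deterministic_and_writes_manifest(self, tmp_path):
        tree = random_species_tree(6, 20)
        hists = simulate_dtl(tree, DtlParams(n_families=5, seed=21))
        a = emit_rec_summaries(hists, tree, 20, 0.3, seed=22, out_dir=tmp_path / "a")
        b = emit_rec_summaries(hists, tree, 20, 0.3, seed=22, out_dir=tmp_path / "b")
        assert a == b
        assert (tmp_path / "a" / "manifest.json").exists()
        fa = sorted(p.name for p in (tmp_path / "a").glob("*.rec.tsv"))
        for name in fa:
            assert (tmp_path / "a" / name).read_text() == (tmp_path / "b" / name).read_text()


class TestBiasedAlignment:
    def test_zero_fraction_nearly_homogeneous(self):
        aln, planted = simulate_biased_alignment(6, 300, 0.0, 5.0, seed=23)
        assert planted == []
        table = composition_stats(aln)
        # chi2 ~ chi-square with 19 dof under homogeneity; stay well below planted-bias levels
        assert table.chi2.mean() < 60

    def test_strong_bias_separates_planted_sites(self):
        from haloflux.composition import rank_heterogeneous_sites

        aln, planted = simulate_biased_alignment(8, 200, 0.2, 8.0, seed=24)
        top = set(rank_heterogeneous_sites(aln, "single_pass")[: len(planted)])
        assert len(top & set(planted)) / len(planted) >= 0.9

    def test_fixed_seed_reproducible(self):
        a1, p1 = simulate_biased_alignment(5, 50, 0.3, 4.0, seed=25)
        a2, p2 = simulate_biased_alignment(5, 50, 0.3, 4.0, seed=25)
        assert a1.rows == a2.rows and p1 == p2

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_biased_alignment(5, 50, 1.5, 2.0, seed=0)


class TestFusionGenerator:
    def test_concatenation_arithmetic(self):
        pa = {"a1": "M" * 300}
        pb = {"b1": "W" * 150}
        proteins, truths, hits = make_fusion_proteins(pa, pb, 1, seed=0, jitter=0)
        t = truths[0]
        assert t.breakpoint == 300
        assert t.region_a == (1, 300) and t.region_b == (301, 450)
        assert len(proteins[t.protein]) == 450
        assert {(h.cog, h.start, h.end) for h in hits} == {
            ("COG1009", 1, 300),
            ("COG2111", 301, 450),
        }

    def test_jitter_bounded(self):
        pa = random_protein_pool(3, (200, 300), 1)
        pb = random_protein_pool(3, (100, 200), 2)
        _, truths, hits = make_fusion_proteins(pa, pb, 30, seed=3, jitter=5)
        by_protein = {}
        for h in hits:
            by_protein.setdefault(h.protein, []).append(h)
        for t in truths:
            a = next(h for h in by_protein[t.protein] if h.cog == t.cog_a)
            b = next(h for h in by_protein[t.protein] if h.cog == t.cog_b)
            assert abs(a.end - t.breakpoint) <= 5
            assert abs(b.start - (t.breakpoint + 1)) <= 5

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            make_fusion_proteins({"a": "MA"}, {"b": "WC"}, 0)


class TestPlacementScenarios:
    def test_noise_split_keeps_donor_argmax(self):
        tax = {
            "e1": ("root", "X"),
            "e2": ("root", "Y"),
            "e3": ("root", "Z"),
        }
        scenarios = make_placement_scenarios(tax, 1, ["X"], noise=0.4, seed=1)
        plist = scenarios[0].profile.placements["orig0000_s0"]
        best = max(plist, key=lambda p: p.like_weight_ratio)
        assert best.edge_id == "e1"
        assert best.like_weight_ratio == pytest.approx(0.6)
        others = [p.like_weight_ratio for p in plist if p.edge_id != "e1"]
        assert others == pytest.approx([0.2, 0.2])

    def test_de_novo_family_has_no_profile(self):
        scenarios = make_placement_scenarios(default_edge_taxonomy(), 2, ["TACK", None], seed=2)
        assert scenarios[1].profile is None
        assert scenarios[1].donor_label is None

    def test_noise_one_rejected(self):
        with pytest.raises(ValueError):
            make_placement_scenarios(default_edge_taxonomy(), 1, ["TACK"], noise=1.0)
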
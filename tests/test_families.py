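"""Single-linkage clustering, fusion detection and region splitting."""

import numpy as np
import pytest

from haloflux.families import (
    PairwiseHit,
    RegionHit,
    cluster_single_linkage,
    detect_fusion_clusters,
    naive_profile_scan,
    read_domtblout,
    resolve_regions,
    split_family,
)
from haloflux.synthetic_data import make_fusion_proteins, random_protein_pool


def bruteforce_components(hits, min_ident, min_overlap):
    """Independent oracle: adjacency lists + breadth-first search."""
    adj: dict[str, set[str]] = {}
    for h in hits:
        adj.setdefault(h.query, set())
        adj.setdefault(h.subject, set())
        if h.identity >= min_ident and h.overlap >= min_overlap:
            adj[h.query].add(h.subject)
            adj[h.subject].add(h.query)
    seen: set[str] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        comp = set()
        queue = [start]
        while queue:
            v = queue.pop()
            if v in comp:
                continue
            comp.add(v)
            queue.extend(adj[v] - comp)
        seen |= comp
        comps.append(comp)
    return sorted(comps, key=min)


class TestClustering:
    def test_transitive_chain_merges(self):
        hits = [PairwiseHit("A", "B", 0.7, 0.95), PairwiseHit("B", "C", 0.65, 0.92)]
        assert cluster_single_linkage(hits, 0.6, 0.9) == [{"A", "B", "C"}]

    def test_below_identity_threshold_splits(self):
        hits = [PairwiseHit("A", "B", 0.55, 0.95)]
        assert cluster_single_linkage(hits, 0.6, 0.9) == [{"A"}, {"B"}]

    @pytest.mark.parametrize(
        "ident,overlap,merged",
        [(0.6, 0.9, True), (0.6, 0.89, False), (0.59, 0.9, False), (0.61, 0.91, True)],
    )
    def test_thresholds_are_inclusive(self, ident, overlap, merged):
        hits = [PairwiseHit("A", "B", ident, overlap)]
        comps = cluster_single_linkage(hits, 0.6, 0.9)
        assert (comps == [{"A", "B"}]) is merged

    def test_empty_hit_list(self):
        assert cluster_single_linkage([]) == []

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        proteins = [f"p{i}" for i in range(n)]
        hits = []
        for _ in range(int(rng.integers(1, 25))):
            i, j = rng.integers(n, size=2)
            if i == j:
                continue
            # mix in exact boundary values to probe the >= semantics
            ident = float(rng.choice([0.6, 0.9, rng.random()]))
            overlap = float(rng.choice([0.9, 0.6, rng.random()]))
            hits.append(PairwiseHit(proteins[i], proteins[j], ident, overlap))
        assert cluster_single_linkage(hits, 0.6, 0.9) == bruteforce_components(
            hits, 0.6, 0.9
        )


class TestFusionDetection:
    def test_multi_cog_member_flags_family(self):
        annotations = {"P1": {"COG1009", "COG2111"}, "P2": {"COG1009"}}
        assert detect_fusion_clusters(annotations, {"F": ["P1", "P2"]}) == {"F"}

    def test_single_cog_members_not_flagged(self):
        annotations = {"P1": {"COG1"}, "P2": {"COG2"}}
        assert detect_fusion_clusters(annotations, {"F": ["P1", "P2"]}) == set()

    def test_three_cogs_flagged(self):
        annotations = {"P1": {"COG1", "COG2", "COG3"}}
        assert detect_fusion_clusters(annotations, {"F": ["P1"]}) == {"F"}

    def test_unannotated_member_is_empty_set(self):
        assert detect_fusion_clusters({}, {"F": ["P1"]}) == set()


class TestResolveRegions:
    def test_lower_scoring_region_trimmed(self):
        hits = [
            RegionHit("P", "COG1", 10, 110, 50.0),
            RegionHit("P", "COG2", 90, 200, 30.0),
        ]
        out = resolve_regions(hits)
        assert [(h.cog, h.start, h.end) for h in out] == [
            ("COG1", 10, 110),
            ("COG2", 111, 200),
        ]

    def test_contained_region_discarded(self):
        hits = [
            RegionHit("P", "COG1", 10, 110, 50.0),
            RegionHit("P", "COG2", 20, 105, 30.0),
        ]
        out = resolve_regions(hits)
        assert [(h.cog, h.start, h.end) for h in out] == [("COG1", 10, 110)]

    def test_disjoint_hits_returned_sorted(self):
        hits = [
            RegionHit("P", "COG2", 200, 300, 20.0),
            RegionHit("P", "COG1", 10, 100, 50.0),
        ]
        out = resolve_regions(hits)
        assert [h.start for h in out] == [10, 200]
        assert [(h.start, h.end) for h in out] == [(10, 100), (200, 300)]

    def test_thirty_percent_retention_boundary(self):
        # remaining 30 of 100 residues: exactly 30% is kept, 29% is not
        kept = resolve_regions(
            [RegionHit("P", "A", 1, 100, 50.0), RegionHit("P", "B", 31, 130, 30.0)]
        )
        assert ("B", 101, 130) in [(h.cog, h.start, h.end) for h in kept]
        dropped = resolve_regions(
            [RegionHit("P", "A", 1, 100, 50.0), RegionHit("P", "B", 30, 129, 30.0)]
        )
        assert [h.cog for h in dropped] == ["A"]

    def test_output_disjoint_and_retention_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            hits = []
            for k in range(int(rng.integers(2, 6))):
                s = int(rng.integers(1, 300))
                e = s + int(rng.integers(20, 150))
                hits.append(RegionHit("P", f"COG{k}", s, e, float(rng.random() * 100)))
            out = resolve_regions(hits)
            intervals = sorted((h.start, h.end) for h in out)
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 < s2
            originals = {h.cog: h.length for h in hits}
            for h in out:
                assert h.length >= 0.3 * originals[h.cog] - 1e-9

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            RegionHit("P", "COG1", 10, 5, 1.0)

    def test_hits_on_multiple_proteins_rejected(self):
        with pytest.raises(ValueError):
            resolve_regions(
                [RegionHit("P1", "A", 1, 10, 1.0), RegionHit("P2", "A", 1, 10, 1.0)]
            )


class TestSplitFamily:
    def test_split_into_per_cog_families(self):
        resolved = {
            "P1": [
                RegionHit("P1", "COG1009", 1, 300, 50.0),
                RegionHit("P1", "COG2111", 301, 450, 40.0),
            ]
        }
        parts = split_family("0KS6Y", ["P1"], resolved)
        names = {p.family_id: p.members for p in parts}
        assert names["0KS6Y_COG1009"] == [("P1", 1, 300)]
        assert names["0KS6Y_COG2111"] == [("P1", 301, 450)]

    def test_two_same_cog_regions_become_two_members(self):
        resolved = {
            "P2": [
                RegionHit("P2", "COG1009", 1, 100, 50.0),
                RegionHit("P2", "COG1009", 150, 260, 45.0),
            ]
        }
        parts = split_family("F", ["P2"], resolved)
        assert [p.family_id for p in parts] == ["F_COG1009"]
        assert len(parts[0].members) == 2

    def test_member_without_region_goes_to_rest(self):
        resolved = {"P1": [RegionHit("P1", "COG1", 1, 100, 10.0)]}
        parts = split_family("F", ["P1", "P3"], resolved, sequences={"P3": "M" * 80})
        rest = [p for p in parts if p.residual]
        assert len(rest) == 1
        assert rest[0].family_id == "F_rest"
        assert rest[0].members == [("P3", 1, 80)]

    def test_no_resolved_regions_rejected(self):
        with pytest.raises(ValueError):
            split_family("F", ["P1"], {})

    def test_no_residue_shared_between_cog_families(self):
        pool_a = random_protein_pool(4, (150, 250), 1)
        pool_b = random_protein_pool(4, (100, 200), 2)
        proteins, truths, hits = make_fusion_proteins(pool_a, pool_b, 20, seed=3, jitter=5)
        by_protein: dict[str, list[RegionHit]] = {}
        for h in hits:
            by_protein.setdefault(h.protein, []).append(h)
        resolved = {p: resolve_regions(hl) for p, hl in by_protein.items()}
        parts = split_family("F", list(proteins), resolved, sequences=proteins)
        used: dict[str, set[int]] = {}
        for p in parts:
            for protein, s, e in p.members:
                assert 1 <= s <= e <= len(proteins[protein])
                span = set(range(s, e + 1))
                assert not (used.get(protein, set()) & span)
                used.setdefault(protein, set()).update(span)

    @pytest.mark.parametrize("jitter", [0, 5])
    def test_breakpoint_recovery(self, jitter):
        pool_a = random_protein_pool(5, (200, 400), 11)
        pool_b = random_protein_pool(5, (100, 250), 12)
        proteins, truths, hits = make_fusion_proteins(
            pool_a, pool_b, 50, seed=13, jitter=jitter
        )
        by_protein: dict[str, list[RegionHit]] = {}
        for h in hits:
            by_protein.setdefault(h.protein, []).append(h)
        ok = 0
        for t in truths:
            out = resolve_regions(by_protein[t.protein])
            a = [h for h in out if h.cog == t.cog_a]
            b = [h for h in out if h.cog == t.cog_b]
            if (
                a
                and b
                and abs(a[0].end - t.breakpoint) <= jitter
                and abs(b[0].start - (t.breakpoint + 1)) <= jitter
            ):
                ok += 1
        assert ok / len(truths) >= 0.95


class TestProfileInput:
    DOMTBL = (
        "# comment line\n"
        "P1 - 450 COG1009 - 320 1e-50 210.0 1.1 1 2 1e-48 1e-45 180.5 0.9 "
        "5 310 10 300 8 305 0.95 description here\n"
    )

    def test_read_domtblout_fields(self, tmp_path):
        p = tmp_path / "hits.domtbl"
        p.write_text(self.DOMTBL, encoding="utf-8")
        hits = read_domtblout(p)
        assert len(hits) == 1
        h = hits[0]
        assert (h.protein, h.cog) == ("P1", "COG1009")
        assert (h.start, h.end) == (10, 300)
        assert h.score == pytest.approx(180.5)  # per-domain bit score

    def test_naive_scan_finds_planted_motif(self):
        rng = np.random.default_rng(5)
        motif = "WWWHHHWWW"
        background = {a: 0.05 for a in "ACDEFGHIKLMNPQRSTVWY"}
        profile = [{ch: 0.9} for ch in motif]
        seq = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[k] for k in rng.integers(0, 20, size=60)
        )
        seq = seq[:25] + motif + seq[25:]
        hit = naive_profile_scan(seq, profile, background)
        assert (hit.start, hit.end) == (26, 26 + len(motif) - 1)
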
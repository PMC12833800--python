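import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bundlemine.bundler import (
    BundlingParams,
    build_initial_clusters,
    bundle_genome,
    cluster_ordinals,
    interspersed_genes,
    merge_clusters,
)
from bundlemine.errors import ValidationError
from bundlemine.motif_filter import DomainHit

from conftest import make_genome
from oracles import brute_force_two_stage


def hit(gene_id, motif="p450", passed=True):
    return DomainHit(gene_id, motif, 50.0, 1e-20, passed)


ordinal_sets = st.lists(
    st.integers(min_value=0, max_value=40), min_size=0, max_size=12, unique=True
).map(sorted)


class TestStage1:
    def test_gap_exceeding_g1_splits_and_min_core_drops_singletons(self):
        params = BundlingParams(g1=5, g2=20, min_core=2)
        # 2 -> 9 has 6 intervening genes (> g1); lone {9} is not a bundle
        assert build_initial_clusters([1, 2, 9], params) == [(1, 2)]

    def test_contiguous_genes_form_one_cluster(self):
        assert build_initial_clusters([0, 1, 2, 3], BundlingParams(g1=0)) == [(0, 1, 2, 3)]

    def test_exact_gap_boundary_is_inclusive(self):
        # gaps of exactly 1 intervening gene with g1=1
        assert build_initial_clusters([3, 5, 7], BundlingParams(g1=1, g2=1)) == [(3, 5, 7)]

    def test_unsorted_or_duplicate_ordinals_rejected(self):
        with pytest.raises(ValidationError):
            cluster_ordinals([5, 3], 2)
        with pytest.raises(ValidationError):
            cluster_ordinals([3, 3], 2)


class TestStage2:
    def test_broadly_spaced_clusters_merge_within_g2(self):
        clusters = [(1, 2, 3, 4), (20, 21, 25)]
        # ordinals 5..19 -> 15 intervening genes
        assert merge_clusters(clusters, BundlingParams(g2=20)) == [(1, 2, 3, 4, 20, 21, 25)]
        assert merge_clusters(clusters, BundlingParams(g2=10)) == clusters

    def test_merge_is_transitive_and_idempotent(self):
        clusters = [(0, 1), (10, 11), (20, 21)]
        merged = merge_clusters(clusters, BundlingParams(g2=8))
        assert merged == [(0, 1, 10, 11, 20, 21)]
        assert merge_clusters(merged, BundlingParams(g2=8)) == merged

    def test_overlapping_clusters_rejected(self):
        with pytest.raises(ValidationError):
            merge_clusters([(0, 5), (3, 8)], BundlingParams())


class TestOracleEquivalence:
    @given(
        ordinals=ordinal_sets,
        g1=st.integers(min_value=0, max_value=6),
        extra=st.integers(min_value=0, max_value=20),
        min_core=st.integers(min_value=1, max_value=3),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_two_stage_matches_brute_force_partition(self, ordinals, g1, extra, min_core):
        params = BundlingParams(g1=g1, g2=g1 + extra, min_core=min_core)
        ours = merge_clusters(build_initial_clusters(ordinals, params), params)
        assert ours == brute_force_two_stage(ordinals, params.g1, params.g2, params.min_core)

    @given(
        ordinals=ordinal_sets,
        g_small=st.integers(min_value=0, max_value=5),
        bump=st.integers(min_value=0, max_value=5),
        min_core=st.integers(min_value=1, max_value=3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_widening_gaps_coarsens_bundles(self, ordinals, g_small, bump, min_core):
        """Every bundle at tighter gaps lies inside exactly one bundle at wider
        gaps, and no gene ever loses bundle membership.  (The raw bundle
        *count* is only monotone when min_core=1: with min_core>1, widening
        can promote previously discarded singletons into a new bundle.)"""
        small = BundlingParams(g1=g_small, g2=g_small + 10, min_core=min_core)
        big = BundlingParams(g1=g_small + bump, g2=g_small + bump + 10, min_core=min_core)
        fine = merge_clusters(build_initial_clusters(ordinals, small), small)
        coarse = merge_clusters(build_initial_clusters(ordinals, big), big)
        for b in fine:
            assert sum(1 for c in coarse if set(b) <= set(c)) == 1
        covered_fine = {o for b in fine for o in b}
        covered_coarse = {o for b in coarse for o in b}
        assert covered_fine <= covered_coarse
        if min_core == 1:
            assert len(coarse) <= len(fine)


def spaced_genome(flagged_slots, n=40, motifs=None):
    genes = [("s1", 100 * i + 1, 100 * i + 50, f"g{i}") for i in range(n)]
    genome = make_genome("G", genes, {f"g{i}": "MKVLA" for i in range(n)})
    hits = [
        hit(f"g{s}", motif=(motifs or {}).get(s, "p450")) for s in flagged_slots
    ]
    return genome, hits


class TestBundleGenome:
    def test_no_flagged_genes_yields_no_bundles(self):
        genome, _ = spaced_genome([])
        assert bundle_genome(genome, [], BundlingParams()) == []

    def test_split_bundle_recovered_only_after_stage_two(self):
        # two tight pairs separated by 19 intervening genes
        genome, hits = spaced_genome([0, 2, 22, 24])
        params = BundlingParams(g1=5, g2=20)
        assert build_initial_clusters([0, 2, 22, 24], params) == [(0, 2), (22, 24)]
        bundles = bundle_genome(genome, hits, params)
        assert len(bundles) == 1
        assert bundles[0].stage == "merged"
        assert bundles[0].core_genes == ("g0", "g2", "g22", "g24")

    def test_scaffold_boundary_never_crossed(self):
        genes = [("s1", 10, 20, "a"), ("s1", 30, 40, "b"), ("s2", 10, 20, "c"), ("s2", 30, 40, "d")]
        genome = make_genome("G", genes, {g: "MKVLA" for g in "abcd"})
        bundles = bundle_genome(genome, [hit(g) for g in "abcd"], BundlingParams(g2=10**6))
        assert sorted((b.scaffold_id, b.core_genes) for b in bundles) == [
            ("s1", ("a", "b")),
            ("s2", ("c", "d")),
        ]

    def test_signature_is_union_of_passed_motifs_and_counts_multiset(self):
        genome, hits = spaced_genome([0, 1, 2], motifs={0: "p450", 1: "p450", 2: "mtase"})
        hits.append(hit("g2", motif="failed_motif", passed=False))
        (b,) = bundle_genome(genome, hits, BundlingParams())
        assert b.domain_signature == frozenset({"p450", "mtase"})
        assert dict(b.domain_counts) == {"p450": 2, "mtase": 1}

    def test_hits_for_unknown_genes_rejected(self):
        genome, _ = spaced_genome([0])
        with pytest.raises(ValidationError, match="phantom"):
            bundle_genome(genome, [hit("phantom")], BundlingParams())

    def test_bundle_ids_and_spans_follow_scaffold_order(self):
        genome, hits = spaced_genome([3, 4, 30, 31])
        bundles = bundle_genome(genome, hits, BundlingParams(g1=5, g2=10))
        assert [b.bundle_id for b in bundles] == ["G.s1.b0", "G.s1.b1"]
        assert bundles[0].span == (3, 4)
        assert bundles[0].bp_span == (301, 450)

    def test_interspersed_genes_listed_but_not_in_signature(self):
        genome, hits = spaced_genome([5, 9])
        (b,) = bundle_genome(genome, hits, BundlingParams(g1=5))
        rows = interspersed_genes(genome, [b])
        assert [r["gene_id"] for r in rows] == ["g6", "g7", "g8"]
        assert b.domain_signature == frozenset({"p450"})

    def test_permutation_invariance_of_hit_order(self, rng):
        genome, hits = spaced_genome([0, 2, 4, 20, 22], motifs={0: "a", 2: "b", 4: "c"})
        shuffled = hits[:]
        rng.shuffle(shuffled)
        assert bundle_genome(genome, hits, BundlingParams()) == bundle_genome(
            genome, shuffled, BundlingParams()
        )
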
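import filecmp
import json

import pytest

from bundlemine.bundler import BundlingParams, bundle_genome
from bundlemine.errors import ConfigurationError
from bundlemine.genome_io import load_genome
from bundlemine.motif_filter import MotifLibrary, flag_genes, flagged_gene_ids
from bundlemine.synthetic import (
    FixtureConfig,
    PlantedBundle,
    generate_fixture,
)


def small_config(seed=0, **kw):
    defaults = dict(
        n_producers=3,
        n_nonproducers=2,
        genes_per_scaffold=100,
        scaffolds_per_genome=2,
        seed=seed,
    )
    defaults.update(kw)
    return FixtureConfig(**defaults)


def load_and_flag(fixture, gid, matcher="builtin_kmer"):
    files = fixture.genome_files[gid]
    table = load_genome(files["gff3"], files["fasta"], genome_id=gid)
    if matcher == "builtin_kmer":
        lib = MotifLibrary.from_fasta(fixture.motif_fasta)
        hits = flag_genes(table, lib)
    else:
        lib = MotifLibrary(MotifLibrary.from_fasta(fixture.motif_fasta).motifs, "table")
        hits = flag_genes(table, lib, hits_table=files["hits"])
    return table, hits


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        fx1 = generate_fixture(small_config(seed=5), tmp_path / "a")
        fx2 = generate_fixture(small_config(seed=5), tmp_path / "b")
        names = sorted(p.name for p in fx1.root.iterdir())
        assert names == sorted(p.name for p in fx2.root.iterdir())
        for name in names:
            assert filecmp.cmp(fx1.root / name, fx2.root / name, shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        fx1 = generate_fixture(small_config(seed=5), tmp_path / "a")
        fx2 = generate_fixture(small_config(seed=6), tmp_path / "b")
        assert (fx1.root / "P1.gff3").read_text() != (fx2.root / "P1.gff3").read_text()


class TestManifestAgreement:
    def test_flagged_set_equals_manifest_for_both_matchers(self, tmp_path):
        fixture = generate_fixture(small_config(seed=2), tmp_path / "fx")
        for gid, entry in fixture.manifest["genomes"].items():
            expected = {
                g for p in entry["planted"] for g in p["gene_ids"]
            } | {d["gene_id"] for d in entry["decoys"]}
            for matcher in ("builtin_kmer", "table"):
                _, hits = load_and_flag(fixture, gid, matcher)
                assert flagged_gene_ids(hits) == expected, (gid, matcher)

    def test_planted_bundles_recovered_exactly(self, tmp_path):
        fixture = generate_fixture(small_config(seed=3), tmp_path / "fx")
        params = BundlingParams()
        for gid, entry in fixture.manifest["genomes"].items():
            table, hits = load_and_flag(fixture, gid)
            bundles = bundle_genome(table, hits, params)
            got = {frozenset(b.core_genes) for b in bundles}
            want = {frozenset(p["gene_ids"]) for p in entry["planted"]}
            assert got == want, gid  # decoys are isolated: planted only

    def test_member_order_is_shuffled_per_species(self, tmp_path):
        fixture = generate_fixture(small_config(seed=1), tmp_path / "fx")
        orders = set()
        for gid in ("P1", "P2", "P3"):
            entry = fixture.manifest["genomes"][gid]
            planted = next(
                p for p in entry["planted"] if p["label"] == "universal_pathway"
            )
            orders.add(
                tuple(
                    tuple(planted["motifs_per_gene"][g]) for g in planted["gene_ids"]
                )
            )
        assert len(orders) > 1  # species-specific gene order


class TestEdgeCasesAndRecovery:
    def test_no_planting_no_decoys_yields_zero_bundles(self, tmp_path):
        cfg = small_config(planted_bundles=(), decoy_flagged_rate=0.0)
        fixture = generate_fixture(cfg, tmp_path / "fx")
        for gid in cfg.genome_ids:
            table, hits = load_and_flag(fixture, gid)
            assert hits == []
            assert bundle_genome(table, hits, BundlingParams()) == []

    def test_infeasible_packing_raises(self, tmp_path):
        big = PlantedBundle(
            label="huge",
            gene_motifs=tuple(("p450",) for _ in range(30)),
            gap_lo=10,
            gap_hi=10,
        )
        cfg = small_config(genes_per_scaffold=50, planted_bundles=(big,))
        with pytest.raises(ConfigurationError, match="packing"):
            generate_fixture(cfg, tmp_path / "fx")

    def test_gap_within_g1_recovered_at_stage_one(self, tmp_path):
        bundle = PlantedBundle(
            label="tight",
            gene_motifs=(("p450",), ("halogenase",), ("mtase",)),
            gap_lo=0,
            gap_hi=5,
        )
        cfg = small_config(n_producers=1, n_nonproducers=0, planted_bundles=(bundle,),
                           decoy_flagged_rate=0.0, scaffolds_per_genome=1)
        fixture = generate_fixture(cfg, tmp_path / "fx")
        table, hits = load_and_flag(fixture, "P1")
        (b,) = bundle_genome(table, hits, BundlingParams())
        assert b.stage == "initial"

    def test_gap_beyond_g2_not_recovered(self, tmp_path):
        bundle = PlantedBundle(
            label="wide",
            gene_motifs=(("p450",), ("halogenase",)),
            gaps=(25,),  # > g2 = 20
        )
        cfg = small_config(n_producers=1, n_nonproducers=0, planted_bundles=(bundle,),
                           decoy_flagged_rate=0.0, scaffolds_per_genome=1)
        fixture = generate_fixture(cfg, tmp_path / "fx")
        table, hits = load_and_flag(fixture, "P1")
        assert bundle_genome(table, hits, BundlingParams()) == []

    def test_recovery_fraction_non_increasing_with_gap_width(self, tmp_path):
        """Recovery degrades monotonically as planted gaps exceed g1 then g2."""
        fractions = []
        for lo, hi in [(0, 4), (8, 15), (25, 30)]:
            recovered = 0
            n_seeds = 20
            for seed in range(n_seeds):
                bundle = PlantedBundle(
                    label="probe",
                    gene_motifs=(("p450",), ("halogenase",)),
                    gap_lo=lo,
                    gap_hi=hi,
                )
                cfg = small_config(
                    n_producers=1,
                    n_nonproducers=0,
                    planted_bundles=(bundle,),
                    decoy_flagged_rate=0.0,
                    scaffolds_per_genome=1,
                    seed=seed,
                )
                fixture = generate_fixture(cfg, tmp_path / f"fx_{lo}_{hi}_{seed}")
                table, hits = load_and_flag(fixture, "P1")
                bundles = bundle_genome(table, hits, BundlingParams())
                if len(bundles) == 1 and bundles[0].n_core == 2:
                    recovered += 1
            fractions.append(recovered / n_seeds)
        assert fractions[0] == 1.0
        assert fractions[0] >= fractions[1] >= fractions[2]
        assert fractions[2] == 0.0

    def test_manifest_json_is_valid_and_complete(self, tmp_path):
        cfg = small_config(seed=4)
        fixture = generate_fixture(cfg, tmp_path / "fx")
        manifest = json.loads(fixture.manifest_path.read_text())
        assert set(manifest["genomes"]) == set(cfg.genome_ids)
        assert manifest["phenotypes"]["P1"] == "producer"
        assert manifest["phenotypes"]["N1"] == "nonproducer"
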
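"""Synthetic multi-species genomes with planted gene bundles.

Emulates the comparative setting the pipeline is built for: several
producer and non-producer genomes, each carrying planted bundles whose
member genes appear in species-specific order with a variable number of
interspersed neutral genes between them, plus isolated decoy biosynthetic
genes scattered far from any bundle.  The generator writes exactly the
formats the pipeline consumes (GFF3, protein FASTA, hits TSV, phenotype
TSV, motif-library FASTA) plus a ground-truth manifest JSON.

Sequence design guarantees a clean separation for the built-in k-mer
matcher: exemplar/flagged proteins are drawn from one half of the amino
acid alphabet and neutral proteins from the disjoint other half, so a
flagged gene always scores maximally against its motif and a neutral gene
scores exactly zero.  Bundle-recovery tests therefore probe the bundling
logic, never matcher noise.

All randomness flows from one seed; per-genome substreams are derived by
stable hashing of the genome id, so adding a genome never perturbs the
others.
"""

from __future__ import annotations

import json
import os
import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .bundler import BundlingParams
from .errors import ConfigurationError

#: flagged/exemplar proteins use this alphabet, neutral proteins the other —
#: the two share no k-mers for any k >= 1.
MOTIF_ALPHABET = "ACDEFGHIK"
NEUTRAL_ALPHABET = "LMNPQRSTVWY"
EXEMPLAR_LENGTH = 60

#: ordinal spacing kept between planted bundles, and around decoys, so that
#: nothing merges across ground-truth boundaries under the default g2.
CLEAR_SPACING = BundlingParams().g2 + 1

DEFAULT_MOTIFS = (
    "amidinotransferase",
    "decarboxylase",
    "coa_ligase",
    "acyltransferase",
    "fad_nadp_binding",
    "methyltransferase",
    "p450",
    "halogenase",
    "dioxygenase",
    "n_acyltransferase",
)


def _substream(seed: int, name: str) -> random.Random:
    """Derive an independent RNG from (seed, name) by stable hashing."""
    return random.Random(zlib.crc32(f"{seed}:{name}".encode()) & 0x7FFFFFFF)


@dataclass(frozen=True)
class PlantedBundle:
    """Specification of one ground-truth bundle.

    ``gene_motifs`` lists, per member gene, the motif ids that gene
    carries.  ``present_in`` is ``"producers"``, ``"all"``, or an explicit
    tuple of genome ids.  Gaps between consecutive members are drawn
    uniformly from [gap_lo, gap_hi] unless ``gaps`` pins them explicitly
    (length must be members - 1); member order is shuffled per species.
    """

    label: str
    gene_motifs: tuple[tuple[str, ...], ...]
    present_in: str | tuple[str, ...] = "producers"
    gap_lo: int = 0
    gap_hi: int = 4
    gaps: tuple[int, ...] | None = None

    def span(self, gaps: Sequence[int]) -> int:
        return len(self.gene_motifs) + sum(gaps)


def default_planted(producer_ids: Sequence[str]) -> tuple[PlantedBundle, ...]:
    """One universal producer bundle plus two producer-subset bundles.

    The universal bundle mimics a six-enzyme alkaloid pathway conserved in
    every producer; the subset bundles are conserved in only some
    producers (the first three and the last three), as real families
    usually are.
    """
    return (
        PlantedBundle(
            label="universal_pathway",
            gene_motifs=(
                ("amidinotransferase",),
                ("decarboxylase",),
                ("coa_ligase",),
                ("acyltransferase",),
                ("fad_nadp_binding",),
                ("methyltransferase",),
            ),
            present_in="producers",
        ),
        PlantedBundle(
            label="subset_oxidative",
            gene_motifs=(("p450",), ("halogenase",), ("dioxygenase",), ("n_acyltransferase",)),
            present_in=tuple(producer_ids[:3]),
        ),
        PlantedBundle(
            label="subset_tailoring",
            gene_motifs=(("p450",), ("methyltransferase",), ("coa_ligase",)),
            present_in=tuple(producer_ids[-3:]),
        ),
    )


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic multi-genome fixture.

    Defaults mirror a small comparative survey: five producer and three
    non-producer genomes, two scaffolds of 120 gene models each, one
    universal producer-only bundle plus two producer-subset bundles, and
    roughly 2% of genes flagged as isolated decoys — comparable to the low
    flagged fraction real biosynthetic filters retain.
    """

    n_producers: int = 5
    n_nonproducers: int = 3
    genes_per_scaffold: int = 120
    scaffolds_per_genome: int = 2
    planted_bundles: tuple[PlantedBundle, ...] | None = None
    decoy_flagged_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_bundles is None:
            self.planted_bundles = default_planted(self.producer_ids)

    @property
    def producer_ids(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_producers)]

    @property
    def nonproducer_ids(self) -> list[str]:
        return [f"N{i + 1}" for i in range(self.n_nonproducers)]

    @property
    def genome_ids(self) -> list[str]:
        return self.producer_ids + self.nonproducer_ids

    def resolve_present_in(self, bundle: PlantedBundle) -> list[str]:
        if bundle.present_in == "producers":
            return self.producer_ids
        if bundle.present_in == "all":
            return self.genome_ids
        unknown = [g for g in bundle.present_in if g not in self.genome_ids]
        if unknown:
            raise ConfigurationError(
                f"bundle {bundle.label!r}: unknown genome(s) {unknown} in present_in"
            )
        return list(bundle.present_in)


@dataclass
class Fixture:
    """Paths and ground truth of one generated fixture."""

    root: Path
    genome_files: dict[str, dict[str, Path]]  # gid -> {gff3, fasta, hits}
    motif_fasta: Path
    phenotype_tsv: Path
    manifest_path: Path
    manifest: dict


def make_exemplars(seed: int, motif_ids: Sequence[str] = DEFAULT_MOTIFS) -> dict[str, str]:
    """Deterministic exemplar protein per motif, from the motif alphabet."""
    rng = _substream(seed, "library")
    return {
        m: "".join(rng.choice(MOTIF_ALPHABET) for _ in range(EXEMPLAR_LENGTH))
        for m in motif_ids
    }


def _draw_gaps(bundle: PlantedBundle, rng: random.Random) -> list[int]:
    n = len(bundle.gene_motifs) - 1
    if bundle.gaps is not None:
        if len(bundle.gaps) != n:
            raise ConfigurationError(
                f"bundle {bundle.label!r}: {len(bundle.gaps)} gaps for {n + 1} members"
            )
        return list(bundle.gaps)
    if bundle.gap_lo > bundle.gap_hi or bundle.gap_lo < 0:
        raise ConfigurationError(f"bundle {bundle.label!r}: bad gap range")
    return [rng.randint(bundle.gap_lo, bundle.gap_hi) for _ in range(n)]


def _split_slack(slack: int, parts: int, rng: random.Random) -> list[int]:
    """Random non-negative integers, ``parts`` of them, summing to slack."""
    if parts == 1:
        return [slack]
    cuts = sorted(rng.randint(0, slack) for _ in range(parts - 1))
    prev = 0
    out = []
    for c in cuts:
        out.append(c - prev)
        prev = c
    out.append(slack - prev)
    return out


def _layout_scaffold(
    n_genes: int,
    instances: list[tuple[PlantedBundle, list[int]]],
    rng: random.Random,
) -> list[tuple[PlantedBundle, list[int], int]]:
    """Place bundle instances on a scaffold, CLEAR_SPACING apart.

    Returns (bundle, gaps, start_slot) per instance; raises if the
    scaffold cannot hold them.
    """
    spans = [b.span(g) for b, g in instances]
    k = len(instances)
    slack = n_genes - sum(spans) - CLEAR_SPACING * (k - 1 if k else 0)
    if slack < 0:
        raise ConfigurationError(
            f"infeasible packing: {sum(spans)} bundle slots + spacing exceed "
            f"{n_genes} genes on scaffold"
        )
    offsets = _split_slack(slack, k + 1, rng) if k else []
    placed = []
    cursor = 0
    for (bundle, gaps), span, off in zip(instances, spans, offsets):
        cursor += off
        placed.append((bundle, gaps, cursor))
        cursor += span + CLEAR_SPACING
    return placed


def _member_slots(gaps: Sequence[int], start: int) -> list[int]:
    slots = [start]
    for g in gaps:
        slots.append(slots[-1] + g + 1)
    return slots


def generate_fixture(config: FixtureConfig, outdir: str | os.PathLike) -> Fixture:
    """Write a complete synthetic fixture under ``outdir``.

    Deterministic: the same config (including seed) yields byte-identical
    files.  Planted members appear on one scaffold with per-species
    shuffled gene order and gaps from the configured distribution; decoy
    flagged genes are isolated — at least g2+1 gene models from any
    planted bundle and from each other — so ground-truth bundles are
    exactly the planted ones.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    motif_ids = sorted(
        {m for b in config.planted_bundles for gm in b.gene_motifs for m in gm}
        | set(DEFAULT_MOTIFS)
    )
    exemplars = make_exemplars(config.seed, motif_ids)

    motif_fasta = outdir / "motifs.faa"
    with open(motif_fasta, "w") as fh:
        for m in motif_ids:
            fh.write(f">{m} biosynthetic exemplar\n{exemplars[m]}\n")

    presence = {
        b.label: set(config.resolve_present_in(b)) for b in config.planted_bundles
    }
    phenotype_tsv = outdir / "phenotypes.tsv"
    with open(phenotype_tsv, "w") as fh:
        for gid in config.genome_ids:
            label = "producer" if gid in set(config.producer_ids) else "nonproducer"
            fh.write(f"{gid}\t{label}\n")

    genome_files: dict[str, dict[str, Path]] = {}
    manifest_genomes: dict[str, dict] = {}
    for gid in config.genome_ids:
        rng = _substream(config.seed, gid)
        files, entry = _generate_genome(gid, config, exemplars, motif_ids, rng, outdir)
        genome_files[gid] = files
        manifest_genomes[gid] = entry

    manifest = {
        "seed": config.seed,
        "motif_ids": motif_ids,
        "phenotypes": {
            gid: ("producer" if gid in set(config.producer_ids) else "nonproducer")
            for gid in config.genome_ids
        },
        "planted_presence": {k: sorted(v) for k, v in presence.items()},
        "genomes": manifest_genomes,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return Fixture(
        root=outdir,
        genome_files=genome_files,
        motif_fasta=motif_fasta,
        phenotype_tsv=phenotype_tsv,
        manifest_path=manifest_path,
        manifest=manifest,
    )


def _generate_genome(
    gid: str,
    config: FixtureConfig,
    exemplars: Mapping[str, str],
    motif_ids: Sequence[str],
    rng: random.Random,
    outdir: Path,
) -> tuple[dict[str, Path], dict]:
    mine = [
        b for b in config.planted_bundles if gid in set(config.resolve_present_in(b))
    ]
    # round-robin bundle instances over scaffolds
    per_scaffold: dict[int, list[tuple[PlantedBundle, list[int]]]] = {
        s: [] for s in range(config.scaffolds_per_genome)
    }
    for i, bundle in enumerate(mine):
        order = list(range(len(bundle.gene_motifs)))
        rng.shuffle(order)  # species-specific gene order
        gaps = _draw_gaps(bundle, rng)
        shuffled = PlantedBundle(
            label=bundle.label,
            gene_motifs=tuple(bundle.gene_motifs[j] for j in order),
            present_in=bundle.present_in,
            gap_lo=bundle.gap_lo,
            gap_hi=bundle.gap_hi,
        )
        per_scaffold[i % config.scaffolds_per_genome].append((shuffled, gaps))

    planted_entries: list[dict] = []
    decoy_entries: list[dict] = []
    gff_lines = ["##gff-version 3"]
    fasta_chunks: list[str] = []
    hit_lines = ["# gene_id\tmotif_id\tscore\tevalue"]

    for s in range(config.scaffolds_per_genome):
        scaffold = f"scf{s + 1}"
        n = config.genes_per_scaffold
        placed = _layout_scaffold(n, per_scaffold[s], rng)

        slot_motifs: dict[int, tuple[str, ...]] = {}
        blocked: list[tuple[int, int]] = []
        for bundle, gaps, start in placed:
            slots = _member_slots(gaps, start)
            blocked.append((slots[0], slots[-1]))
            gene_ids = []
            motifs_per_gene = {}
            for slot, motifs in zip(slots, bundle.gene_motifs):
                slot_motifs[slot] = motifs
                gid_gene = f"{gid}_{scaffold}_g{slot:04d}"
                gene_ids.append(gid_gene)
                motifs_per_gene[gid_gene] = list(motifs)
            planted_entries.append(
                {
                    "label": bundle.label,
                    "scaffold": scaffold,
                    "ordinals": slots,
                    "gene_ids": gene_ids,
                    "motifs_per_gene": motifs_per_gene,
                }
            )

        def clear_of_planted(slot: int) -> bool:
            return all(
                slot < lo - CLEAR_SPACING or slot > hi + CLEAR_SPACING
                for lo, hi in blocked
            )

        last_decoy = -10 * CLEAR_SPACING
        for slot in range(n):
            if slot in slot_motifs or not clear_of_planted(slot):
                continue
            if rng.random() < config.decoy_flagged_rate and slot - last_decoy > CLEAR_SPACING:
                motif = rng.choice(list(motif_ids))
                slot_motifs[slot] = (motif,)
                last_decoy = slot
                decoy_entries.append(
                    {
                        "gene_id": f"{gid}_{scaffold}_g{slot:04d}",
                        "scaffold": scaffold,
                        "ordinal": slot,
                        "motif": motif,
                    }
                )

        prev_end = 0
        for slot in range(n):
            gene_id = f"{gid}_{scaffold}_g{slot:04d}"
            if slot in slot_motifs:
                protein = "".join(exemplars[m] for m in slot_motifs[slot])
                for m in slot_motifs[slot]:
                    hit_lines.append(f"{gene_id}\t{m}\t100.0\t1e-30")
            else:
                protein = "".join(
                    rng.choice(NEUTRAL_ALPHABET) for _ in range(rng.randint(50, 150))
                )
            start = prev_end + rng.randint(200, 800)
            end = start + 3 * len(protein) + 2
            prev_end = end
            strand = rng.choice("+-")
            gff_lines.append(
                f"{scaffold}\tbundlemine_sim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}"
            )
            fasta_chunks.append(f">{gene_id}\n{protein}\n")

    files = {
        "gff3": outdir / f"{gid}.gff3",
        "fasta": outdir / f"{gid}.faa",
        "hits": outdir / f"{gid}.hits.tsv",
    }
    files["gff3"].write_text("\n".join(gff_lines) + "\n")
    files["fasta"].write_text("".join(fasta_chunks))
    files["hits"].write_text("\n".join(hit_lines) + "\n")

    entry = {
        "planted": planted_entries,
        "decoys": decoy_entries,
        "n_genes": config.genes_per_scaffold * config.scaffolds_per_genome,
    }
    return files, entry
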
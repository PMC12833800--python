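"""Two-stage gap-tolerant bundling of flagged genes.

Stage 1 walks each scaffold's flagged genes in ordinal order and joins
consecutive genes into a tight cluster whenever at most ``g1`` non-flagged
gene models lie between them; clusters with fewer than ``min_core`` flagged
genes are discarded.  Stage 2 then merges neighbouring stage-1 clusters
whenever at most ``g2`` gene models separate their spans, transitively,
producing the large candidate bundles that can span dozens of interspersed
unrelated genes.  Gaps are counted in intervening *gene models*, never base
pairs: animal assemblies differ wildly in intergenic span, but the number
of gene models between two pathway genes is comparable across species.

Strand and gene orientation never enter the procedure — bundles are sets
of neighbouring genes regardless of order, orientation, or colinearity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .genome_io import GenomeTable
from .motif_filter import DomainHit, passed_motifs_by_gene

STAGE_INITIAL = "initial"
STAGE_MERGED = "merged"


@dataclass(frozen=True)
class BundlingParams:
    """Gap tolerances, counted in intervening gene models.

    g1
        Max non-flagged genes between members of a tight stage-1 cluster.
    g2
        Max genes between stage-1 clusters merged in stage 2; must be
        >= g1.  The default 20 covers the separations observed between
        co-bundled vertebrate pathway genes (up to 19 intervening genes).
    min_core
        Minimum flagged genes for a reported bundle; a lone flagged gene
        is not a bundle.
    """

    g1: int = 5
    g2: int = 20
    min_core: int = 2

    def __post_init__(self) -> None:
        if self.g1 < 0 or self.g2 < 0:
            raise ValidationError("gap tolerances must be >= 0")
        if self.g2 < self.g1:
            raise ValidationError(f"g2 ({self.g2}) must be >= g1 ({self.g1})")
        if self.min_core < 1:
            raise ValidationError("min_core must be >= 1")


@dataclass(frozen=True)
class Bundle:
    """A per-scaffold group of flagged genes plus its domain signature.

    ``core_genes`` holds only flagged genes, in ordinal order; non-flagged
    genes inside the span are "interspersed" and never contribute to the
    signature.  ``domain_counts`` maps each motif to the number of core
    genes carrying it (the multiset view used by the weighted metric).
    """

    bundle_id: str
    genome_id: str
    scaffold_id: str
    core_genes: tuple[str, ...]
    span: tuple[int, int]  # (first_ordinal, last_ordinal)
    bp_span: tuple[int, int]  # (first_start, last_end)
    domain_signature: frozenset[str]
    domain_counts: Mapping[str, int]
    stage: str = STAGE_INITIAL

    def __post_init__(self) -> None:
        if self.span[1] < self.span[0]:
            raise ValidationError(f"bundle {self.bundle_id!r}: inverted ordinal span")
        if set(self.domain_counts) != set(self.domain_signature):
            raise ValidationError(
                f"bundle {self.bundle_id!r}: domain_counts/signature mismatch"
            )

    @property
    def n_core(self) -> int:
        return len(self.core_genes)


# ----------------------------------------------------------------------
# stage algorithms on ordinals
# ----------------------------------------------------------------------

def _check_ordinals(ordinals: Sequence[int]) -> None:
    for prev, cur in zip(ordinals, ordinals[1:]):
        if cur <= prev:
            raise ValidationError("flagged ordinals must be sorted, unique ascending")


def cluster_ordinals(ordinals: Sequence[int], g1: int) -> list[tuple[int, ...]]:
    """Partition sorted ordinals into maximal runs with gaps <= g1.

    Two consecutive flagged genes fall in the same cluster iff the number
    of intervening gene models (ordinal difference minus one) is at most
    ``g1``.  The resulting partition is unique.
    """
    _check_ordinals(ordinals)
    clusters: list[list[int]] = []
    for o in ordinals:
        if clusters and o - clusters[-1][-1] - 1 <= g1:
            clusters[-1].append(o)
        else:
            clusters.append([o])
    return [tuple(c) for c in clusters]


def merge_ordinal_clusters(
    clusters: Sequence[Sequence[int]], g2: int
) -> list[tuple[int, ...]]:
    """Transitively merge neighbouring clusters separated by <= g2 genes.

    Input clusters must be non-overlapping and sorted by first ordinal;
    the gap between two clusters is the number of ordinals strictly
    between the first's span end and the next's span start.
    """
    for prev, cur in zip(clusters, clusters[1:]):
        if cur[0] <= prev[-1]:
            raise ValidationError("input clusters overlap or are unsorted")
    merged: list[list[int]] = []
    for c in clusters:
        if merged and c[0] - merged[-1][-1] - 1 <= g2:
            merged[-1].extend(c)
        else:
            merged.append(list(c))
    return [tuple(m) for m in merged]


def build_initial_clusters(
    flagged_ordinals: Sequence[int], params: BundlingParams
) -> list[tuple[int, ...]]:
    """Stage 1: tight clusters on one scaffold, min_core applied."""
    return [
        c
        for c in cluster_ordinals(flagged_ordinals, params.g1)
        if len(c) >= params.min_core
    ]


def merge_clusters(
    initial: Sequence[Sequence[int]], params: BundlingParams
) -> list[tuple[int, ...]]:
    """Stage 2: merge broadly spaced stage-1 clusters on one scaffold.

    Idempotent: rerunning on its own output changes nothing, because any
    two surviving neighbours are separated by more than ``g2`` genes.
    """
    return merge_ordinal_clusters(initial, params.g2)


# ----------------------------------------------------------------------
# whole-genome composition
# ----------------------------------------------------------------------

def bundle_genome(
    genome: GenomeTable,
    hits: Iterable[DomainHit],
    params: BundlingParams = BundlingParams(),
) -> list[Bundle]:
    """Run both bundling stages over every scaffold of one genome.

    Bundle ids are assigned in (scaffold, first ordinal) order as
    ``<genome>.<scaffold>.b<N>``.  Every flagged gene retained by stage 1
    ends up in exactly one bundle.  Scaffold boundaries are never crossed.
    """
    hits = list(hits)
    unknown = sorted({h.gene_id for h in hits} - set(genome.gene_ids))
    if unknown:
        raise ValidationError(
            f"hits reference unknown gene_id(s): {', '.join(unknown)}"
        )
    motifs_by_gene = passed_motifs_by_gene(hits)

    bundles: list[Bundle] = []
    for scaffold in sorted(genome.scaffolds):
        genes = genome.genes_on(scaffold)  # already in ordinal order
        by_ordinal = {g.ordinal: g for g in genes}
        flagged = [g.ordinal for g in genes if g.gene_id in motifs_by_gene]
        initial = build_initial_clusters(flagged, params)
        merged = merge_clusters(initial, params)

        n_initial_parts = {  # how many stage-1 clusters each merged bundle absorbed
            m[0]: sum(1 for c in initial if c[0] >= m[0] and c[-1] <= m[-1])
            for m in merged
        }
        for idx, ordinals in enumerate(merged):
            members = [by_ordinal[o] for o in ordinals]
            gene_ids = tuple(g.gene_id for g in members)
            counts: dict[str, int] = {}
            for g in members:
                for m in motifs_by_gene[g.gene_id]:
                    counts[m] = counts.get(m, 0) + 1
            bundles.append(
                Bundle(
                    bundle_id=f"{genome.genome_id}.{scaffold}.b{idx}",
                    genome_id=genome.genome_id,
                    scaffold_id=scaffold,
                    core_genes=gene_ids,
                    span=(ordinals[0], ordinals[-1]),
                    bp_span=(members[0].start, members[-1].end),
                    domain_signature=frozenset(counts),
                    domain_counts=counts,
                    stage=STAGE_MERGED if n_initial_parts[ordinals[0]] > 1 else STAGE_INITIAL,
                )
            )
    return bundles


def interspersed_genes(genome: GenomeTable, bundles: Iterable[Bundle]) -> list[dict]:
    """Non-flagged gene models lying inside a bundle's ordinal span.

    These are reported for inspection but never contribute to domain
    signatures — they are exactly the genes the filtering step excluded.
    """
    rows = []
    for b in bundles:
        if b.genome_id != genome.genome_id:
            continue
        core = set(b.core_genes)
        for g in genome.genes_on(b.scaffold_id):
            if b.span[0] <= g.ordinal <= b.span[1] and g.gene_id not in core:
                rows.append(
                    {
                        "bundle_id": b.bundle_id,
                        "genome_id": b.genome_id,
                        "scaffold_id": b.scaffold_id,
                        "gene_id": g.gene_id,
                        "ordinal": g.ordinal,
                        "start": g.start,
                        "end": g.end,
                    }
                )
    return rows
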
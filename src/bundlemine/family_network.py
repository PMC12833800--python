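"""Cross-genome bundle comparison: raw distances and bundle families.

Two bundles are compared by their domain-content signatures only.  The
default metric is ``raw_distance = 1 - Jaccard`` on domain *sets*; a
weighted multiset variant (min/max over per-gene domain counts) is
available for users who want copy number to matter.  Position, orientation
and colinearity deliberately play no role: the method's premise is that
animal pathway genes keep their neighbourhood but not their order.

Bundles joined by an edge (raw_distance <= threshold, default 0.5) fall
into the same *family* via single linkage, i.e. families are the connected
components of the thresholded distance graph.  A family with one member
bundle is a *singleton* — a bundle seen in a single species only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .bundler import Bundle
from .errors import ValidationError

DEFAULT_FAMILY_THRESHOLD = 0.5


@dataclass(frozen=True)
class BundlePairDistance:
    """Symmetric domain-content distance between two bundles."""

    bundle_a: str
    bundle_b: str
    jaccard: float
    raw_distance: float


@dataclass(frozen=True)
class BundleFamily:
    """A connected component of bundles under the raw-distance threshold."""

    family_id: str
    member_bundles: frozenset[str]
    genomes_present: frozenset[str]

    @property
    def is_singleton(self) -> bool:
        return len(self.member_bundles) == 1

    @property
    def is_multi_species(self) -> bool:
        return len(self.genomes_present) >= 2


def _similarity(a: Bundle, b: Bundle, metric: str) -> float:
    if not a.domain_signature or not b.domain_signature:
        empty = a.bundle_id if not a.domain_signature else b.bundle_id
        raise ValidationError(f"bundle {empty!r} has an empty domain signature")
    if metric == "jaccard":
        inter = len(a.domain_signature & b.domain_signature)
        union = len(a.domain_signature | b.domain_signature)
        return inter / union
    if metric == "multiset_jaccard":
        keys = set(a.domain_counts) | set(b.domain_counts)
        mins = sum(min(a.domain_counts.get(k, 0), b.domain_counts.get(k, 0)) for k in keys)
        maxs = sum(max(a.domain_counts.get(k, 0), b.domain_counts.get(k, 0)) for k in keys)
        return mins / maxs
    raise ValidationError(f"unknown metric {metric!r}")


def bundle_distance(a: Bundle, b: Bundle, metric: str = "jaccard") -> BundlePairDistance:
    """Jaccard similarity and raw distance between two bundles' signatures."""
    sim = _similarity(a, b, metric)
    return BundlePairDistance(a.bundle_id, b.bundle_id, sim, 1.0 - sim)


def build_families(
    bundles: Sequence[Bundle],
    threshold: float = DEFAULT_FAMILY_THRESHOLD,
    metric: str = "jaccard",
) -> tuple[list[BundleFamily], list[BundlePairDistance]]:
    """Form bundle families by single linkage at a raw-distance threshold.

    An edge joins two bundles iff ``raw_distance <= threshold`` (inclusive);
    families are the connected components of the resulting graph, so every
    bundle belongs to exactly one family.  Family ids are assigned in
    sorted order of each component's smallest member bundle_id.

    Returns the families plus the retained edges.
    """
    ids = [b.bundle_id for b in bundles]
    if len(ids) != len(set(ids)):
        dup = sorted(i for i in set(ids) if ids.count(i) > 1)
        raise ValidationError(f"duplicate bundle_id(s): {', '.join(dup)}")

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    edges: list[BundlePairDistance] = []
    for a, b in combinations(sorted(bundles, key=lambda x: x.bundle_id), 2):
        d = bundle_distance(a, b, metric=metric)
        if d.raw_distance <= threshold:
            edges.append(d)
            graph.add_edge(d.bundle_a, d.bundle_b, weight=d.raw_distance)

    genome_of = {b.bundle_id: b.genome_id for b in bundles}
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    families = [
        BundleFamily(
            family_id=f"FAM{i:04d}",
            member_bundles=frozenset(comp),
            genomes_present=frozenset(genome_of[m] for m in comp),
        )
        for i, comp in enumerate(components)
    ]
    return families, edges


def families_to_rows(families: Iterable[BundleFamily]) -> list[dict]:
    return [
        {
            "family_id": f.family_id,
            "n_members": len(f.member_bundles),
            "members": ";".join(sorted(f.member_bundles)),
            "genomes": ";".join(sorted(f.genomes_present)),
            "is_singleton": str(f.is_singleton).lower(),
        }
        for f in sorted(families, key=lambda f: f.family_id)
    ]


def read_families_tsv(path) -> list[BundleFamily]:
    """Re-read a families TSV written by the pipeline."""
    import csv

    families = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            families.append(
                BundleFamily(
                    family_id=row["family_id"],
                    member_bundles=frozenset(row["members"].split(";")),
                    genomes_present=frozenset(row["genomes"].split(";")),
                )
            )
    return families
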
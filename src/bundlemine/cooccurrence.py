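"""Domain co-occurrence network across bundles.

For every unordered pair of motifs/domains, the co-occurrence count is the
number of bundles whose domain signature contains both (presence within a
bundle, not multiplicity), and

    probability = cooccurrence / total_clusters

where ``total_clusters`` is the number of bundles considered.  Only edges
with probability strictly greater than the display threshold (default
0.025) are retained.  Frequently co-occurring pairs reveal the recurring
enzymatic vocabulary of the bundles — FAD/NAD(P)-binding oxidases, acyl-CoA
enzymes, methyltransferases, cytochromes P450 and the like.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .bundler import Bundle
from .errors import ValidationError

DEFAULT_PROB_THRESHOLD = 0.025


@dataclass(frozen=True)
class CooccurrenceEdge:
    """An unordered domain pair with its bundle co-occurrence statistics.

    Invariant: ``domain_a < domain_b`` lexicographically, and
    ``probability * total_clusters == cooccurrence`` exactly.
    """

    domain_a: str
    domain_b: str
    cooccurrence: int
    total_clusters: int
    probability: float


def cooccurrence_network(
    bundles: Sequence[Bundle],
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
) -> list[CooccurrenceEdge]:
    """Count domain-pair co-occurrence over bundles and threshold the edges.

    Edges are kept iff ``probability > prob_threshold`` (strict) and
    returned sorted by descending probability, then pair name.  The result
    does not depend on the order of ``bundles``.
    """
    if not bundles:
        raise ValidationError("cannot compute co-occurrence over zero bundles")
    total = len(bundles)
    counts: Counter[tuple[str, str]] = Counter()
    for b in bundles:
        for pair in combinations(sorted(b.domain_signature), 2):
            counts[pair] += 1
    edges = [
        CooccurrenceEdge(a, b, n, total, n / total)
        for (a, b), n in counts.items()
        if n / total > prob_threshold
    ]
    edges.sort(key=lambda e: (-e.probability, (e.domain_a, e.domain_b)))
    return edges


def top_cooccurrences(edges: Sequence[CooccurrenceEdge], k: int) -> list[CooccurrenceEdge]:
    """First ``k`` edges under the deterministic sort (ties by pair name)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    ordered = sorted(edges, key=lambda e: (-e.probability, (e.domain_a, e.domain_b)))
    return ordered[:k]


def edges_to_rows(edges: Iterable[CooccurrenceEdge]) -> list[dict]:
    return [
        {
            "domain_a": e.domain_a,
            "domain_b": e.domain_b,
            "cooccurrence": e.cooccurrence,
            "total_clusters": e.total_clusters,
            "probability": repr(e.probability),
        }
        for e in edges
    ]
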
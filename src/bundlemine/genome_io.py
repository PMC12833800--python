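"""Gene-model and protein I/O.

Reads GFF3 gene annotations (via :mod:`gffutils`) and protein FASTA (via
Biopython) into a canonical per-genome gene table, and writes the tabular
and network outputs produced downstream.

Coordinates stay GFF3-native (1-based, inclusive) at the I/O boundary.
All bundling logic operates on per-scaffold gene *ordinals* — the rank of
a gene in start-coordinate order on its scaffold — because separations in
this method are counted in intervening gene models, not base pairs.
"""

from __future__ import annotations

import csv
import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import gffutils
import networkx as nx
from Bio import SeqIO

from .errors import EmptyGenomeError, InputError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .bundler import Bundle

logger = logging.getLogger(__name__)

#: Residues accepted in protein sequences: the 20 amino acids plus the
#: ambiguity code X and the stop symbol (trailing stops are stripped on load).
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

BUNDLE_TSV_COLUMNS = (
    "bundle_id",
    "genome_id",
    "scaffold_id",
    "first_ordinal",
    "last_ordinal",
    "first_bp",
    "last_bp",
    "n_core_genes",
    "core_genes",
    "domain_signature",
    "stage",
)


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One gene model with its genomic position and per-scaffold ordinal.

    ``ordinal`` is the 0-based rank of the gene on its scaffold when genes
    are sorted by (start, end, gene_id); ordinals restart at 0 on every
    scaffold and form a contiguous 0..n-1 sequence.
    """

    genome_id: str
    scaffold_id: str
    start: int
    end: int
    gene_id: str
    strand: str = "."
    ordinal: int = -1


@dataclass
class GenomeTable:
    """All gene models of one genome plus their protein sequences.

    ``genes`` is ordered by (scaffold_id, start, end, gene_id), which by
    construction is also per-scaffold ordinal order.  ``proteins`` maps
    gene_id to an amino-acid sequence; genes may lack a protein (they are
    retained and listed in :attr:`genes_without_protein`).
    """

    genome_id: str
    genes: list[GeneRecord]
    proteins: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def scaffolds(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.scaffold_id, None)
        return list(seen)

    @property
    def genes_without_protein(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.gene_id not in self.proteins]

    def genes_on(self, scaffold_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.scaffold_id == scaffold_id]

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError as exc:
            raise KeyError(f"unknown gene_id {gene_id!r} in genome {self.genome_id!r}") from exc

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate gene_id {dup!r} in genome {self.genome_id!r}")
        per_scaffold: dict[str, list[int]] = {}
        for g in self.genes:
            if g.end < g.start:
                raise ValidationError(f"gene {g.gene_id!r}: end {g.end} < start {g.start}")
            per_scaffold.setdefault(g.scaffold_id, []).append(g.ordinal)
        for scaffold, ordinals in per_scaffold.items():
            if sorted(ordinals) != list(range(len(ordinals))):
                raise ValidationError(
                    f"scaffold {scaffold!r}: ordinals are not a contiguous 0..n-1 sequence"
                )
        for gid in self.proteins:
            if gid not in set(ids):
                raise ValidationError(f"protein {gid!r} has no gene model")
        self._by_id = {g.gene_id: g for g in self.genes}


def _clean_protein(seq: str, record_id: str) -> str:
    seq = seq.strip().upper().rstrip("*")
    bad = set(seq) - ALLOWED_RESIDUES
    if bad:
        raise ValidationError(
            f"protein {record_id!r} contains invalid residues {sorted(bad)!r}"
        )
    return seq


def assign_ordinals(
    raw: Iterable[tuple[str, int, int, str, str]], genome_id: str
) -> list[GeneRecord]:
    """Turn (scaffold, start, end, gene_id, strand) tuples into ordered GeneRecords.

    Sorting key is (scaffold_id, start, end, gene_id); ordinals restart per
    scaffold.  Deterministic for any input permutation of the same records.
    """
    rows = sorted(raw, key=lambda r: (r[0], r[1], r[2], r[3]))
    records: list[GeneRecord] = []
    counters: dict[str, int] = {}
    for scaffold, start, end, gene_id, strand in rows:
        ordinal = counters.get(scaffold, 0)
        counters[scaffold] = ordinal + 1
        records.append(
            GeneRecord(
                genome_id=genome_id,
                scaffold_id=scaffold,
                start=start,
                end=end,
                gene_id=gene_id,
                strand=strand,
                ordinal=ordinal,
            )
        )
    return records


def load_genome(
    gff3_path: str | os.PathLike,
    fasta_path: str | os.PathLike,
    *,
    genome_id: str | None = None,
    feature_type: str = "gene",
    id_attribute: str = "ID",
    collapse_isoforms: bool = False,
) -> GenomeTable:
    """Load one genome's gene models and proteins into a :class:`GenomeTable`.

    Parameters
    ----------
    gff3_path, fasta_path
        GFF3 annotation and protein FASTA.  FASTA record identifiers must
        resolve to gene identifiers through ``id_attribute``.
    genome_id
        Defaults to the GFF3 file stem.
    feature_type
        GFF3 feature type to keep (default ``"gene"``).
    id_attribute
        GFF3 attribute holding the gene identifier (default ``"ID"``).
    collapse_isoforms
        For mRNA/CDS-level annotations: group features by their ``Parent``
        attribute and keep one record per gene.  The isoform with the
        longest protein wins; ties break to the lexicographically smallest
        feature id.  The collapsed record keeps the winning isoform's
        coordinates and its protein is stored under the parent gene id.

    Genes lacking a protein are retained (see
    :attr:`GenomeTable.genes_without_protein`); proteins lacking a gene
    model are dropped with a warning.
    """
    gff3_path = Path(gff3_path)
    fasta_path = Path(fasta_path)
    if genome_id is None:
        genome_id = gff3_path.stem
    for p in (gff3_path, fasta_path):
        if not p.is_file():
            raise InputError(f"cannot read input file: {p}")

    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise InputError(f"failed to parse GFF3 {gff3_path}: {exc}") from exc

    features = []
    for feat in db.features_of_type(feature_type):
        vals = feat.attributes.get(id_attribute)
        if not vals:
            raise ValidationError(
                f"{gff3_path}: {feature_type} feature at {feat.seqid}:{feat.start}"
                f" lacks attribute {id_attribute!r}"
            )
        features.append((feat, vals[0]))
    if not features:
        raise EmptyGenomeError(
            f"{gff3_path}: no features of type {feature_type!r}"
        )

    try:
        proteins_raw = {
            rec.id: _clean_protein(str(rec.seq), rec.id)
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
    except ValidationError:
        raise
    except Exception as exc:
        raise InputError(f"failed to parse FASTA {fasta_path}: {exc}") from exc

    if collapse_isoforms:
        raw, proteins = _collapse_isoforms(features, proteins_raw)
    else:
        ids = [fid for _, fid in features]
        dup = _first_duplicate(ids)
        if dup is not None:
            raise ValidationError(f"duplicate gene_id {dup!r} in {gff3_path}")
        raw = [
            (f.seqid, f.start, f.end, fid, f.strand if f.strand in "+-" else ".")
            for f, fid in features
        ]
        known = set(ids)
        proteins = {}
        for pid, seq in proteins_raw.items():
            if pid in known:
                proteins[pid] = seq
            else:
                logger.warning(
                    "genome %s: protein %r has no gene model; dropped", genome_id, pid
                )

    table = GenomeTable(
        genome_id=genome_id,
        genes=assign_ordinals(raw, genome_id),
        proteins=proteins,
    )
    missing = table.genes_without_protein
    if missing:
        logger.warning(
            "genome %s: %d gene(s) lack a protein sequence (e.g. %s)",
            genome_id,
            len(missing),
            missing[0],
        )
    return table


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


def _collapse_isoforms(features, proteins_raw):
    """Keep one isoform per parent gene: longest protein, tie -> smallest id."""
    groups: dict[str, list] = {}
    for feat, fid in features:
        parents = feat.attributes.get("Parent")
        parent = parents[0] if parents else fid
        groups.setdefault(parent, []).append((feat, fid))
    raw = []
    proteins: dict[str, str] = {}
    for parent, members in groups.items():
        def rank(item):
            _, fid = item
            return (-len(proteins_raw.get(fid, "")), fid)

        feat, fid = min(members, key=rank)
        raw.append(
            (feat.seqid, feat.start, feat.end, parent, feat.strand if feat.strand in "+-" else ".")
        )
        if fid in proteins_raw:
            proteins[parent] = proteins_raw[fid]
    dup = _first_duplicate([r[3] for r in raw])
    if dup is not None:
        raise ValidationError(f"duplicate gene_id {dup!r} after isoform collapse")
    return raw, proteins


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------

def _atomic_open(path: Path):
    path.parent.mkdir(parents=True, exist_ok=True)
    return tempfile.NamedTemporaryFile(
        "w", dir=path.parent, suffix=".tmp", delete=False, newline=""
    )


def write_bundles_tsv(bundles: Iterable["Bundle"], path: str | os.PathLike) -> Path:
    """Write bundles to a TSV, one row per bundle, byte-stable across runs.

    Rows are sorted by (genome_id, scaffold_id, first ordinal); member gene
    ids are semicolon-joined in ordinal order and the domain signature is
    sorted.  An empty input yields a header-only file.
    """
    path = Path(path)
    rows = sorted(
        bundles, key=lambda b: (b.genome_id, b.scaffold_id, b.span[0], b.bundle_id)
    )
    try:
        tmp = _atomic_open(path)
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
    with tmp:
        writer = csv.writer(tmp, delimiter="\t", lineterminator="\n")
        writer.writerow(BUNDLE_TSV_COLUMNS)
        for b in rows:
            writer.writerow(
                [
                    b.bundle_id,
                    b.genome_id,
                    b.scaffold_id,
                    b.span[0],
                    b.span[1],
                    b.bp_span[0],
                    b.bp_span[1],
                    len(b.core_genes),
                    ";".join(b.core_genes),
                    ";".join(sorted(b.domain_signature)),
                    b.stage,
                ]
            )
    os.replace(tmp.name, path)
    return path


def read_bundles_tsv(path: str | os.PathLike) -> list["Bundle"]:
    """Re-read a bundles TSV written by :func:`write_bundles_tsv`.

    Per-gene domain counts are not serialized, so bundles read back carry a
    set signature only (sufficient for the default set-Jaccard metric and
    for co-occurrence counting).
    """
    from .bundler import Bundle

    path = Path(path)
    bundles: list[Bundle] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            core = tuple(row["core_genes"].split(";")) if row["core_genes"] else ()
            sig = frozenset(s for s in row["domain_signature"].split(";") if s)
            bundles.append(
                Bundle(
                    bundle_id=row["bundle_id"],
                    genome_id=row["genome_id"],
                    scaffold_id=row["scaffold_id"],
                    core_genes=core,
                    span=(int(row["first_ordinal"]), int(row["last_ordinal"])),
                    bp_span=(int(row["first_bp"]), int(row["last_bp"])),
                    domain_signature=sig,
                    domain_counts={m: 1 for m in sorted(sig)},
                    stage=row["stage"],
                )
            )
    return bundles


def write_network(
    nodes: Iterable[str],
    edges: Iterable[tuple[str, str, float]],
    path: str | os.PathLike,
    format: str = "graphml",
) -> Path:
    """Write an undirected weighted network as GraphML or a 3-column TSV.

    Nodes and edges are emitted in deterministic sorted order; duplicate
    undirected edges collapse to one (conflicting weights are an error), and
    an edge endpoint absent from ``nodes`` is a validation error.
    """
    path = Path(path)
    node_list = sorted(set(str(n) for n in nodes))
    node_set = set(node_list)
    dedup: dict[tuple[str, str], float] = {}
    for a, b, w in edges:
        a, b = str(a), str(b)
        for end in (a, b):
            if end not in node_set:
                raise ValidationError(f"edge endpoint {end!r} is not a node")
        key = (a, b) if a <= b else (b, a)
        if key in dedup and abs(dedup[key] - float(w)) > 1e-12:
            raise ValidationError(
                f"conflicting weights for undirected edge {key!r}"
            )
        dedup[key] = float(w)

    if format == "graphml":
        graph = nx.Graph()
        graph.add_nodes_from(node_list)
        for (a, b), w in sorted(dedup.items()):
            graph.add_edge(a, b, weight=w)
        path.parent.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(graph, str(path), named_key_ids=True)
    elif format == "edge_tsv":
        try:
            tmp = _atomic_open(path)
        except OSError as exc:
            raise InputError(f"cannot write {path}: {exc}") from exc
        with tmp:
            writer = csv.writer(tmp, delimiter="\t", lineterminator="\n")
            writer.writerow(["node_a", "node_b", "weight"])
            for (a, b), w in sorted(dedup.items()):
                writer.writerow([a, b, repr(w)])
        os.replace(tmp.name, path)
    else:
        raise ValidationError(f"unknown network format {format!r}")
    return path


def write_table(
    rows: Iterable[Mapping[str, object]],
    columns: Sequence[str],
    path: str | os.PathLike,
) -> Path:
    """Small helper: write dict rows as a TSV with a fixed column order."""
    path = Path(path)
    tmp = _atomic_open(path)
    with tmp:
        writer = csv.DictWriter(
            tmp, fieldnames=list(columns), delimiter="\t", lineterminator="\n"
        )
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
    os.replace(tmp.name, path)
    return path
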
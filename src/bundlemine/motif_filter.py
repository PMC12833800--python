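"""Biosynthetic motif library and the first filtering step.

A gene is *flagged* as candidate-biosynthetic when it carries at least one
passing hit against the motif library.  Three matcher backends satisfy the
same contract (gene -> passed/failed against a biosynthetic motif set):

``table``
    Consume a precomputed hit table (hmmscan / DIAMOND run by the user).
    The parser accepts either a simple whitespace-delimited table with
    columns ``target_gene  motif_id  score  [e-value]`` or full HMMER
    domtblout rows (23+ columns; target name, query name, full-sequence
    e-value and score at their standard positions).  ``#`` lines are
    comments.

``builtin_kmer``
    A deterministic shared-k-mer scorer against reference exemplar
    proteins: score = number of distinct k-mers (default k = 4) shared
    with the best exemplar, divided by query length.  A query identical to
    an exemplar scores the maximum attainable for its length.  Used by all
    tests and fixtures; no external program is ever invoked.

``external``
    A documented adapter point: run your own search, feed the result back
    through the ``table`` backend.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import ConfigurationError, InputError, ValidationError
from .genome_io import GenomeTable, write_table

DEFAULT_KMER_K = 4
DEFAULT_SCORE_THRESHOLD = 0.1
DEFAULT_EVALUE_THRESHOLD = 1e-5


@dataclass(frozen=True)
class Motif:
    motif_id: str
    label: str = ""
    source: str = "domain_id"  # or "reference_protein"


@dataclass(frozen=True)
class DomainHit:
    """A motif match on a gene; ``passed`` reflects the thresholds in force."""

    gene_id: str
    motif_id: str
    score: float
    evalue: float | None
    passed: bool


@dataclass
class MotifLibrary:
    """The set of biosynthetic motifs genes are screened against."""

    motifs: tuple[Motif, ...]
    matcher_kind: str = "table"  # table | builtin_kmer | external
    exemplars: dict[str, str] | None = None  # motif_id -> protein, builtin_kmer only

    def __post_init__(self) -> None:
        ids = [m.motif_id for m in self.motifs]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate motif_id in library")

    def __len__(self) -> int:
        return len(self.motifs)

    @property
    def motif_ids(self) -> frozenset[str]:
        return frozenset(m.motif_id for m in self.motifs)

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "MotifLibrary":
        """Reference exemplar proteins -> builtin_kmer library.

        Each FASTA record is one motif: id = record id, label = description
        remainder.
        """
        path = Path(path)
        if not path.is_file():
            raise InputError(f"cannot read motif library: {path}")
        motifs = []
        exemplars = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            label = rec.description[len(rec.id):].strip()
            motifs.append(Motif(rec.id, label, source="reference_protein"))
            exemplars[rec.id] = str(rec.seq).upper().rstrip("*")
        return cls(tuple(motifs), matcher_kind="builtin_kmer", exemplars=exemplars)

    @classmethod
    def from_motif_list(cls, path: str | os.PathLike) -> "MotifLibrary":
        """Two-column TSV (motif_id, label) -> table-backend library."""
        path = Path(path)
        if not path.is_file():
            raise InputError(f"cannot read motif list: {path}")
        motifs = []
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                motifs.append(Motif(parts[0], parts[1] if len(parts) > 1 else ""))
        return cls(tuple(motifs), matcher_kind="table")


@dataclass
class FilterSummary:
    """Per-genome and pooled flagged-gene statistics.

    ``mean_percent`` is the unweighted mean of per-genome percentages;
    ``pooled_percent`` is 100 * pooled_flagged / pooled_total.  The two can
    differ substantially when genome sizes differ, so both are always
    reported.
    """

    per_genome: dict[str, tuple[int, int, float]]  # genome -> (total, flagged, percent)
    pooled_total: int
    pooled_flagged: int
    pooled_percent: float
    mean_percent: float

    @classmethod
    def from_counts(cls, counts: Mapping[str, tuple[int, int]]) -> "FilterSummary":
        """Build a summary from precomputed (total, flagged) counts."""
        per_genome = {}
        for genome, (total, flagged) in counts.items():
            if not 0 <= flagged <= total:
                raise ValidationError(
                    f"genome {genome!r}: flagged {flagged} outside [0, {total}]"
                )
            pct = 100.0 * flagged / total if total else 0.0
            per_genome[genome] = (total, flagged, pct)
        pooled_total = sum(t for t, _, _ in per_genome.values())
        pooled_flagged = sum(f for _, f, _ in per_genome.values())
        pooled_percent = 100.0 * pooled_flagged / pooled_total if pooled_total else 0.0
        percents = [p for _, _, p in per_genome.values()]
        mean_percent = sum(percents) / len(percents) if percents else 0.0
        return cls(per_genome, pooled_total, pooled_flagged, pooled_percent, mean_percent)

    def render(self) -> str:
        """Human-readable report; percentages to one decimal."""
        lines = []
        for genome in sorted(self.per_genome):
            total, flagged, pct = self.per_genome[genome]
            lines.append(f"{genome}\t{flagged}/{total} flagged ({pct:.1f}%)")
        lines.append(
            f"pooled\t{self.pooled_flagged}/{self.pooled_total} flagged "
            f"({self.pooled_percent:.1f}%); unweighted mean {self.mean_percent:.1f}%"
        )
        return "\n".join(lines)

    def write_tsv(self, path: str | os.PathLike) -> Path:
        rows = [
            {
                "genome_id": genome,
                "total_genes": total,
                "flagged_genes": flagged,
                "percent_flagged": f"{pct:.1f}",
            }
            for genome, (total, flagged, pct) in sorted(self.per_genome.items())
        ]
        rows.append(
            {
                "genome_id": "POOLED",
                "total_genes": self.pooled_total,
                "flagged_genes": self.pooled_flagged,
                "percent_flagged": f"{self.pooled_percent:.1f}",
            }
        )
        return write_table(
            rows,
            ["genome_id", "total_genes", "flagged_genes", "percent_flagged"],
            path,
        )


# ----------------------------------------------------------------------
# hit tables
# ----------------------------------------------------------------------

def parse_hits_table(path: str | os.PathLike) -> list[tuple[str, str, float, float | None]]:
    """Parse a hits table into (gene_id, motif_id, score, evalue) tuples.

    Accepts the simple 3/4-column convention or full HMMER domtblout rows
    (whitespace-delimited; comment lines start with ``#``).
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read hits table: {path}")
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if len(fields) >= 22:  # full domtblout
                    gene, motif = fields[0], fields[3]
                    evalue: float | None = float(fields[6])
                    score = float(fields[7])
                elif len(fields) == 4:
                    gene, motif = fields[0], fields[1]
                    score = float(fields[2])
                    evalue = float(fields[3])
                elif len(fields) == 3:
                    gene, motif = fields[0], fields[1]
                    score = float(fields[2])
                    evalue = None
                else:
                    raise ValueError(f"{len(fields)} columns")
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: malformed hit row ({exc})") from exc
            if score < 0:
                raise InputError(f"{path}:{lineno}: negative score")
            out.append((gene, motif, score, evalue))
    return out


def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_score(query: str, exemplars: Mapping[str, str], k: int = DEFAULT_KMER_K) -> dict[str, float]:
    """Shared-k-mer score of ``query`` against each exemplar.

    score(motif) = |kmers(query) ∩ kmers(exemplar)| / len(query).  Zero
    scores are omitted.
    """
    if len(query) < k:
        return {}
    qk = _kmers(query, k)
    scores = {}
    for motif_id, ex in exemplars.items():
        shared = len(qk & _kmers(ex, k))
        if shared:
            scores[motif_id] = shared / len(query)
    return scores


# ----------------------------------------------------------------------
# flagging
# ----------------------------------------------------------------------

def flag_genes(
    genome: GenomeTable,
    library: MotifLibrary,
    hits_table: str | os.PathLike | None = None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    k: int = DEFAULT_KMER_K,
) -> list[DomainHit]:
    """Score every gene against the motif library and mark passing hits.

    A gene is *flagged* iff it has at least one hit with
    ``score >= score_threshold`` and (when an e-value is present)
    ``evalue <= evalue_threshold``.  Output is sorted by (gene_id,
    motif_id) and deterministic for fixed inputs.
    """
    if len(library) == 0:
        raise ConfigurationError("motif library is empty")
    known = set(genome.gene_ids)
    hits: list[DomainHit] = []

    if library.matcher_kind == "builtin_kmer":
        if not library.exemplars:
            raise ConfigurationError("builtin_kmer library has no exemplar sequences")
        for gene_id in sorted(genome.proteins):
            for motif_id, score in sorted(
                kmer_score(genome.proteins[gene_id], library.exemplars, k=k).items()
            ):
                hits.append(
                    DomainHit(gene_id, motif_id, score, None, score >= score_threshold)
                )
    elif library.matcher_kind in ("table", "external"):
        if hits_table is None:
            raise ConfigurationError(
                f"matcher_kind={library.matcher_kind!r} requires a hits table"
            )
        rows = parse_hits_table(hits_table)
        unknown = sorted({g for g, _, _, _ in rows if g not in known})
        if unknown:
            raise ValidationError(
                f"hits table references unknown gene_id(s): {', '.join(unknown)}"
            )
        lib_ids = library.motif_ids
        for gene, motif, score, evalue in sorted(rows):
            if motif not in lib_ids:
                continue  # hit against a motif outside the configured library
            passed = score >= score_threshold and (
                evalue is None or evalue <= evalue_threshold
            )
            hits.append(DomainHit(gene, motif, score, evalue, passed))
    else:
        raise ConfigurationError(f"unknown matcher_kind {library.matcher_kind!r}")
    return hits


def flagged_gene_ids(hits: Iterable[DomainHit]) -> set[str]:
    """Genes carrying at least one passed hit."""
    return {h.gene_id for h in hits if h.passed}


def passed_motifs_by_gene(hits: Iterable[DomainHit]) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {}
    for h in hits:
        if h.passed:
            out.setdefault(h.gene_id, set()).add(h.motif_id)
    return {g: frozenset(m) for g, m in out.items()}


def summarize_filter(
    all_hits: Mapping[str, Sequence[DomainHit]],
    all_tables: Mapping[str, GenomeTable],
) -> FilterSummary:
    """Per-genome and pooled flagged fractions across a multi-genome run."""
    if set(all_hits) != set(all_tables):
        missing = set(all_hits) ^ set(all_tables)
        raise ValidationError(f"genome mismatch between hits and tables: {sorted(missing)}")
    counts = {
        genome: (len(all_tables[genome].genes), len(flagged_gene_ids(all_hits[genome])))
        for genome in all_tables
    }
    return FilterSummary.from_counts(counts)
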
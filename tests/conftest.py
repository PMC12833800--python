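import random

import pytest

from bundlemine.bundler import Bundle
from bundlemine.genome_io import GenomeTable, assign_ordinals


def make_genome(genome_id, genes, proteins=None):
    """Build a GenomeTable from (scaffold, start, end, gene_id[, strand]) tuples."""
    raw = []
    for g in genes:
        scaffold, start, end, gene_id = g[:4]
        strand = g[4] if len(g) > 4 else "."
        raw.append((scaffold, start, end, gene_id, strand))
    return GenomeTable(
        genome_id=genome_id,
        genes=assign_ordinals(raw, genome_id),
        proteins=dict(proteins or {}),
    )


def make_bundle(bundle_id, signature, genome_id="G", scaffold="scf1", span=(0, 1)):
    """Minimal bundle carrying just what distance/co-occurrence logic needs."""
    sig = frozenset(signature)
    return Bundle(
        bundle_id=bundle_id,
        genome_id=genome_id,
        scaffold_id=scaffold,
        core_genes=tuple(f"{bundle_id}_g{i}" for i in range(2)),
        span=span,
        bp_span=(1, 1000),
        domain_signature=sig,
        domain_counts={m: 1 for m in sig},
        stage="initial",
    )


@pytest.fixture
def rng():
    return random.Random(20240917)


def write_gff3(path, rows, shuffle_with=None):
    """Write gene rows (scaffold, start, end, gene_id, strand) as GFF3."""
    rows = list(rows)
    if shuffle_with is not None:
        shuffle_with.shuffle(rows)
    lines = ["##gff-version 3"]
    for scaffold, start, end, gene_id, strand in rows:
        lines.append(
            f"{scaffold}\ttest\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_fasta(path, proteins):
    path.write_text("".join(f">{gid}\n{seq}\n" for gid, seq in proteins.items()))
    return path
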
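"""End-to-end orchestration: load -> flag -> bundle -> families -> screen -> co-occurrence.

Every stage is a pure function of its inputs and the run configuration;
the run manifest records all parameters plus SHA-256 checksums of every
input file so a run can be audited and reproduced bit-for-bit.  On
failure, partial outputs are retained next to a ``FAILED`` marker naming
the stage and offending file.
"""

from __future__ import annotations

import hashlib
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from . import cooccurrence as cooc
from . import family_network as fam
from . import phenotype_screen as pheno
from .bundler import Bundle, BundlingParams, bundle_genome, interspersed_genes
from .errors import BundlemineError, ConfigurationError, InputError
from .genome_io import (
    GenomeTable,
    load_genome,
    write_bundles_tsv,
    write_network,
    write_table,
)
from .motif_filter import (
    DEFAULT_EVALUE_THRESHOLD,
    DEFAULT_SCORE_THRESHOLD,
    MotifLibrary,
    flag_genes,
    summarize_filter,
)
from .synthetic import Fixture

logger = logging.getLogger(__name__)


@dataclass
class GenomeSpec:
    genome_id: str
    gff3: Path
    fasta: Path
    hits: Path | None = None  # required for the table matcher


@dataclass
class RunConfig:
    """Everything one pipeline run needs; see the YAML schema in the README."""

    genomes: list[GenomeSpec]
    motif_library: Path
    output_dir: Path
    matcher: str = "builtin_kmer"  # builtin_kmer | table
    score_threshold: float = DEFAULT_SCORE_THRESHOLD
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD
    bundling: BundlingParams = field(default_factory=BundlingParams)
    family_threshold: float = 0.5
    cooccurrence_threshold: float = 0.025
    phenotypes: Path | None = None
    feature_type: str = "gene"
    id_attribute: str = "ID"

    def validate(self) -> None:
        if not self.genomes:
            raise ConfigurationError("no genomes configured")
        for thr in (self.family_threshold, self.cooccurrence_threshold):
            if not 0.0 <= thr <= 1.0:
                raise ConfigurationError(f"threshold {thr} outside [0, 1]")
        for spec in self.genomes:
            for p in (spec.gff3, spec.fasta, spec.hits):
                if p is not None and not Path(p).is_file():
                    raise ConfigurationError(f"genome {spec.genome_id!r}: missing {p}")
            if self.matcher == "table" and spec.hits is None:
                raise ConfigurationError(
                    f"genome {spec.genome_id!r}: table matcher needs a hits file"
                )
        if not Path(self.motif_library).is_file():
            raise ConfigurationError(f"missing motif library: {self.motif_library}")
        if self.phenotypes is not None and not Path(self.phenotypes).is_file():
            raise ConfigurationError(f"missing phenotype table: {self.phenotypes}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        path = Path(path)
        if not path.is_file():
            raise InputError(f"cannot read config: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def _p(v):
            return (base / v).resolve() if v is not None else None

        genomes = [
            GenomeSpec(
                genome_id=g["genome_id"],
                gff3=_p(g["gff3"]),
                fasta=_p(g["fasta"]),
                hits=_p(g.get("hits")),
            )
            for g in raw.get("genomes", [])
        ]
        bundling = BundlingParams(**raw.get("bundling", {}))
        kwargs = dict(
            genomes=genomes,
            motif_library=_p(raw.get("motif_library")),
            output_dir=_p(raw.get("output_dir", "bundlemine_out")),
            matcher=raw.get("matcher", "builtin_kmer"),
            score_threshold=float(raw.get("score_threshold", DEFAULT_SCORE_THRESHOLD)),
            evalue_threshold=float(raw.get("evalue_threshold", DEFAULT_EVALUE_THRESHOLD)),
            bundling=bundling,
            family_threshold=float(raw.get("family_threshold", 0.5)),
            cooccurrence_threshold=float(raw.get("cooccurrence_threshold", 0.025)),
            phenotypes=_p(raw.get("phenotypes")),
            feature_type=raw.get("feature_type", "gene"),
            id_attribute=raw.get("id_attribute", "ID"),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_fixture(
        cls,
        fixture: Fixture,
        output_dir: str | os.PathLike,
        matcher: str = "builtin_kmer",
        **overrides,
    ) -> "RunConfig":
        """Configure a run directly over a generated synthetic fixture."""
        genomes = [
            GenomeSpec(
                genome_id=gid,
                gff3=files["gff3"],
                fasta=files["fasta"],
                hits=files["hits"],
            )
            for gid, files in sorted(fixture.genome_files.items())
        ]
        return cls(
            genomes=genomes,
            motif_library=fixture.motif_fasta,
            output_dir=Path(output_dir),
            matcher=matcher,
            phenotypes=fixture.phenotype_tsv,
            **overrides,
        )


@dataclass
class RunResult:
    """In-memory results of a full run (everything is also written to disk)."""

    output_dir: Path
    tables: dict[str, GenomeTable]
    bundles: list[Bundle]
    families: list[fam.BundleFamily]
    edges: list[fam.BundlePairDistance]
    filter_summary: object
    screen_report: pheno.ScreenReport | None
    cooccurrence_edges: list[cooc.CooccurrenceEdge]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> RunResult:
    """Execute the whole pipeline and write every output under output_dir."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "configure"
    try:
        t0 = time.monotonic()
        if config.matcher == "builtin_kmer" or str(config.motif_library).endswith(
            (".fa", ".faa", ".fasta")
        ):
            library = MotifLibrary.from_fasta(config.motif_library)
        else:
            library = MotifLibrary.from_motif_list(config.motif_library)
        if len(library) == 0:
            raise ConfigurationError(f"empty motif library: {config.motif_library}")
        if config.matcher == "table":
            library = MotifLibrary(library.motifs, matcher_kind="table")

        stage = "load"
        tables: dict[str, GenomeTable] = {}
        for spec in config.genomes:
            tables[spec.genome_id] = load_genome(
                spec.gff3,
                spec.fasta,
                genome_id=spec.genome_id,
                feature_type=config.feature_type,
                id_attribute=config.id_attribute,
            )
        logger.info("loaded %d genomes [%.2fs]", len(tables), time.monotonic() - t0)

        stage = "filter"
        all_hits = {}
        for spec in config.genomes:
            all_hits[spec.genome_id] = flag_genes(
                tables[spec.genome_id],
                library,
                hits_table=spec.hits if config.matcher == "table" else None,
                score_threshold=config.score_threshold,
                evalue_threshold=config.evalue_threshold,
            )
        summary = summarize_filter(all_hits, tables)
        summary.write_tsv(out / "filter_summary.tsv")
        logger.info("filter: %s", summary.render().splitlines()[-1])

        stage = "bundle"
        bundles: list[Bundle] = []
        inter_rows: list[dict] = []
        for gid in sorted(tables):
            genome_bundles = bundle_genome(tables[gid], all_hits[gid], config.bundling)
            bundles.extend(genome_bundles)
            inter_rows.extend(interspersed_genes(tables[gid], genome_bundles))
        write_bundles_tsv(bundles, out / "bundles.tsv")
        write_table(
            inter_rows,
            ["bundle_id", "genome_id", "scaffold_id", "gene_id", "ordinal", "start", "end"],
            out / "interspersed_genes.tsv",
        )
        logger.info("bundle: %d bundles", len(bundles))

        stage = "compare"
        families, edges = fam.build_families(bundles, threshold=config.family_threshold)
        write_table(
            [
                {
                    "bundle_a": e.bundle_a,
                    "bundle_b": e.bundle_b,
                    "jaccard": repr(e.jaccard),
                    "raw_distance": repr(e.raw_distance),
                }
                for e in sorted(edges, key=lambda e: (e.bundle_a, e.bundle_b))
            ],
            ["bundle_a", "bundle_b", "jaccard", "raw_distance"],
            out / "distances.tsv",
        )
        write_table(
            fam.families_to_rows(families),
            ["family_id", "n_members", "members", "genomes", "is_singleton"],
            out / "families.tsv",
        )
        write_network(
            [b.bundle_id for b in bundles],
            [(e.bundle_a, e.bundle_b, e.raw_distance) for e in edges],
            out / "family_network.graphml",
            format="graphml",
        )
        logger.info("compare: %d families", len(families))

        stage = "screen"
        report = None
        if config.phenotypes is not None:
            phen = pheno.load_phenotype_table(config.phenotypes)
            report = pheno.screen(families, phen)
            report.to_json(out / "screen_report.json")
            report.write_tsv(out / "screen_report.tsv")
            logger.info(
                "screen: %d multi-species, %d exclusive, %d universal",
                report.n_families_multi_species,
                report.n_exclusive_to_producers,
                report.n_in_all_producers,
            )

        stage = "cooccur"
        co_edges: list[cooc.CooccurrenceEdge] = []
        if bundles:
            co_edges = cooc.cooccurrence_network(
                bundles, prob_threshold=config.cooccurrence_threshold
            )
        write_table(
            cooc.edges_to_rows(co_edges),
            ["domain_a", "domain_b", "cooccurrence", "total_clusters", "probability"],
            out / "cooccurrence.tsv",
        )
        domains = sorted({m for b in bundles for m in b.domain_signature})
        write_network(
            domains,
            [(e.domain_a, e.domain_b, e.probability) for e in co_edges],
            out / "cooccurrence.graphml",
            format="graphml",
        )

        stage = "manifest"
        _write_run_manifest(config, out)
    except BundlemineError as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    return RunResult(
        output_dir=out,
        tables=tables,
        bundles=bundles,
        families=families,
        edges=edges,
        filter_summary=summary,
        screen_report=report,
        cooccurrence_edges=co_edges,
    )


def _write_run_manifest(config: RunConfig, out: Path) -> None:
    inputs: dict[str, str] = {}
    for spec in config.genomes:
        for key, p in (("gff3", spec.gff3), ("fasta", spec.fasta), ("hits", spec.hits)):
            if p is not None:
                inputs[f"{spec.genome_id}.{key}"] = _sha256(Path(p))
    inputs["motif_library"] = _sha256(Path(config.motif_library))
    if config.phenotypes is not None:
        inputs["phenotypes"] = _sha256(Path(config.phenotypes))
    manifest = {
        "parameters": {
            "matcher": config.matcher,
            "score_threshold": config.score_threshold,
            "evalue_threshold": config.evalue_threshold,
            "g1": config.bundling.g1,
            "g2": config.bundling.g2,
            "min_core": config.bundling.min_core,
            "family_threshold": config.family_threshold,
            "cooccurrence_threshold": config.cooccurrence_threshold,
            "feature_type": config.feature_type,
            "id_attribute": config.id_attribute,
        },
        "input_sha256": inputs,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
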
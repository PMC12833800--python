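"""Producer / non-producer comparison of bundle families.

Given a phenotype table (genome -> producer | nonproducer), report two
independent predicates over bundle families:

* *exclusive*: the family occurs in at least one producer genome and in
  no non-producer genome;
* *universal*: the family occurs in every producer genome.

Presence means at least one member bundle from that genome — copy number
is ignored.  By default only multi-species families enter the screen;
singleton families (one bundle in one species) are not comparable across
phenotypes and are counted separately.  A family that is both exclusive
and universal is the strongest candidate for the phenotype's pathway.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import InputError, ValidationError
from .family_network import BundleFamily
from .genome_io import write_table

PRODUCER = "producer"
NONPRODUCER = "nonproducer"


def load_phenotype_table(path: str | os.PathLike) -> dict[str, str]:
    """Read a 2-column TSV (genome_id, label); labels must be producer/nonproducer."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read phenotype table: {path}")
    table: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
            genome, label = parts
            if label not in (PRODUCER, NONPRODUCER):
                raise ValidationError(
                    f"{path}:{lineno}: label {label!r} is not producer/nonproducer"
                )
            if genome in table:
                raise ValidationError(f"{path}:{lineno}: duplicate genome {genome!r}")
            table[genome] = label
    return table


@dataclass
class ScreenReport:
    """Outcome of the producer/non-producer family screen."""

    n_families_multi_species: int
    n_exclusive_to_producers: int
    exclusive_family_ids: list[str]
    n_in_all_producers: int
    universal_family_ids: list[str]
    n_singletons: int
    producers: list[str]
    nonproducers: list[str]

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def write_tsv(self, path: str | os.PathLike) -> Path:
        exclusive = set(self.exclusive_family_ids)
        universal = set(self.universal_family_ids)
        rows = [
            {
                "family_id": fid,
                "exclusive_to_producers": str(fid in exclusive).lower(),
                "in_all_producers": str(fid in universal).lower(),
            }
            for fid in sorted(exclusive | universal)
        ]
        return write_table(
            rows, ["family_id", "exclusive_to_producers", "in_all_producers"], path
        )


def screen(
    families: Sequence[BundleFamily],
    phenotypes: Mapping[str, str],
    require_multi_species: bool = True,
) -> ScreenReport:
    """Screen families against producer phenotypes.

    Exclusivity and universality are computed independently (a family can
    be either, both, or neither).  With ``require_multi_species`` (the
    default) singleton families are excluded from the screened set, since
    a bundle seen in one species cannot show cross-species conservation.
    """
    genomes_seen = set()
    for f in families:
        genomes_seen |= f.genomes_present
    unlabeled = sorted(genomes_seen - set(phenotypes))
    if unlabeled:
        raise ValidationError(f"genome(s) without phenotype label: {', '.join(unlabeled)}")
    producers = sorted(g for g, lab in phenotypes.items() if lab == PRODUCER)
    nonproducers = sorted(g for g, lab in phenotypes.items() if lab == NONPRODUCER)
    if not producers:
        raise ValidationError("phenotype table contains no producer genome")

    producer_set = set(producers)
    nonproducer_set = set(nonproducers)

    screened = [
        f for f in families if not (require_multi_species and f.is_singleton)
    ]
    n_singletons = sum(1 for f in families if f.is_singleton)

    exclusive = [
        f.family_id
        for f in screened
        if f.genomes_present & producer_set and not f.genomes_present & nonproducer_set
    ]
    universal = [
        f.family_id for f in screened if producer_set <= f.genomes_present
    ]
    return ScreenReport(
        n_families_multi_species=len(screened),
        n_exclusive_to_producers=len(exclusive),
        exclusive_family_ids=sorted(exclusive),
        n_in_all_producers=len(universal),
        universal_family_ids=sorted(universal),
        n_singletons=n_singletons,
        producers=producers,
        nonproducers=nonproducers,
    )
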
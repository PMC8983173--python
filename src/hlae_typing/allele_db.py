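"""Reference allele database for the HLA-E promoter amplicon.

The database holds pre-aligned, equal-length reference sequences (one per
allele, plain A/C/G/T — references carry no ambiguity codes) together with a
map from symbolic regulatory-site labels such as ``NT-26`` to 0-based column
indices. The site label is purely symbolic: coordinates are configured, never
inferred, because promoter numbering conventions vary between sources.

Indel and gap handling is deliberately out of scope — the amplicon is a short
(~400 bp) promoter fragment and scoring stays positional and exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    DuplicateAlleleError,
    InputError,
    SiteConfigError,
    UnknownAlleleError,
)

log = logging.getLogger(__name__)

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class SiteSpec:
    """A named biallelic site: label, aligned column, reference/alternate base."""

    label: str
    index: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in _DNA or self.alt_base not in _DNA:
            raise SiteConfigError(
                f"site {self.label!r}: bases must be one of A/C/G/T, "
                f"got ref={self.ref_base!r} alt={self.alt_base!r}"
            )
        if self.ref_base == self.alt_base:
            raise SiteConfigError(f"site {self.label!r}: ref and alt bases are equal")
        if self.index < 0:
            raise SiteConfigError(f"site {self.label!r}: negative index {self.index}")


@dataclass(frozen=True)
class AlleleRecord:
    """One reference allele: id, aligned amplicon sequence, free-text metadata."""

    allele_id: str
    region_seq: str
    metadata: str = ""

    def __post_init__(self) -> None:
        if not self.region_seq:
            raise InputError(f"allele {self.allele_id!r}: empty sequence")
        bad = set(self.region_seq) - _DNA
        if bad:
            raise InputError(
                f"allele {self.allele_id!r}: reference sequences must be plain "
                f"A/C/G/T, found {sorted(bad)}"
            )


@dataclass
class AlleleDB:
    """Indexed collection of equal-length reference alleles plus a site map."""

    records: dict[str, AlleleRecord] = field(default_factory=dict)
    site_map: dict[str, SiteSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(r.region_seq) for r in self.records.values()}
        if len(lengths) > 1:
            raise AlignmentError(
                f"reference sequences are not equal length: found lengths {sorted(lengths)}"
            )
        for site in self.site_map.values():
            self._check_site(site)

    @property
    def seq_length(self) -> int:
        if not self.records:
            return 0
        return len(next(iter(self.records.values())).region_seq)

    @property
    def allele_ids(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, allele_id: str) -> bool:
        return allele_id in self.records

    def _check_site(self, site: SiteSpec) -> None:
        if self.records and not 0 <= site.index < self.seq_length:
            raise SiteConfigError(
                f"site {site.label!r}: index {site.index} outside aligned "
                f"sequences of length {self.seq_length}"
            )
        if self.records and not any(
            r.region_seq[site.index] == site.ref_base for r in self.records.values()
        ):
            raise SiteConfigError(
                f"site {site.label!r}: reference base {site.ref_base!r} matches "
                f"no allele at column {site.index}"
            )

    def record(self, allele_id: str) -> AlleleRecord:
        try:
            return self.records[allele_id]
        except KeyError:
            raise UnknownAlleleError(f"unknown allele id {allele_id!r}") from None

    def site(self, label: str) -> SiteSpec:
        try:
            return self.site_map[label]
        except KeyError:
            raise UnknownAlleleError(f"unknown site label {label!r}") from None


def base_at(db: AlleleDB, allele_id: str, site: str | SiteSpec) -> str:
    """Reference base of ``allele_id`` at a named site (or an explicit SiteSpec)."""
    spec = db.site(site) if isinstance(site, str) else site
    return db.record(allele_id).region_seq[spec.index]


def _parse_site_config(site_config: str | Path | Mapping) -> dict[str, SiteSpec]:
    """Accept a YAML path or an in-memory mapping ``{label: {index, ref, alt}}``."""
    if isinstance(site_config, (str, Path)):
        with open(site_config) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(site_config)
    if isinstance(raw, Mapping) and "sites" in raw:
        raw = raw["sites"]
    if not isinstance(raw, Mapping) or not raw:
        raise SiteConfigError("site config must map site labels to {index, ref, alt}")
    sites = {}
    for label, entry in raw.items():
        try:
            sites[str(label)] = SiteSpec(
                label=str(label),
                index=int(entry["index"]),
                ref_base=str(entry["ref"]).upper(),
                alt_base=str(entry["alt"]).upper(),
            )
        except (KeyError, TypeError) as exc:
            raise SiteConfigError(f"site {label!r}: malformed entry {entry!r}") from exc
    return sites


def load_allele_db(
    fasta_path: str | Path, site_config: str | Path | Mapping
) -> AlleleDB:
    """Load pre-aligned reference alleles from FASTA and attach the site map.

    The first whitespace-delimited header token is the allele id; the remainder
    is kept as free-text metadata. Duplicate ids, unequal lengths, empty files
    and out-of-bounds site indices are all rejected.
    """
    records: dict[str, AlleleRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        allele_id = rec.id
        if allele_id in records:
            raise DuplicateAlleleError(f"duplicate allele id {allele_id!r} in {fasta_path}")
        meta = rec.description[len(rec.id):].strip() if rec.description else ""
        records[allele_id] = AlleleRecord(
            allele_id=allele_id, region_seq=str(rec.seq).upper(), metadata=meta
        )
    if not records:
        raise InputError(f"no FASTA records found in {fasta_path}")
    db = AlleleDB(records=records, site_map=_parse_site_config(site_config))
    log.info(
        "loaded %d reference alleles (length %d nt, %d sites) from %s",
        len(db), db.seq_length, len(db.site_map), fasta_path,
    )
    return db


def write_fasta(db: AlleleDB, path: str | Path) -> None:
    """Write the reference alleles back to FASTA (round-trips with load)."""
    recs: Iterable[SeqRecord] = (
        SeqRecord(Seq(r.region_seq), id=r.allele_id, description=r.metadata)
        for r in db.records.values()
    )
    SeqIO.write(recs, str(path), "fasta")
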
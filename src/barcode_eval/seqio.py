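"""Aligned-FASTA input/output, dataset filters and multi-locus concatenation.

Sequences are gapped, pre-aligned barcode records whose FASTA headers carry
both a sample identifier and a binomial species label, e.g.::

    >MK1234|Dendrobium_nobile

The header dialect (separator and field order) is configurable. Filters
implement the sampling rules used throughout the package: a minimum ungapped
length (default 300 bp, with an exemption set for short loci such as ITS2),
a per-species cap (default 20 individuals, keeping the longest), and deletion
of singleton species ahead of similarity-based matching.

Coordinates are 0-based and half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import (
    DuplicateSampleError,
    HeaderParseError,
    InputError,
    RaggedAlignmentError,
)

__all__ = [
    "HeaderDialect",
    "SeqRecord",
    "LocusAlignment",
    "ConcatAlignment",
    "FilterEntry",
    "FilterLog",
    "read_alignment",
    "write_alignment",
    "apply_sampling_filters",
    "drop_singleton_species",
    "concatenate",
]

# gap/ambiguity-tolerant DNA alphabet after normalisation
_ALLOWED = frozenset("ACGTRYSWKMBDHVN-")
_NORMALISE = str.maketrans({"U": "T", ".": "-", "?": "N"})


@dataclass(frozen=True)
class HeaderDialect:
    """How FASTA headers encode sample and species.

    ``fields`` gives the order of the two mandatory fields around
    ``separator``; extra trailing fields are ignored.
    """

    separator: str = "|"
    fields: tuple[str, str] = ("sample_id", "species")

    def parse(self, header: str) -> tuple[str, str]:
        parts = header.strip().split(self.separator)
        if len(parts) < 2:
            raise HeaderParseError(
                f"header {header!r} lacks separator {self.separator!r}"
            )
        values = dict(zip(self.fields, parts))
        sample_id, species = values["sample_id"], values["species"]
        if not sample_id or not species:
            raise HeaderParseError(f"header {header!r} has an empty field")
        return sample_id, species

    def format(self, sample_id: str, species: str) -> str:
        values = {"sample_id": sample_id, "species": species}
        return self.separator.join(values[f] for f in self.fields)


DEFAULT_DIALECT = HeaderDialect()


@dataclass(frozen=True)
class SeqRecord:
    """One aligned sequence: an individual of a species at one locus."""

    sample_id: str
    species: str
    locus: str
    residues: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise InputError("sample_id must be non-empty")
        if not self.species:
            raise InputError("species must be non-empty")
        if not self.residues:
            raise InputError(f"record {self.sample_id}: empty residues")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise InputError(
                f"record {self.sample_id}: illegal residues {sorted(bad)}"
            )

    @property
    def ungapped_length(self) -> int:
        """Number of determinate bases: gaps and N excluded."""
        return len(self.residues) - self.residues.count("-") - self.residues.count("N")


@dataclass
class LocusAlignment:
    """A gapped multiple alignment of one barcode locus.

    May be empty (e.g. after singleton deletion removed everything);
    downstream operations reject empty alignments.
    """

    locus: str
    records: list[SeqRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise DuplicateSampleError(
                    f"duplicate sample_id {rec.sample_id!r} in locus {self.locus}"
                )
            seen.add(rec.sample_id)
        if self.records:
            width = len(self.records[0].residues)
            for rec in self.records:
                if len(rec.residues) != width:
                    raise RaggedAlignmentError(
                        f"record {rec.sample_id!r} has {len(rec.residues)} columns, "
                        f"expected {width}"
                    )

    @property
    def length(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.species] = counts.get(rec.species, 0) + 1
        return counts

    def species_of(self) -> dict[str, str]:
        return {rec.sample_id: rec.species for rec in self.records}


@dataclass
class ConcatAlignment:
    """Concatenation of several loci over the samples shared by all of them."""

    loci: list[str]
    partitions: list[tuple[str, int, int]]  # (locus, start, end), half-open
    records: list[SeqRecord]

    @property
    def locus(self) -> str:
        return "+".join(self.loci)

    @property
    def length(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def __len__(self) -> int:
        return len(self.records)

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.species] = counts.get(rec.species, 0) + 1
        return counts

    def species_of(self) -> dict[str, str]:
        return {rec.sample_id: rec.species for rec in self.records}


@dataclass(frozen=True)
class FilterEntry:
    sample_id: str
    species: str
    locus: str
    reason: str  # "min_len" | "species_cap" | "singleton"
    detail: str = ""


@dataclass
class FilterLog:
    entries: list[FilterEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, rec: SeqRecord, reason: str, detail: str = "") -> None:
        self.entries.append(
            FilterEntry(rec.sample_id, rec.species, rec.locus, reason, detail)
        )


def read_alignment(
    path: str | Path,
    locus: str,
    dialect: HeaderDialect = DEFAULT_DIALECT,
) -> LocusAlignment:
    """Read a gapped FASTA alignment, normalising residues to uppercase DNA.

    Lowercase is uppercased, U mapped to T, '.' to '-' and '?' to 'N'.
    Ragged alignments, duplicate sample ids and unparseable headers raise
    hard errors (headers with the offending line number).
    """
    path = Path(path)
    # map record index -> 1-based line number of its '>' header
    header_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines.append(lineno)
    records: list[SeqRecord] = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        try:
            sample_id, species = dialect.parse(rec.description)
        except HeaderParseError as exc:
            raise HeaderParseError(f"{path}:{header_lines[idx]}: {exc}") from None
        residues = str(rec.seq).upper().translate(_NORMALISE)
        records.append(SeqRecord(sample_id, species, locus, residues))
    if not records:
        raise InputError(f"{path}: no FASTA records")
    return LocusAlignment(locus=locus, records=records)


def write_alignment(
    aln: LocusAlignment | ConcatAlignment,
    path: str | Path,
    dialect: HeaderDialect = DEFAULT_DIALECT,
    width: int = 70,
) -> None:
    """Write FASTA; for a ConcatAlignment also write ``<path>.partitions.tsv``.

    Round-trip stable with :func:`read_alignment`.
    """
    if not aln.records:
        raise InputError("refusing to write an empty alignment")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in aln.records:
            fh.write(">" + dialect.format(rec.sample_id, rec.species) + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
    if isinstance(aln, ConcatAlignment):
        side = path.with_name(path.name + ".partitions.tsv")
        with open(side, "w") as fh:
            fh.write("locus\tstart\tend\n")
            for locus, start, end in aln.partitions:
                fh.write(f"{locus}\t{start}\t{end}\n")


def apply_sampling_filters(
    aln: LocusAlignment,
    min_len: int = 300,
    max_per_species: int = 20,
    exempt_min_len: Iterable[str] = ("ITS2",),
) -> tuple[LocusAlignment, FilterLog]:
    """Apply the dataset sampling rules to one locus.

    Records with fewer than ``min_len`` determinate bases are dropped
    (unless the locus is exempt, as for short ITS2 fragments); species with
    more than ``max_per_species`` individuals are truncated to the longest
    ungapped sequences, ties broken by sample_id. Idempotent.
    """
    log = FilterLog()
    exempt = set(exempt_min_len)
    kept = []
    for rec in aln.records:
        if aln.locus not in exempt and rec.ungapped_length < min_len:
            log.add(rec, "min_len", f"ungapped {rec.ungapped_length} < {min_len}")
        else:
            kept.append(rec)

    by_species: dict[str, list[SeqRecord]] = {}
    for rec in kept:
        by_species.setdefault(rec.species, []).append(rec)
    drop: set[str] = set()
    for species, recs in by_species.items():
        if len(recs) > max_per_species:
            ranked = sorted(recs, key=lambda r: (-r.ungapped_length, r.sample_id))
            for rec in ranked[max_per_species:]:
                log.add(rec, "species_cap", f"> {max_per_species} individuals")
                drop.add(rec.sample_id)
    kept = [rec for rec in kept if rec.sample_id not in drop]
    if not kept:
        raise InputError(
            f"locus {aln.locus}: sampling filters removed every record"
        )
    return LocusAlignment(locus=aln.locus, records=kept), log


def drop_singleton_species(
    aln: LocusAlignment,
) -> tuple[LocusAlignment, list[str]]:
    """Delete all species represented by a single sequence.

    Required before best-match / best-close-match analysis. May return an
    empty alignment; downstream operations must reject it.
    """
    counts = aln.species_counts()
    removed = sorted(sp for sp, n in counts.items() if n < 2)
    kept = [rec for rec in aln.records if counts[rec.species] >= 2]
    return LocusAlignment(locus=aln.locus, records=kept), removed


def concatenate(alns: Sequence[LocusAlignment]) -> ConcatAlignment:
    """Join loci over the samples present in every input (intersection join).

    Residues are concatenated in the given locus order; partition ranges are
    recorded. A sample labelled with different species at two loci is an
    error.
    """
    if len(alns) < 2:
        raise InputError("concatenation needs at least two loci")
    shared = set(alns[0].species_of())
    for aln in alns[1:]:
        shared &= set(aln.species_of())
    if not shared:
        raise InputError(
            "no sample is present in all loci: " + "+".join(a.locus for a in alns)
        )
    by_locus = [{rec.sample_id: rec for rec in aln.records} for aln in alns]
    for sid in shared:
        species = {table[sid].species for table in by_locus}
        if len(species) > 1:
            raise InputError(
                f"sample {sid!r} has conflicting species labels across loci: "
                f"{sorted(species)}"
            )
    loci = [aln.locus for aln in alns]
    partitions: list[tuple[str, int, int]] = []
    start = 0
    for aln in alns:
        partitions.append((aln.locus, start, start + aln.length))
        start += aln.length
    joined = "+".join(loci)
    # keep the record order of the first locus for determinism
    order = [rec.sample_id for rec in alns[0].records if rec.sample_id in shared]
    records = [
        SeqRecord(
            sample_id=sid,
            species=by_locus[0][sid].species,
            locus=joined,
            residues="".join(table[sid].residues for table in by_locus),
        )
        for sid in order
    ]
    return ConcatAlignment(loci=loci, partitions=partitions, records=records)
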
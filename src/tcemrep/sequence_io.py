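"""Sequence input/output, curation and the repertoire data model.

All residue coordinates in this package are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Residue alphabet accepted in records: the 20 standard amino acids plus X
#: (ambiguous).  Windows containing X are skipped during motif extraction.
VALID_RESIDUES = frozenset(AA20) | {"X"}

CLASS_LABELS = frozenset({"IgG", "IgM", "IgE", "IgA", "IgD", "unknown"})

#: Length (residues) at which variable-region sequences are truncated by
#: default during curation.
DEFAULT_MAX_LENGTH = 130


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed into valid records."""


class CurationError(ValueError):
    """Raised when curation removes every record."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single amino-acid sequence with repertoire annotations.

    Parameters
    ----------
    id : str
        Unique accession-like identifier.
    residues : str
        Upper-case amino-acid string over the 20-letter alphabet plus X.
    description : str
        Free text carried from the FASTA header.
    class_label : str
        One of IgG, IgM, IgE, IgA, IgD or ``unknown``.
    is_germline : bool
        True for germline reference sequences.
    """

    id: str
    residues: str
    description: str = ""
    class_label: str = "unknown"
    is_germline: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue characters {sorted(bad)!r}"
            )
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"record {self.id!r}: class_label {self.class_label!r} not one of "
                f"{sorted(CLASS_LABELS)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class RepertoireDataset:
    """An ordered, curated collection of sequence records.

    Invariants: record ids are unique; if ``max_length_applied`` is set every
    record length is at most that value.
    """

    records: list[SequenceRecord]
    max_length_applied: int | None = None
    provenance: str = ""
    germline_reference: list[SequenceRecord] | None = None
    _by_id: dict[str, SequenceRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for rec in self.records:
            if rec.id in self._by_id:
                raise ValueError(f"duplicate record id {rec.id!r} in dataset")
            if self.max_length_applied is not None and len(rec) > self.max_length_applied:
                raise ValueError(
                    f"record {rec.id!r} length {len(rec)} exceeds "
                    f"max_length_applied={self.max_length_applied}"
                )
            self._by_id[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def get(self, record_id: str) -> SequenceRecord:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    The header token before the first whitespace becomes the record id and
    residues are upper-cased.  Invalid residue characters raise
    :class:`FastaParseError` naming the offending line.  An empty file
    returns an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython is lenient
        raise FastaParseError(f"{path}: {exc}") from exc
    text = path.read_text()
    if not parsed:
        if text.strip():
            raise FastaParseError(f"{path}: no FASTA records found in non-empty file")
        warnings.warn(f"{path}: empty FASTA file, returning no records", stacklevel=2)
        return []

    records: list[SequenceRecord] = []
    for seqrec in parsed:
        residues = str(seqrec.seq).upper()
        bad = set(residues) - VALID_RESIDUES
        if bad:
            line_no = _find_line(text, sorted(bad)[0], seqrec.id)
            raise FastaParseError(
                f"{path}:{line_no}: entry {seqrec.id!r} contains invalid residue "
                f"characters {sorted(bad)!r}"
            )
        records.append(
            SequenceRecord(
                id=seqrec.id,
                residues=residues,
                description=seqrec.description,
            )
        )
    return records


def _find_line(text: str, bad_char: str, entry_id: str) -> int:
    """Best-effort line number of the first occurrence of *bad_char* in the
    sequence lines following the header of *entry_id*."""
    in_entry = False
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            in_entry = line[1:].split()[0] == entry_id if line[1:].split() else False
            continue
        if in_entry and bad_char in line.upper():
            return i
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as multi-line FASTA wrapped at *width* columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else (
                f"{rec.id} {rec.description}" if not rec.description.startswith(rec.id)
                else rec.description
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def curate(
    records: Sequence[SequenceRecord],
    max_length: int = DEFAULT_MAX_LENGTH,
    deduplicate: bool = True,
    dedup_by_sequence: bool = False,
    germline_reference: Sequence[SequenceRecord] | None = None,
) -> RepertoireDataset:
    """Curate raw records into a :class:`RepertoireDataset`.

    Records longer than *max_length* are truncated to their first
    *max_length* residues.  Duplicate ids are removed keeping the first
    occurrence; ``dedup_by_sequence=True`` additionally drops records whose
    full residue string was already seen.  Counts of truncations and
    removals are recorded in ``provenance``.
    """
    if not records:
        raise CurationError("cannot curate an empty record collection")

    seen_ids: set[str] = set()
    seen_seqs: set[str] = set()
    kept: list[SequenceRecord] = []
    n_truncated = 0
    n_dup_id = 0
    n_dup_seq = 0
    for rec in records:
        if deduplicate and rec.id in seen_ids:
            n_dup_id += 1
            continue
        if len(rec) > max_length:
            rec = replace(rec, residues=rec.residues[:max_length])
            n_truncated += 1
        if dedup_by_sequence:
            if rec.residues in seen_seqs:
                n_dup_seq += 1
                continue
            seen_seqs.add(rec.residues)
        seen_ids.add(rec.id)
        kept.append(rec)

    if not kept:
        raise CurationError("empty after curation")

    provenance = (
        f"curate: kept={len(kept)} truncated={n_truncated} "
        f"duplicate_ids_removed={n_dup_id} duplicate_sequences_removed={n_dup_seq} "
        f"max_length={max_length}"
    )
    return RepertoireDataset(
        records=kept,
        max_length_applied=max_length,
        provenance=provenance,
        germline_reference=list(germline_reference) if germline_reference else None,
    )


MOTIF_TABLE_COLUMNS = (
    "motif",
    "register",
    "molecule_count",
    "instance_count",
    "frequency_class",
    "origin",
)


def write_motif_table(table, path: str | Path, origins: dict[str, str] | None = None) -> None:
    """Write a motif frequency table as TSV with stable lexicographic motif
    ordering.

    Columns: motif, register, molecule_count, instance_count,
    frequency_class, origin.  Origin is taken from the optional *origins*
    mapping (motif letters -> ``germline``/``SHM``) and written as ``NA``
    when unknown.
    """
    from tcemrep.frequency_analysis import assign_frequency_class

    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(MOTIF_TABLE_COLUMNS) + "\n")
        for motif in sorted(table.entries):
            entry = table.entries[motif]
            fc = assign_frequency_class(entry.molecule_count, table.total_molecules)
            origin = (origins or {}).get(motif, "NA")
            fh.write(
                f"{motif}\t{table.register}\t{entry.molecule_count}\t"
                f"{entry.instance_count}\t{fc}\t{origin}\n"
            )


def read_motif_table(path: str | Path):
    """Read a TSV written by :func:`write_motif_table` back into a
    :class:`~tcemrep.frequency_analysis.MotifFrequencyTable`.

    Position histograms are not stored in the TSV and come back empty;
    ``total_molecules`` is recovered as the maximum molecule count, which is
    exact whenever some motif occurs in every molecule and a lower bound
    otherwise (the frequency_class column preserves the original classes).
    """
    import pandas as pd

    from tcemrep.frequency_analysis import MotifEntry, MotifFrequencyTable

    df = pd.read_csv(path, sep="\t", dtype={"motif": str})
    missing = set(MOTIF_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing motif-table columns {sorted(missing)}")
    registers = set(df["register"])
    if len(registers) > 1:
        raise ValueError(f"{path}: mixed registers {sorted(registers)} in one table")
    register = registers.pop() if registers else "TCEM_I"
    entries = {
        str(row.motif): MotifEntry(
            molecule_count=int(row.molecule_count),
            instance_count=int(row.instance_count),
        )
        for row in df.itertuples()
    }
    total_molecules = max((e.molecule_count for e in entries.values()), default=0)
    total_instances = sum(e.instance_count for e in entries.values())
    return MotifFrequencyTable(
        register=register,
        entries=entries,
        total_molecules=total_molecules,
        total_instances=total_instances,
    ), df
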
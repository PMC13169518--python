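"""Reading, validating, filtering and writing labelled protein sequence sets.

Sequences travel through the pipeline as :class:`SequenceDataset` objects:
ordered collections of :class:`LabeledSequence` records (amino-acid string +
optional binary G4-binder label).  FASTA is the on-disk sequence format and a
two-column TSV (``id<TAB>label``) carries the labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical; also the one-hot column order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Letters that appear in real proteomes but are not one of the standard 20
#: (ambiguity codes B/J/Z, selenocysteine U, pyrrolysine O, unknown X).
NONSTANDARD_AA = set("BJOUXZ")

_VALID_LETTERS = set(STANDARD_AA) | NONSTANDARD_AA


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


@dataclass(frozen=True)
class LabeledSequence:
    """A protein sequence with an identifier and optional binary binder label."""

    id: str
    residues: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label for {self.id!r} must be 0 or 1, got {self.label!r}")
        bad = set(self.residues) - _VALID_LETTERS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-amino-acid letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceDataset:
    """An ordered, id-unique collection of labelled sequences."""

    records: list[LabeledSequence] = field(default_factory=list)
    provenance: str = "raw"

    def __post_init__(self) -> None:
        dupes = _duplicated_ids(self.records)
        if dupes:
            raise ValueError(f"duplicate sequence ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LabeledSequence]:
        return iter(self.records)

    def __getitem__(self, seq_id: str) -> LabeledSequence:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, ids: Iterable[str], provenance: str | None = None) -> "SequenceDataset":
        keep = set(ids)
        return SequenceDataset(
            [r for r in self.records if r.id in keep],
            provenance=provenance or self.provenance,
        )

    def label_counts(self) -> dict[int | None, int]:
        counts: dict[int | None, int] = {}
        for rec in self.records:
            counts[rec.label] = counts.get(rec.label, 0) + 1
        return counts


def _duplicated_ids(records: Iterable[LabeledSequence]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for rec in records:
        if rec.id in seen:
            dupes.add(rec.id)
        seen.add(rec.id)
    return dupes


def _validate_fasta_lines(path: Path) -> None:
    # SeqIO is forgiving; do a strict structural pass first so errors carry
    # line numbers.
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if len(stripped) == 1:
                    raise FastaParseError(f"{path}:{lineno}: header line has no identifier")
                in_record = True
            elif not in_record:
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before any '>' header"
                )


def read_fasta(
    path: str | Path,
    label_table: Mapping[str, int] | None = None,
) -> SequenceDataset:
    """Read a FASTA file into a :class:`SequenceDataset`.

    Residues are upper-cased and internal whitespace is stripped.  Labels are
    attached where ``label_table`` provides them (ids absent from the table get
    ``label=None``).  Duplicate ids raise, listing the offenders; a file with
    no records yields an empty dataset with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_fasta_lines(path)

    records: list[LabeledSequence] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        residues = "".join(str(entry.seq).split()).upper()
        label = None if label_table is None else label_table.get(entry.id)
        records.append(LabeledSequence(id=entry.id, residues=residues, label=label))

    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return SequenceDataset(records, provenance="raw")


def write_fasta(ds: SequenceDataset, path: str | Path) -> None:
    """Write the dataset as multi-record FASTA (60-column wrapped)."""
    recs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in ds]
    SeqIO.write(recs, str(path), "fasta")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read an ``id<TAB>label`` TSV (header optional) into a dict."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label'")
            if lineno == 1 and parts[1].lower() == "label":
                continue
            table[parts[0]] = int(parts[1])
    return table


def write_label_table(ds: SequenceDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for rec in ds:
            if rec.label is not None:
                fh.write(f"{rec.id}\t{rec.label}\n")


def deduplicate(ds: SequenceDataset) -> SequenceDataset:
    """Collapse exact residue-string duplicates, keeping the first occurrence.

    Near-duplicates are the job of the 90 %-identity clustering round, not of
    this step.
    """
    seen: set[str] = set()
    kept: list[LabeledSequence] = []
    for rec in ds:
        if rec.residues in seen:
            continue
        seen.add(rec.residues)
        kept.append(rec)
    removed = len(ds) - len(kept)
    if removed:
        logger.info("deduplicate: removed %d exact-duplicate sequences", removed)
    return SequenceDataset(kept, provenance="deduplicated")


def length_filter(
    ds: SequenceDataset, min_len: int = 50, max_len: int = 2500
) -> SequenceDataset:
    """Retain sequences with ``min_len <= length <= max_len`` (closed interval).

    The default bounds drop fragments too short to carry signal and outliers
    long enough to destabilise batched training.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    kept = [r for r in ds if min_len <= len(r) <= max_len]
    removed_per_class: dict[int | None, int] = {}
    for r in ds:
        if not (min_len <= len(r) <= max_len):
            removed_per_class[r.label] = removed_per_class.get(r.label, 0) + 1
    if removed_per_class:
        logger.info("length_filter: removed per class %s", removed_per_class)
    if not kept:
        logger.warning("length_filter: no sequences left after filtering")
    return SequenceDataset(kept, provenance="length-filtered")


def relabel(ds: SequenceDataset, label_table: Mapping[str, int]) -> SequenceDataset:
    """Return a copy of ``ds`` with labels attached from ``label_table``."""
    return SequenceDataset(
        [replace(r, label=label_table.get(r.id, r.label)) for r in ds],
        provenance=ds.provenance,
    )
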
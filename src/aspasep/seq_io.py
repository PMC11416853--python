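"""FASTA input/output, sequence validation and labeled datasets.

Sequences are validated against the canonical 20-letter amino-acid
alphabet.  Residues outside it (B, J, O, U, X, Z, ``*``) are handled by a
:class:`ResiduePolicy`:

``strict``
    any non-standard residue raises :class:`SequenceValidationError`;
``drop_record``
    the whole record is discarded (default — keeps descriptor and
    feature matrices aligned across stages);
``mask_skip``
    offending characters are removed and the record kept.

Input is case-insensitive; sequences are upper-cased on read and gap
characters (``-``, ``.``) are stripped with a warning.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import AMINO_ACIDS

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset(AMINO_ACIDS)
GAP_CHARACTERS = frozenset("-.")


class SequenceValidationError(ValueError):
    """A sequence failed residue validation under the strict policy."""


class FastaFormatError(ValueError):
    """The input file is not parseable FASTA."""


class DatasetError(ValueError):
    """A labeled dataset violates its invariants."""


class ResiduePolicy(str, Enum):
    STRICT = "strict"
    DROP_RECORD = "drop_record"
    MASK_SKIP = "mask_skip"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with an identifier and optional class label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: str) -> "ProteinRecord":
        return replace(self, label=label)


@dataclass(frozen=True)
class LabeledDataset:
    """An ordered two-class collection of protein records.

    Invariants: exactly two distinct class names, every record labeled
    with one of them, ids unique across the dataset.
    """

    records: tuple[ProteinRecord, ...]
    class_names: tuple[str, str]

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != 2:
            raise DatasetError(f"need two distinct class names, got {self.class_names}")
        ids = Counter(r.id for r in self.records)
        dupes = [i for i, c in ids.items() if c > 1]
        if dupes:
            raise DatasetError(f"duplicate record ids: {dupes[:5]}")
        stray = {r.label for r in self.records} - set(self.class_names)
        if stray:
            raise DatasetError(f"records with labels outside class_names: {stray}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(r.label for r in self.records)
        return {name: c.get(name, 0) for name in self.class_names}

    def subset(self, label: str) -> tuple[ProteinRecord, ...]:
        return tuple(r for r in self.records if r.label == label)


def _clean_sequence(
    raw: str, record_id: str, policy: ResiduePolicy
) -> str | None:
    """Upper-case, strip gaps, apply the residue policy.

    Returns the cleaned sequence, or None when the record is dropped.
    """
    seq = raw.upper()
    gaps = set(seq) & GAP_CHARACTERS
    if gaps:
        logger.warning("record %s: stripping gap characters %s", record_id, sorted(gaps))
        seq = "".join(c for c in seq if c not in GAP_CHARACTERS)
    bad = set(seq) - VALID_RESIDUES
    if not bad:
        return seq
    if policy is ResiduePolicy.STRICT:
        raise SequenceValidationError(
            f"record {record_id!r}: non-standard residues {sorted(bad)}"
        )
    if policy is ResiduePolicy.DROP_RECORD:
        logger.warning(
            "record %s: dropped (non-standard residues %s)", record_id, sorted(bad)
        )
        return None
    # mask_skip: remove offending characters, keep the record
    logger.warning(
        "record %s: removed non-standard residues %s", record_id, sorted(bad)
    )
    seq = "".join(c for c in seq if c in VALID_RESIDUES)
    return seq if seq else None


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(
    path: str | Path,
    label: str | None = None,
    residue_policy: ResiduePolicy | str = ResiduePolicy.DROP_RECORD,
) -> list[ProteinRecord]:
    """Read a (possibly gzipped) FASTA file into validated records.

    The record id is the first whitespace-delimited token of the header.
    Input order is preserved; records removed by the residue policy are
    counted in the log.
    """
    path = Path(path)
    policy = ResiduePolicy(residue_policy)
    records: list[ProteinRecord] = []
    n_seen = 0
    with _open_maybe_gzip(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            n_seen += 1
            raw = str(entry.seq)
            if not raw:
                raise FastaFormatError(
                    f"{path}: entry {entry.id!r} has no sequence lines"
                )
            seq = _clean_sequence(raw, entry.id, policy)
            if seq is None:
                continue
            records.append(ProteinRecord(id=entry.id, sequence=seq, label=label))
    if n_seen == 0:
        logger.warning("%s: no FASTA entries found", path)
    dropped = n_seen - len(records)
    if dropped:
        logger.warning("%s: %d of %d records dropped by residue policy", path, dropped, n_seen)
    return records


def write_fasta(
    records: Iterable[ProteinRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records as FASTA (gzipped if the path ends in .gz)."""
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with _open_maybe_gzip(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(seq_records)


def build_dataset(
    group_a: Sequence[ProteinRecord], group_b: Sequence[ProteinRecord]
) -> LabeledDataset:
    """Merge two labeled groups into a validated two-class dataset.

    Both groups must be non-empty, carry distinct labels, and share no ids.
    """
    if not group_a or not group_b:
        raise DatasetError("both groups must be non-empty")
    labels_a = {r.label for r in group_a}
    labels_b = {r.label for r in group_b}
    if len(labels_a) != 1 or len(labels_b) != 1:
        raise DatasetError(
            f"each group must have one uniform label, got {labels_a} and {labels_b}"
        )
    (name_a,) = labels_a
    (name_b,) = labels_b
    if name_a is None or name_b is None:
        raise DatasetError("group records must be labeled")
    if name_a == name_b:
        raise DatasetError(f"class names must differ, both are {name_a!r}")
    shared = {r.id for r in group_a} & {r.id for r in group_b}
    if shared:
        raise DatasetError(f"ids present in both groups: {sorted(shared)[:5]}")
    return LabeledDataset(
        records=tuple(group_a) + tuple(group_b), class_names=(name_a, name_b)
    )


def load_two_class_fasta(
    path_a: str | Path,
    path_b: str | Path,
    label_a: str,
    label_b: str,
    residue_policy: ResiduePolicy | str = ResiduePolicy.DROP_RECORD,
) -> LabeledDataset:
    """Convenience: read two FASTA files and assemble a labeled dataset."""
    return build_dataset(
        read_fasta(path_a, label=label_a, residue_policy=residue_policy),
        read_fasta(path_b, label=label_b, residue_policy=residue_policy),
    )
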
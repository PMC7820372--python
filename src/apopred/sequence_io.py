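"""FASTA input/output, sequence validation and labelled datasets.

Sequences are plain strings over the standard 20-letter amino-acid
alphabet; labels ride either in the FASTA header after a ``|`` separator
(``>P12345|ApoA``) or in a separate two-column TSV table (``id<TAB>label``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: residue -> index into the alphabetically ordered alphabet
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

BINARY_LABELS = ("apo", "non-apo")
SUBFAMILY_LABELS = ("ApoA", "ApoB", "ApoC", "ApoD", "ApoE", "ApoL", "Apoelse")


class SequenceIOError(ValueError):
    """Malformed FASTA/label input or an invariant violation."""


def validate_sequence(sequence: str) -> frozenset[str]:
    """Return the set of characters outside the 20-letter alphabet.

    An empty return value means every character is a standard residue
    (ambiguity codes such as B, J, O, U, X and Z are reported as
    offending). Total function: never raises.
    """
    return frozenset(sequence.upper()) - _AA_SET


def is_valid_sequence(sequence: str, min_length: int = 1) -> bool:
    """True iff ``sequence`` is non-empty, long enough and standard-alphabet."""
    return len(sequence) >= max(min_length, 1) and not validate_sequence(sequence)


@dataclass
class ProteinRecord:
    """One identifier plus an amino-acid sequence of length ``L``."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise SequenceIOError(f"record {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Ordered protein records with an optional parallel list of labels."""

    records: list[ProteinRecord]
    labels: list[str] | None = None
    label_set: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceIOError(f"duplicate record ids: {dupes}")
        if self.labels is not None:
            if len(self.labels) != len(self.records):
                raise SequenceIOError(
                    f"{len(self.records)} records but {len(self.labels)} labels"
                )
            if self.label_set is not None:
                unknown = sorted(set(self.labels) - set(self.label_set))
                if unknown:
                    raise SequenceIOError(f"labels outside declared set: {unknown}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            records=[self.records[i] for i in indices],
            labels=None if self.labels is None else [self.labels[i] for i in indices],
            label_set=self.label_set,
        )

    def relabeled(self, labels: Iterable[str], label_set: tuple[str, ...] | None = None
                  ) -> "LabeledDataset":
        return LabeledDataset(list(self.records), list(labels), label_set)


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id<TAB>label`` TSV (header row required)."""
    table: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            return table
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise SequenceIOError(f"{path}:{lineno}: expected 2 columns")
            table[parts[0]] = parts[1]
    return table


def read_fasta(
    path: str | Path,
    label_source: str | None = None,
    label_table: str | Path | None = None,
    label_set: tuple[str, ...] | None = None,
) -> LabeledDataset:
    """Read a FASTA file, normalising residues to upper case.

    Parameters
    ----------
    label_source : {"header", "table", None}
        "header" splits each id at the first ``|``; "table" looks ids up in
        ``label_table``; None returns an unlabelled dataset.
    """
    if label_source not in (None, "none", "header", "table"):
        raise SequenceIOError(f"unknown label_source {label_source!r}")
    if label_source == "table":
        if label_table is None:
            raise SequenceIOError("label_source='table' requires label_table")
        table = read_label_table(label_table)

    records: list[ProteinRecord] = []
    labels: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        seq = str(rec.seq).upper()
        if not seq:
            raise SequenceIOError(f"record {rid!r}: empty sequence")
        if label_source == "header":
            if "|" not in rid:
                raise SequenceIOError(f"record {rid!r}: no '|label' in header")
            rid, lab = rid.split("|", 1)
            labels.append(lab)
        elif label_source == "table":
            if rid not in table:
                raise SequenceIOError(f"record {rid!r} missing from label table")
            labels.append(table[rid])
        records.append(ProteinRecord(rid, seq))

    return LabeledDataset(
        records,
        labels if label_source in ("header", "table") else None,
        label_set,
    )


def write_fasta(dataset: LabeledDataset, path: str | Path) -> None:
    """Write standard 60-column FASTA; labels appended as ``id|label``."""
    out = []
    for i, rec in enumerate(dataset.records):
        rid = rec.id
        if dataset.labels is not None:
            rid = f"{rid}|{dataset.labels[i]}"
        out.append(SeqRecord(Seq(rec.sequence), id=rid, description=""))
    SeqIO.write(out, str(path), "fasta")


def write_label_table(dataset: LabeledDataset, path: str | Path) -> None:
    if dataset.labels is None:
        raise SequenceIOError("dataset has no labels to write")
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for rec, lab in zip(dataset.records, dataset.labels):
            fh.write(f"{rec.id}\t{lab}\n")
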
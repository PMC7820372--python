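"""Benchmark-style dataset curation.

Mirrors the usual construction of protein-family benchmarks: drop sequences
with non-standard residues, cap pairwise redundancy with a greedy
CD-HIT-style clustering at an identity cutoff (default 0.8), and pool small
subfamilies into a catch-all class (``Apoelse``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .sequence_io import LabeledDataset, SequenceIOError, is_valid_sequence

#: subfamilies pooled into the catch-all class by default
DEFAULT_MERGE_MAP = {
    "ApoF": "Apoelse",
    "ApoH": "Apoelse",
    "ApoM": "Apoelse",
    "ApoN": "Apoelse",
    "ApoR": "Apoelse",
}


class CurationError(ValueError):
    pass


@dataclass
class CurationConfig:
    identity_cutoff: float = 0.8
    min_length: int = 10
    subfamily_merge_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MERGE_MAP))

    def __post_init__(self) -> None:
        if not 0 < self.identity_cutoff <= 1:
            raise CurationError("identity_cutoff must be in (0, 1]")
        if self.min_length < 1:
            raise CurationError("min_length must be positive")


def filter_invalid(dataset: LabeledDataset, min_length: int = 10) -> LabeledDataset:
    """Keep records that are standard-alphabet and at least ``min_length`` long."""
    keep = [i for i, rec in enumerate(dataset.records)
            if is_valid_sequence(rec.sequence, min_length)]
    return dataset.subset(keep)


def _aligner() -> Align.PairwiseAligner:
    # global alignment, match=1 / mismatch=0, linear gap penalty -1
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Fraction of identical aligned positions over the shorter sequence.

    The denominator follows the CD-HIT convention (length of the shorter
    sequence), so identical subsequences of very different lengths can still
    reach identity 1.
    """
    if aligner is None:
        aligner = _aligner()
    alignment = aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def reduce_redundancy(
    dataset: LabeledDataset,
    identity_cutoff: float = 0.8,
    representatives: list[str] | None = None,
) -> LabeledDataset:
    """Greedy redundancy reduction at an identity cutoff.

    Sequences are visited in descending length order (ties broken by record
    id); each joins the first retained representative it matches at
    ``identity >= identity_cutoff``, otherwise it becomes a new
    representative. Only representatives are returned, in the original
    dataset order. ``representatives`` lets callers substitute an externally
    produced representative id list (e.g. an actual CD-HIT run) for the
    built-in clustering.
    """
    if not 0 < identity_cutoff <= 1:
        raise CurationError("identity_cutoff must be in (0, 1]")
    if len(dataset) == 0:
        raise CurationError("reduce_redundancy requires a non-empty dataset")

    if representatives is not None:
        wanted = set(representatives)
        keep = [i for i, rec in enumerate(dataset.records) if rec.id in wanted]
        return dataset.subset(keep)

    order = sorted(range(len(dataset)),
                   key=lambda i: (-dataset.records[i].length, dataset.records[i].id))
    aligner = _aligner()
    kept: list[int] = []
    for i in order:
        seq = dataset.records[i].sequence
        for j in kept:
            if pairwise_identity(dataset.records[j].sequence, seq, aligner) >= identity_cutoff:
                break
        else:
            kept.append(i)
    return dataset.subset(sorted(kept))


def merge_subfamilies(dataset: LabeledDataset,
                      merge_map: dict[str, str] | None = None,
                      target_label_set: tuple[str, ...] | None = None) -> LabeledDataset:
    """Rename labels through ``merge_map``; unmapped labels pass through.

    Record order and count are preserved. If ``target_label_set`` is given,
    any resulting label outside it raises.
    """
    if dataset.labels is None:
        raise SequenceIOError("merge_subfamilies requires a labelled dataset")
    if merge_map is None:
        merge_map = DEFAULT_MERGE_MAP
    new_labels = [merge_map.get(lab, lab) for lab in dataset.labels]
    if target_label_set is not None:
        unknown = sorted(set(new_labels) - set(target_label_set))
        if unknown:
            raise CurationError(f"labels not in map and not in target set: {unknown}")
    return dataset.relabeled(new_labels, target_label_set)
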
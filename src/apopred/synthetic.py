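"""Synthetic labelled protein datasets with controllable class signal.

Each class draws a residue-frequency profile from a symmetric Dirichlet
(``composition_concentration`` controls how far profiles sit from uniform:
small values give strongly contrasting compositions, large values make
classes indistinguishable). Sequences are emitted i.i.d. from their class
profile, then class-specific k-spaced residue pairs are planted by
rewriting randomly chosen positions — creating exactly the compositional
(PseAAC/188D/DPC) and pair-level (CKSAAP) contrasts a family classifier
exploits. No attempt is made at realistic protein evolution (no phylogeny,
indels or domain architecture).

Ground truth (profiles and planted pairs) is returned, and written as JSON
next to the FASTA by the command-line interface, so tests never re-derive
it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .sequence_io import AMINO_ACIDS, LabeledDataset, ProteinRecord, SUBFAMILY_LABELS


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of one generated multi-class dataset.

    pair_signal_strength is the per-eligible-position probability that a
    planted (a, b, k) pair is written into a sequence of its class; the
    background rate of any specific ordered pair is about 1/400 per
    position, so 0.05 already yields a strong, easily recoverable signal.
    """

    n_classes: int = 2
    n_per_class: int = 40
    length_range: tuple[int, int] = (60, 140)
    composition_concentration: float = 1.0
    pair_signal_strength: float = 0.05
    planted_pairs_per_class: int = 3
    max_pair_gap: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 12:
            raise SyntheticError("length_range.min must be >= 12")
        if hi < lo:
            raise SyntheticError("length_range must be (min, max) with max >= min")
        if self.n_classes < 1 or self.n_per_class < 1:
            raise SyntheticError("n_classes and n_per_class must be positive")
        if self.pair_signal_strength < 0:
            raise SyntheticError("pair_signal_strength must be >= 0")
        if self.max_pair_gap + 2 > lo:
            raise SyntheticError("planted pair gap too large for minimum length")


def generate(spec: SyntheticSpec, class_labels: list[str] | None = None,
             id_prefix: str = "syn") -> tuple[LabeledDataset, dict]:
    """Generate a labelled dataset plus its ground-truth record.

    Deterministic: the same spec (including its seed) yields byte-identical
    sequences. Ground truth holds the per-class residue profiles and the
    planted (a, b, k) pairs.
    """
    if class_labels is None:
        class_labels = [f"class{c}" for c in range(spec.n_classes)]
    if len(class_labels) != spec.n_classes:
        raise SyntheticError(
            f"{spec.n_classes} classes but {len(class_labels)} labels")

    rng = np.random.default_rng(spec.seed)
    alphabet = np.asarray(list(AMINO_ACIDS))

    profiles: dict[str, np.ndarray] = {}
    planted: dict[str, list[tuple[str, str, int]]] = {}
    for lab in class_labels:
        profiles[lab] = rng.dirichlet(
            np.full(20, spec.composition_concentration))
        pairs = []
        for _ in range(spec.planted_pairs_per_class):
            a, b = alphabet[rng.integers(0, 20, size=2)]
            k = int(rng.integers(0, spec.max_pair_gap + 1))
            pairs.append((str(a), str(b), k))
        planted[lab] = pairs

    records: list[ProteinRecord] = []
    labels: list[str] = []
    lo, hi = spec.length_range
    counter = 0
    for lab in class_labels:
        for _ in range(spec.n_per_class):
            L = int(rng.integers(lo, hi + 1))
            seq = rng.choice(alphabet, size=L, p=profiles[lab])
            if spec.pair_signal_strength > 0:
                for a, b, k in planted[lab]:
                    n_slots = L - k - 1
                    mask = rng.random(n_slots) < spec.pair_signal_strength
                    for s in np.flatnonzero(mask):
                        seq[s] = a
                        seq[s + k + 1] = b
            records.append(ProteinRecord(f"{id_prefix}{counter:05d}", "".join(seq)))
            labels.append(lab)
            counter += 1

    truth = {
        "spec": asdict(spec),
        "class_labels": list(class_labels),
        "class_profiles": {lab: profiles[lab].tolist() for lab in class_labels},
        "planted_pairs": {lab: [[a, b, k] for a, b, k in planted[lab]]
                          for lab in class_labels},
    }
    return LabeledDataset(records, labels, tuple(class_labels)), truth


def generate_two_tier(
    spec_pos: SyntheticSpec,
    spec_neg: SyntheticSpec,
    subfamily_labels: list[str] | None = None,
) -> tuple[LabeledDataset, LabeledDataset, dict]:
    """Generate the binary (apo vs non-apo) and subfamily datasets.

    Positives carry subfamily labels drawn from ``spec_pos``'s classes and
    are pooled with the negatives under binary labels; id namespaces are
    disjoint (``pos...`` / ``neg...``).
    """
    if subfamily_labels is None:
        subfamily_labels = list(SUBFAMILY_LABELS[:spec_pos.n_classes])
    if len(subfamily_labels) != spec_pos.n_classes:
        raise SyntheticError("subfamily label count must equal spec_pos.n_classes")

    sub_ds, truth_pos = generate(spec_pos, subfamily_labels, id_prefix="pos")
    neg_ds, truth_neg = generate(spec_neg, id_prefix="neg")

    binary = LabeledDataset(
        records=list(sub_ds.records) + list(neg_ds.records),
        labels=["apo"] * len(sub_ds) + ["non-apo"] * len(neg_ds),
        label_set=("apo", "non-apo"),
    )
    truth = {"positives": truth_pos, "negatives": truth_neg}
    return binary, sub_ds, truth


def demo_specs(seed: int = 0) -> tuple[SyntheticSpec, SyntheticSpec]:
    """Default demo conditions: 7 subfamilies x 30 positives, 200 negatives.

    Strong compositional contrast (concentration 1.0) plus planted-pair
    signal; negatives come from 4 pooled background families so the
    non-apolipoprotein class is itself heterogeneous, as in real plasma
    protein collections.
    """
    spec_pos = SyntheticSpec(n_classes=7, n_per_class=30, seed=seed)
    spec_neg = SyntheticSpec(n_classes=4, n_per_class=50, seed=seed + 1)
    return spec_pos, spec_neg
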
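"""Fixed-length feature encodings of protein sequences.

Four encoders are provided, each a scikit-learn style transformer mapping a
list of sequences (strings or :class:`~apopred.sequence_io.ProteinRecord`)
to a dense numeric matrix with deterministic feature names:

========  ======================  =========================================
encoder   dimension               description
========  ======================  =========================================
DPC       400                     dipeptide composition: frequency of each
                                  ordered adjacent residue pair, N_rs/(L-1)
CKSAAP    400 x (k_max+1)         composition of k-spaced amino-acid pairs,
                                  one 400-feature block per gap k=0..k_max,
                                  each block normalised by L-(k+1)
188D      188                     20 residue frequencies plus, per each of
                                  8 physicochemical groupings, 3 group
                                  compositions, 3 cross-group transition
                                  frequencies and 15 positional
                                  distribution values
PseAAC    20 + 9*gamma            residue frequencies augmented with
                                  sequence-order correlation factors over 9
                                  physicochemical scales, tiers j=1..gamma
========  ======================  =========================================

All encoders are pure functions of (sequence, config): the same input gives
bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .sequence_io import AA_INDEX, AMINO_ACIDS, LabeledDataset, ProteinRecord, validate_sequence
from .tables import CTD_GROUPS, PSEAAC_PROPERTY_NAMES, standardized_properties

_PAIRS = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]


class EncodingError(ValueError):
    """A sequence violates an encoder precondition."""


@dataclass
class EncoderConfig:
    """Configuration for one encoder.

    Parameters
    ----------
    encoder : {"PseAAC", "CKSAAP", "DPC", "188D"}
    gamma : int
        Number of PseAAC correlation tiers (0 reduces PseAAC to plain
        amino-acid composition).
    w : float
        Weight of the PseAAC pseudo components in the joint normalisation.
    k_max : int
        Largest gap for CKSAAP, in 0..5.
    property_table_id : str
        Which built-in physicochemical table PseAAC uses.
    """

    encoder: str = "PseAAC"
    gamma: int = 10
    w: float = 0.05
    k_max: int = 5
    property_table_id: str = "builtin-v1"

    def __post_init__(self) -> None:
        if self.encoder not in ("PseAAC", "CKSAAP", "DPC", "188D"):
            raise EncodingError(f"unknown encoder {self.encoder!r}")
        if not 0 <= self.k_max <= 5:
            raise EncodingError("k_max must be in 0..5")
        if self.gamma < 0:
            raise EncodingError("gamma must be >= 0")
        if self.w <= 0:
            raise EncodingError("w must be > 0")


def _as_sequence(x) -> str:
    seq = x.sequence if isinstance(x, ProteinRecord) else str(x)
    bad = validate_sequence(seq)
    if bad:
        raise EncodingError(f"non-standard residues {sorted(bad)} in sequence")
    return seq.upper()


def _indices(seq: str) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))


class _BaseEncoder(TransformerMixin, BaseEstimator):
    """Stateless transformer: ``fit`` is a no-op, ``transform`` encodes."""

    def fit(self, X, y=None):
        return self

    def encode(self, sequence) -> np.ndarray:
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        rows = []
        for i, x in enumerate(X):
            try:
                rows.append(self.encode(x))
            except EncodingError as exc:
                name = x.id if isinstance(x, ProteinRecord) else f"sample {i}"
                raise EncodingError(f"{name}: {exc}") from None
        n_feat = len(self.get_feature_names_out())
        if not rows:
            return np.empty((0, n_feat))
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        raise NotImplementedError


class DPCEncoder(_BaseEncoder):
    """Dipeptide composition: 400 ordered-pair frequencies, D(r,s)=N_rs/(L-1)."""

    def encode(self, sequence) -> np.ndarray:
        seq = _as_sequence(sequence)
        if len(seq) < 2:
            raise EncodingError("DPC requires length >= 2")
        idx = _indices(seq)
        v = np.zeros(400)
        np.add.at(v, idx[:-1] * 20 + idx[1:], 1.0)
        return v / (len(seq) - 1)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray([f"DPC_{p}" for p in _PAIRS], dtype=object)


class CKSAAPEncoder(_BaseEncoder):
    """Composition of k-spaced amino-acid pairs.

    For each gap k = 0..k_max the 400 ordered pairs (a at position i, b at
    position i+k+1) are counted and divided by the number of such positions,
    N_total_k = L-(k+1); the blocks are concatenated in increasing k.
    """

    def __init__(self, k_max: int = 5):
        self.k_max = k_max

    def encode(self, sequence) -> np.ndarray:
        if not 0 <= self.k_max <= 5:
            raise EncodingError("k_max must be in 0..5")
        seq = _as_sequence(sequence)
        L = len(seq)
        if L < self.k_max + 2:
            raise EncodingError(f"CKSAAP k_max={self.k_max} requires length >= {self.k_max + 2}")
        idx = _indices(seq)
        blocks = []
        for k in range(self.k_max + 1):
            gap = k + 1
            v = np.zeros(400)
            np.add.at(v, idx[:-gap] * 20 + idx[gap:], 1.0)
            blocks.append(v / (L - gap))
        return np.concatenate(blocks)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        names = [f"CKSAAP_k{k}_{p}" for k in range(self.k_max + 1) for p in _PAIRS]
        return np.asarray(names, dtype=object)


class CTD188Encoder(_BaseEncoder):
    """Composition/transition/distribution features (188 dimensions).

    20 residue frequencies (alphabetical) followed, for each of the eight
    built-in physicochemical groupings, by: the 3 group composition
    frequencies; the 3 transition frequencies (fraction of adjacent residue
    pairs whose members fall in two different groups, unordered, divided by
    L-1); and 15 distribution values — for each group, the sequence
    positions (1-based, divided by L) of its 1st, 25th-percentile,
    50th-percentile, 75th-percentile and last occurrence, zero for groups
    absent from the sequence. 20 + 8*(3+3+15) = 188.
    """

    def encode(self, sequence) -> np.ndarray:
        seq = _as_sequence(sequence)
        L = len(seq)
        if L < 2:
            raise EncodingError("188D requires length >= 2")
        idx = _indices(seq)
        freqs = np.bincount(idx, minlength=20) / L

        out = [freqs]
        for prop in CTD_GROUPS:
            groups = CTD_GROUPS[prop]
            gid = np.empty(20, dtype=np.intp)
            for g, members in enumerate(groups):
                for aa in members:
                    gid[AA_INDEX[aa]] = g
            seq_gid = gid[idx]

            comp = np.bincount(seq_gid, minlength=3) / L

            trans = np.zeros(3)
            a, b = seq_gid[:-1], seq_gid[1:]
            for t, (g1, g2) in enumerate(combinations(range(3), 2)):
                trans[t] = np.sum(((a == g1) & (b == g2)) | ((a == g2) & (b == g1)))
            trans /= L - 1

            dist = np.zeros(15)
            for g in range(3):
                pos = np.flatnonzero(seq_gid == g) + 1  # 1-based
                n_g = pos.size
                if n_g == 0:
                    continue
                for q_i, q in enumerate((0.0, 0.25, 0.50, 0.75, 1.0)):
                    occ = max(1, math.ceil(q * n_g))
                    dist[5 * g + q_i] = pos[occ - 1] / L
            out.extend([comp, trans, dist])
        return np.concatenate(out)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        names = [f"D188_f_{aa}" for aa in AMINO_ACIDS]
        for prop in CTD_GROUPS:
            names += [f"D188_{prop}_comp{g + 1}" for g in range(3)]
            names += [f"D188_{prop}_trans{g1 + 1}{g2 + 1}"
                      for g1, g2 in combinations(range(3), 2)]
            names += [f"D188_{prop}_dist{g + 1}_{pt}"
                      for g in range(3)
                      for pt in ("first", "p25", "p50", "p75", "last")]
        return np.asarray(names, dtype=object)


class PseAACEncoder(_BaseEncoder):
    """Pseudo-amino-acid composition with per-property tier correlation.

    Each of the nine physicochemical scales h_p (standardised to mean 0,
    variance 1 over the 20 residues) contributes one sequence-order factor
    per tier j = 1..gamma:

        tau_{p,j} = (1/(L-j)) * sum_{i=1..L-j} h_p(R_i) * h_p(R_{i+j})

    With f_u the residue frequencies (sum 1) and Z = 1 + w * sum tau, the
    vector is [f_1/Z ... f_20/Z, w*tau_{p,j}/Z ...] ordered tier-major,
    property-minor — dimension 20 + 9*gamma, components summing to 1.
    """

    def __init__(self, gamma: int = 10, w: float = 0.05,
                 property_table_id: str = "builtin-v1"):
        self.gamma = gamma
        self.w = w
        self.property_table_id = property_table_id

    def encode(self, sequence) -> np.ndarray:
        if self.gamma < 0:
            raise EncodingError("gamma must be >= 0")
        if self.w <= 0:
            raise EncodingError("w must be > 0")
        seq = _as_sequence(sequence)
        L = len(seq)
        if L < self.gamma + 1:
            raise EncodingError(f"PseAAC gamma={self.gamma} requires length >= {self.gamma + 1}")
        idx = _indices(seq)
        freqs = np.bincount(idx, minlength=20) / L

        props = standardized_properties(self.property_table_id)
        taus = np.empty(9 * self.gamma)
        for j in range(1, self.gamma + 1):
            for p, name in enumerate(PSEAAC_PROPERTY_NAMES):
                h = props[name][idx]
                taus[9 * (j - 1) + p] = float(np.mean(h[:-j] * h[j:]))

        denom = 1.0 + self.w * taus.sum()
        if abs(denom) < 1e-8:
            raise EncodingError("degenerate PseAAC normalisation (denominator ~ 0)")
        return np.concatenate([freqs / denom, self.w * taus / denom])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        names = [f"PseAAC_f_{aa}" for aa in AMINO_ACIDS]
        names += [f"PseAAC_t{j}_{name}"
                  for j in range(1, self.gamma + 1)
                  for name in PSEAAC_PROPERTY_NAMES]
        return np.asarray(names, dtype=object)


def get_encoder(config: EncoderConfig) -> _BaseEncoder:
    """Instantiate the transformer described by an :class:`EncoderConfig`."""
    if config.encoder == "DPC":
        return DPCEncoder()
    if config.encoder == "CKSAAP":
        return CKSAAPEncoder(k_max=config.k_max)
    if config.encoder == "188D":
        return CTD188Encoder()
    return PseAACEncoder(gamma=config.gamma, w=config.w,
                         property_table_id=config.property_table_id)


def encode_dataset(dataset: LabeledDataset, config: EncoderConfig) -> pd.DataFrame:
    """Encode every record; rows indexed by record id, columns by feature name."""
    enc = get_encoder(config)
    values = enc.transform(dataset.records)
    return pd.DataFrame(values, index=dataset.ids,
                        columns=enc.get_feature_names_out())


def write_feature_matrix(X: pd.DataFrame, path) -> None:
    X.to_csv(path, sep="\t", index_label="id")


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
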
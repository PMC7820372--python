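"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, textbook formulas)
and shares no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def naive_pair_counts(seq: str, k: int) -> dict[str, int]:
    """Count ordered residue pairs with exactly k residues in between."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k - 1):
        pair = seq[i] + seq[i + k + 1]
        counts[pair] = counts.get(pair, 0) + 1
    return counts


def naive_anova_f(columns: np.ndarray, y) -> np.ndarray:
    """Textbook one-way ANOVA per column: (SSB/df_B) / (SSW/df_W)."""
    y = np.asarray(y)
    groups = sorted(set(y.tolist()))
    n, p = columns.shape
    k = len(groups)
    out = np.empty(p)
    for j in range(p):
        x = columns[:, j]
        grand = sum(x) / n
        ssb = ssw = 0.0
        for g in groups:
            xg = x[y == g]
            mg = sum(xg) / len(xg)
            ssb += len(xg) * (mg - grand) ** 2
            ssw += sum((v - mg) ** 2 for v in xg)
        if ssw == 0.0:
            out[j] = 0.0 if ssb == 0.0 else np.inf
        else:
            out[j] = (ssb / (k - 1)) / (ssw / (n - k))
    return out


def naive_binary_metrics(tp: int, tn: int, fp: int, fn: int):
    """Sn, Sp, Acc, MCC straight from the defining formulas."""
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return sn, sp, acc, mcc


def mann_whitney_auc(scores, truth) -> float:
    """AUC as the normalised Mann-Whitney U statistic, by double loop."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    pos = scores[truth]
    neg = scores[~truth]
    wins = 0.0
    for sp in pos:
        for sn_ in neg:
            if sp > sn_:
                wins += 1.0
            elif sp == sn_:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def naive_pseaac(seq: str, gamma: int, w: float,
                 property_order, standardized: dict[str, np.ndarray],
                 aa_index: dict[str, int]) -> np.ndarray:
    """Straight-loop pseudo-amino-acid composition, independent of the encoder."""
    L = len(seq)
    freqs = [seq.count(aa) / L for aa in AMINO_ACIDS]
    taus = []
    for j in range(1, gamma + 1):
        for name in property_order:
            h = standardized[name]
            s = 0.0
            for i in range(L - j):
                s += h[aa_index[seq[i]]] * h[aa_index[seq[i + j]]]
            taus.append(s / (L - j))
    denom = 1.0 + w * sum(taus)
    return np.array([f / denom for f in freqs] + [w * t / denom for t in taus])
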
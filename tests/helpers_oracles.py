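"""Independent brute-force oracles used to validate the implementation.

Everything here is written the naive way on purpose (full DP tables,
explicit pair counting, explicit loops) and must stay independent of the
code paths it checks.
"""

from __future__ import annotations

import numpy as np


def levenshtein_dp(s: str, t: str) -> int:
    """Full-table unit-cost edit distance."""
    n, m = len(s), len(t)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if s[i - 1] == t[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
    return d[n][m]


def lcs_dp(s: str, t: str) -> int:
    """Full-table longest common subsequence length."""
    n, m = len(s), len(t)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if s[i - 1] == t[j - 1]:
                d[i][j] = d[i - 1][j - 1] + 1
            else:
                d[i][j] = max(d[i - 1][j], d[i][j - 1])
    return d[n][m]


def edit_similarity_oracle(s: str, t: str) -> float:
    return 1.0 - levenshtein_dp(s, t) / max(len(s), len(t))


def nlcs_oracle(s: str, t: str) -> float:
    return lcs_dp(s, t) ** 2 / (len(s) * len(t))


def auc_pair_counting(labels, scores) -> float:
    """Mann-Whitney AUC by exhaustive positive x negative pair counting."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def average_precision_enum(labels, scores) -> float:
    """AP = mean of precision@rank over the ranks of the positives."""
    order = sorted(range(len(labels)), key=lambda i: -scores[i])
    ranked = [labels[i] for i in order]
    hits = 0
    precisions = []
    for rank, lab in enumerate(ranked, start=1):
        if lab == 1:
            hits += 1
            precisions.append(hits / rank)
    return float(np.mean(precisions))


def mrr_enum(rankings) -> float:
    vals = []
    for labels in rankings.values():
        labels = list(labels)
        if 1 in labels:
            vals.append(1.0 / (labels.index(1) + 1))
    return float(np.mean(vals))


def map_at_k_enum(rankings, k: int) -> float:
    vals = []
    for labels in rankings.values():
        n_pos = sum(labels)
        if n_pos == 0:
            continue
        hits = 0
        acc = 0.0
        for rank in range(1, min(k, len(labels)) + 1):
            if labels[rank - 1] == 1:
                hits += 1
                acc += hits / rank
        vals.append(acc / min(k, n_pos))
    return float(np.mean(vals))


def lookup_one_new_oracle(neighbor_entries, proba_of_neighbor, skip_id=None) -> float | None:
    """Weighted mean of neighbour probabilities; None when unsupported.

    neighbor_entries: [(id, sim), ...]; proba_of_neighbor: id -> probability
    of (neighbour, known partner); skip_id: the known partner (no self-pair).
    """
    num = den = 0.0
    for c, sim in neighbor_entries:
        if sim == 0.0 or c == skip_id:
            continue
        num += proba_of_neighbor[c] * sim
        den += sim
    if den == 0.0:
        return None
    return num / den


def lookup_two_new_oracle(entries_a, entries_b, proba_of_pair) -> float | None:
    """Harmonic-mean-weighted mean over rank-aligned neighbour pairs."""
    num = den = 0.0
    for (ca, sa), (cb, sb) in zip(entries_a, entries_b):
        if ca == cb or sa == 0.0 or sb == 0.0:
            continue
        w = 2.0 / (1.0 / sa + 1.0 / sb)
        num += proba_of_pair[(ca, cb)] * w
        den += w
    if den == 0.0:
        return None
    return num / den
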
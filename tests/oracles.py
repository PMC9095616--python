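"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimized code paths: matching is
a plain per-offset scan, hypergeometric tails are exact rational sums,
pattern discovery is a full enumeration of the bounded pattern space,
and ROC quantities come from direct pair/threshold counting.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, inf

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def naive_match(symbols: str, peptide: str) -> bool:
    """Per-offset scan: does the pattern string occur in the peptide?"""
    span = len(symbols)
    for o in range(len(peptide) - span + 1):
        if all(c == "." or peptide[o + j] == c for j, c in enumerate(symbols)):
            return True
    return False


def naive_offsets(symbols: str, sequence: str) -> list[int]:
    """All 0-based offsets where the pattern occurs (overlaps allowed)."""
    span = len(symbols)
    return [
        o
        for o in range(len(sequence) - span + 1)
        if all(c == "." or sequence[o + j] == c for j, c in enumerate(symbols))
    ]


def exact_hypergeom_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """Exact rational P(X >= k) for the hypergeometric urn."""
    num = sum(comb(K, j) * comb(N - K, n - j)
              for j in range(k, min(n, K) + 1) if n - j <= N - K)
    return Fraction(num, comb(N, n))


def enumerate_patterns(peptides, max_span: int) -> dict[str, set[str]]:
    """Map every wildcard pattern (residue-bounded ends) to the peptides holding it."""
    patterns: dict[str, set[str]] = {}
    for pep in peptides:
        for s in range(1, max_span + 1):
            for o in range(len(pep) - s + 1):
                window = pep[o:o + s]
                interior = max(0, s - 2)
                for mask in itertools.product((False, True), repeat=interior):
                    chars = list(window)
                    for i, wild in enumerate(mask):
                        if wild:
                            chars[i + 1] = "."
                    patterns.setdefault("".join(chars), set()).add(pep)
    return patterns


def brute_force_discover(query, reference, params, mode="discriminative"):
    """Full enumeration over the bounded pattern space; returns {pattern: (fold, p)}.

    Applies the same selection rule as the discovery contract: distinct
    query support >= min_support, fixed_count >= min_fixed,
    fold >= min_fold (with the +1 reference pseudocount), p < max_p on
    the distinct-peptide urn.
    """
    q_peps = list(query.counts)
    r_peps = list(reference.counts)
    nq, nr = len(q_peps), len(r_peps)
    if params.count_mode == "reads":
        n_q_tot, n_r_tot = query.total, reference.total
    else:
        n_q_tot, n_r_tot = float(nq), float(nr)
    q_map = enumerate_patterns(q_peps, params.max_span)
    r_map = enumerate_patterns(r_peps, params.max_span)
    out = {}
    for pat, q_hits in q_map.items():
        fixed = sum(1 for c in pat if c != ".")
        if fixed < params.min_fixed:
            continue
        if len(q_hits) < params.min_support:
            continue
        r_hits = r_map.get(pat, set())
        if params.count_mode == "reads":
            k_q = sum(query.counts[p] for p in q_hits)
            k_r = sum(reference.counts[p] for p in r_hits)
        else:
            k_q, k_r = float(len(q_hits)), float(len(r_hits))
        fold = (k_q / n_q_tot) / ((k_r + 1.0) / n_r_tot)
        if fold < params.min_fold:
            continue
        p = float(exact_hypergeom_tail(len(q_hits), nq,
                                       len(q_hits) + len(r_hits), nq + nr))
        if p >= params.max_p:
            continue
        out[pat] = (fold, p)
    return out


def pairwise_auc(scores, labels) -> float:
    """AUC by enumerating every (positive, negative) pair."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def sweep_youden(scores, labels):
    """Brute-force threshold sweep; returns (J*, threshold, sens, spec)."""
    thresholds = sorted(set(scores)) + [inf]
    best = None
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= t)
        fn = sum(1 for s, y in zip(scores, labels) if y == 1 and s < t)
        tn = sum(1 for s, y in zip(scores, labels) if y == 0 and s < t)
        fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= t)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        t_key = t if t != inf else 1e308
        key = (j, spec, -t_key)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t, sens, spec = best
    return sens + spec - 1.0, t, sens, spec


def confusion_point(scores, labels, threshold):
    """(sensitivity, specificity) at one threshold by direct counting."""
    tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= threshold)
    fn = sum(1 for s, y in zip(scores, labels) if y == 1 and s < threshold)
    tn = sum(1 for s, y in zip(scores, labels) if y == 0 and s < threshold)
    fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= threshold)
    return tp / (tp + fn), tn / (tn + fp)
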
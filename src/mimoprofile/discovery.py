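"""Exhaustive discriminative epitope-pattern discovery.

An epitope here is a motif of fixed amino-acid positions separated by
single-character wildcards (``'.'``) inside a window of at most 12
residues, e.g. ``"GGQ.HD"``. Patterns are enumerated breadth-first by
appending a residue or a wildcard to the right end, walking a match-list
structure over the query+reference peptides. Pruning uses only the
minimum-support bound, which is monotone non-increasing under extension,
so the search is exhaustive within the span/support bounds.

Enrichment of a pattern is scored two ways:

* fold enrichment of its matching abundance in the query versus the
  reference repertoire (with a +1 pseudocount on the reference matches);
* an upper-tail hypergeometric p-value on distinct-peptide counts, i.e.
  the probability of at least ``k`` matching peptides among the query's
  ``n`` when ``K`` of the ``N`` pooled peptides match.

Default selection thresholds follow the discriminative analysis
convention: fold >= 2 against a paired pre-treatment sample (or >= 10
against a random-peptide reference) and p < 1e-8.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .repertoire import (
    CANONICAL_RESIDUES,
    PEPTIDE_LENGTH,
    PeptideRepertoire,
    RepertoireError,
)

WILDCARD = "."
_RES_INDEX = {c: i for i, c in enumerate(CANONICAL_RESIDUES)}
_N_RES = len(CANONICAL_RESIDUES)


class PatternError(ValueError):
    """Invalid epitope pattern."""


@dataclass(frozen=True, order=True)
class EpitopePattern:
    """A fixed-residue motif with single-position wildcards.

    ``symbols`` is a string over the 20 residue letters plus ``'.'``;
    the first and last symbol are always residue letters (wildcards are
    only interior). ``fixed_count`` is the number of residue letters and
    ``span`` the window length.
    """

    symbols: str

    def __post_init__(self) -> None:
        s = self.symbols
        if not s:
            raise PatternError("empty pattern")
        if len(s) > PEPTIDE_LENGTH:
            raise PatternError(f"pattern span {len(s)} exceeds {PEPTIDE_LENGTH}")
        if s[0] == WILDCARD or s[-1] == WILDCARD:
            raise PatternError(f"pattern {s!r} must start and end with a residue")
        for c in s:
            if c != WILDCARD and c not in _RES_INDEX:
                raise PatternError(f"pattern {s!r}: invalid symbol {c!r}")

    @property
    def span(self) -> int:
        return len(self.symbols)

    @property
    def fixed_count(self) -> int:
        return sum(1 for c in self.symbols if c != WILDCARD)

    def fixed_positions(self) -> list[tuple[int, str]]:
        """(offset, residue) for every fixed position."""
        return [(j, c) for j, c in enumerate(self.symbols) if c != WILDCARD]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.symbols


def as_pattern(pattern: EpitopePattern | str) -> EpitopePattern:
    if isinstance(pattern, EpitopePattern):
        return pattern
    return EpitopePattern(str(pattern))


def match(pattern: EpitopePattern | str, peptide: str) -> bool:
    """True iff the pattern occurs in the peptide at some offset.

    Every fixed residue of the pattern must equal the peptide residue at
    its aligned position; wildcard positions are unconstrained.
    """
    pat = as_pattern(pattern)
    if pat.span > len(peptide):
        if pat.span > PEPTIDE_LENGTH:
            raise PatternError(f"pattern span {pat.span} exceeds peptide length")
        return False
    fixed = pat.fixed_positions()
    for o in range(len(peptide) - pat.span + 1):
        if all(peptide[o + j] == c for j, c in fixed):
            return True
    return False


def encode_peptides(peptides: list[str]) -> np.ndarray:
    """Encode equal-length peptides as a (n, L) uint8 matrix of residue codes."""
    if not peptides:
        return np.zeros((0, PEPTIDE_LENGTH), dtype=np.uint8)
    L = len(peptides[0])
    buf = np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8)
    mat = buf.reshape(len(peptides), L)
    lut = np.full(128, 255, dtype=np.uint8)
    for c, i in _RES_INDEX.items():
        lut[ord(c)] = i
    coded = lut[mat]
    if (coded == 255).any():
        raise PatternError("non-canonical residue in peptide set")
    return coded


def match_mask(mat: np.ndarray, pattern: EpitopePattern | str) -> np.ndarray:
    """Boolean row mask: which encoded peptides contain the pattern."""
    pat = as_pattern(pattern)
    n, L = mat.shape
    if pat.span > L:
        return np.zeros(n, dtype=bool)
    fixed = [(j, _RES_INDEX[c]) for j, c in pat.fixed_positions()]
    out = np.zeros(n, dtype=bool)
    for o in range(L - pat.span + 1):
        m = np.ones(n, dtype=bool)
        for j, code in fixed:
            m &= mat[:, o + j] == code
        out |= m
    return out


def pattern_abundance(
    pattern: EpitopePattern | str,
    rep: PeptideRepertoire,
    count_mode: str = "reads",
) -> float:
    """Abundance of a pattern in a repertoire.

    ``reads`` mode sums the (normalized) counts of the distinct peptides
    containing the pattern; ``unique_peptides`` mode counts the distinct
    matching peptides. A peptide contributes once even if the pattern
    occurs at several internal offsets.
    """
    if count_mode not in ("reads", "unique_peptides"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    peptides = list(rep.counts)
    if not peptides:
        return 0.0
    mask = match_mask(encode_peptides(peptides), pattern)
    if count_mode == "unique_peptides":
        return float(mask.sum())
    weights = np.fromiter((rep.counts[p] for p in peptides), dtype=float,
                          count=len(peptides))
    return float(weights[mask].sum())


def _log_comb(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeometric_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts query-set members among the ``K`` matching peptides when
    ``n`` of the ``N`` pooled distinct peptides form the query set.
    Computed in log space (lgamma) with a scaled sum, accurate to about
    1e-12 relative for p >= 1e-300.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid urn: n={n}, K={K}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"invalid count k={k} for urn n={n}, K={K}, N={N}")
    if k <= max(0, n + K - N):
        return 1.0
    j_hi = min(n, K)
    log_denom = _log_comb(N, n)
    log_terms = [
        _log_comb(K, j) + _log_comb(N - K, n - j) - log_denom
        for j in range(k, j_hi + 1)
    ]
    m = max(log_terms)
    s = math.fsum(math.exp(t - m) for t in log_terms)
    return min(1.0, math.exp(m) * s)


def fold_enrichment(k_q: float, n_q: float, k_r: float, n_r: float) -> float:
    """Query/reference enrichment ratio with a +1 pseudocount on the reference.

    fold = (k_q / n_q) / ((k_r + 1) / n_r). The pseudocount keeps the
    ratio finite when the reference has no matches and biases the
    estimate conservatively (never the query side).
    """
    if n_q <= 0 or n_r <= 0:
        raise ValueError("totals must be positive")
    return (k_q / n_q) / ((k_r + 1.0) / n_r)


@dataclass
class DiscoveryParams:
    """Thresholds and bounds for the exhaustive pattern search.

    min_fold defaults to 2 for discriminative (paired-sample) mode and
    10 for vs_random mode when constructed via :func:`default_params`.
    """

    min_fixed: int = 4
    max_span: int = PEPTIDE_LENGTH
    min_fold: float = 2.0
    max_p: float = 1e-8
    min_support: int = 10
    count_mode: str = "reads"

    def __post_init__(self) -> None:
        if self.min_fixed < 1 or self.max_span < 1 or self.min_support < 1:
            raise ValueError("bounds must be positive")
        if self.max_span > PEPTIDE_LENGTH:
            raise ValueError(f"max_span cannot exceed {PEPTIDE_LENGTH}")
        if self.min_fold <= 0 or not (0 < self.max_p <= 1):
            raise ValueError("invalid thresholds")
        if self.count_mode not in ("reads", "unique_peptides"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")


def default_params(mode: str) -> DiscoveryParams:
    """Mode-specific default thresholds (fold 2 discriminative, 10 vs random)."""
    if mode == "discriminative":
        return DiscoveryParams(min_fold=2.0)
    if mode == "vs_random":
        return DiscoveryParams(min_fold=10.0)
    raise ValueError(f"unknown discovery mode {mode!r}")


@dataclass
class EnrichmentResult:
    """A pattern with its enrichment evidence.

    ``k_query``/``k_ref`` are abundances in the configured count mode;
    ``k_query_unique``/``k_ref_unique`` are the distinct-peptide counts
    feeding the hypergeometric urn.
    """

    pattern: EpitopePattern
    k_query: float
    n_query: float
    k_ref: float
    n_ref: float
    fold: float
    p_value: float
    mode: str
    k_query_unique: int = 0
    k_ref_unique: int = 0

    def sort_key(self) -> tuple:
        return (self.p_value, -self.fold, self.pattern.symbols)


def _distinct_query_support(pep: np.ndarray, n_query: int) -> int:
    # Occurrence lists are kept sorted by peptide index (row-major seeds,
    # order-stable splits), so distinct peptides = value changes + 1.
    q = pep[pep < n_query]
    if q.size == 0:
        return 0
    return int(np.count_nonzero(q[1:] != q[:-1])) + 1


def discover(
    query: PeptideRepertoire,
    reference: PeptideRepertoire,
    params: DiscoveryParams | None = None,
    mode: str = "discriminative",
) -> list[EnrichmentResult]:
    """Exhaustively enumerate enriched patterns in query vs reference.

    Returns exactly the patterns with ``fixed_count >= min_fixed``,
    ``span <= max_span``, at least ``min_support`` distinct matching
    query peptides, ``fold >= min_fold`` and ``p_value < max_p``, sorted
    by ascending p-value, then descending fold, then pattern string.
    """
    if mode not in ("discriminative", "vs_random"):
        raise ValueError(f"unknown discovery mode {mode!r}")
    if params is None:
        params = default_params(mode)
    q_peps = list(query.counts)
    r_peps = list(reference.counts)
    if not q_peps:
        raise RepertoireError(f"{query.sample_id}: empty query repertoire")
    nq, nr = len(q_peps), len(r_peps)
    mat = encode_peptides(q_peps + r_peps)
    wq = np.fromiter((query.counts[p] for p in q_peps), dtype=float, count=nq)
    wr = np.fromiter((reference.counts[p] for p in r_peps), dtype=float, count=nr)
    weights = np.concatenate([wq, wr])
    if params.count_mode == "reads":
        n_q_tot, n_r_tot = float(query.total), float(reference.total)
    else:
        n_q_tot, n_r_tot = float(nq), float(nr)

    results: list[EnrichmentResult] = []
    L = PEPTIDE_LENGTH
    # Seed the search with single-residue patterns and their occurrence lists.
    queue: deque[tuple[str, np.ndarray, np.ndarray]] = deque()
    for r in range(_N_RES):
        pep, off = np.nonzero(mat == r)
        pep = pep.astype(np.int32)
        off = off.astype(np.int32)
        if _distinct_query_support(pep, nq) >= params.min_support:
            queue.append((CANONICAL_RESIDUES[r], pep, off))

    res_codes = np.arange(_N_RES + 1)

    def maybe_report(symbols: str, pep: np.ndarray) -> None:
        if sum(1 for c in symbols if c != WILDCARD) < params.min_fixed:
            return
        uniq = np.unique(pep)
        q_idx = uniq[uniq < nq]
        r_idx = uniq[uniq >= nq]
        k_uq, k_ur = int(q_idx.size), int(r_idx.size)
        if k_uq < params.min_support:
            return
        if params.count_mode == "reads":
            k_q = float(weights[q_idx].sum())
            k_r = float(weights[r_idx].sum())
        else:
            k_q, k_r = float(k_uq), float(k_ur)
        fold = fold_enrichment(k_q, n_q_tot, k_r, n_r_tot)
        if fold < params.min_fold:
            return
        p = hypergeometric_pvalue(k_uq, nq, k_uq + k_ur, nq + nr)
        if p >= params.max_p:
            return
        results.append(
            EnrichmentResult(
                pattern=EpitopePattern(symbols),
                k_query=k_q, n_query=n_q_tot,
                k_ref=k_r, n_ref=n_r_tot,
                fold=fold, p_value=p, mode=mode,
                k_query_unique=k_uq, k_ref_unique=k_ur,
            )
        )

    while queue:
        symbols, pep, off = queue.popleft()
        if symbols[-1] != WILDCARD:
            maybe_report(symbols, pep)
        span = len(symbols)
        if span >= params.max_span:
            continue
        keep = off <= L - span - 1
        if not keep.any():
            continue
        pep_v, off_v = pep[keep], off[keep]
        nxt = mat[pep_v, off_v + span]
        order = np.argsort(nxt, kind="stable")
        bounds = np.searchsorted(nxt[order], res_codes)
        for r in range(_N_RES):
            idx = order[bounds[r]:bounds[r + 1]]
            if idx.size == 0:
                continue
            cpep, coff = pep_v[idx], off_v[idx]
            if _distinct_query_support(cpep, nq) >= params.min_support:
                queue.append((symbols + CANONICAL_RESIDUES[r], cpep, coff))
        # A wildcard child must still fit one more residue inside max_span.
        if span + 2 <= params.max_span:
            if _distinct_query_support(pep_v, nq) >= params.min_support:
                queue.append((symbols + WILDCARD, pep_v, off_v))

    results.sort(key=EnrichmentResult.sort_key)
    return results


def generate_random_reference(
    n_unique: int,
    freqs: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> PeptideRepertoire:
    """A random-peptide reference repertoire: n distinct 12-mers, count 1 each.

    Used for non-discriminatory discovery when no paired pre-treatment
    sample exists. Residues are drawn i.i.d. from ``freqs`` (uniform by
    default); the result is normalized to the standard depth.
    """
    from .repertoire import normalize_reads
    from .synthetic import _validate_freqs, _draw_unique_peptides

    if n_unique <= 0:
        raise ValueError("n_unique must be positive")
    letters, probs = _validate_freqs(freqs)
    n_pos = int((probs > 0).sum())
    if n_pos < 4 and n_pos ** PEPTIDE_LENGTH < n_unique:
        raise ValueError("n_unique exceeds the number of achievable peptides")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    peps = _draw_unique_peptides(n_unique, letters, probs, rng)
    rep = PeptideRepertoire(
        sample_id="random-reference",
        counts={p: 1.0 for p in peps},
        normalized=False,
    )
    return normalize_reads(rep)


def reduce_to_core(
    results: list[EnrichmentResult], query: PeptideRepertoire
) -> list[EnrichmentResult]:
    """Reduce raw discovery output to core epitopes by match-set subsumption.

    A pattern is dropped when its set of matching distinct query peptides
    is a subset of a retained pattern's match set with smaller-or-equal
    p-value. Among mutually subsuming equal-p patterns, the one with more
    fixed positions (then the lexicographically smallest) is kept.
    """
    if not results:
        return []
    peptides = list(query.counts)
    mat = encode_peptides(peptides)
    order = sorted(
        range(len(results)),
        key=lambda i: (
            results[i].p_value,
            -results[i].pattern.fixed_count,
            results[i].pattern.symbols,
        ),
    )
    kept: list[EnrichmentResult] = []
    kept_masks: list[np.ndarray] = []
    for i in order:
        res = results[i]
        mask = match_mask(mat, res.pattern)
        subsumed = False
        for other, omask in zip(kept, kept_masks):
            if other.p_value <= res.p_value and not np.any(mask & ~omask):
                subsumed = True
                break
        if not subsumed:
            kept.append(res)
            kept_masks.append(mask)
    kept.sort(key=EnrichmentResult.sort_key)
    return kept


def results_to_frame(results: list[EnrichmentResult]):
    """Tabulate discovery results (column layout of the epitopes TSV)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "pattern": r.pattern.symbols,
                "fixed_count": r.pattern.fixed_count,
                "span": r.pattern.span,
                "k_query": r.k_query,
                "n_query": r.n_query,
                "k_ref": r.k_ref,
                "n_ref": r.n_ref,
                "fold": r.fold,
                "p_value": r.p_value,
                "mode": r.mode,
                "k_query_unique": r.k_query_unique,
                "k_ref_unique": r.k_ref_unique,
            }
            for r in results
        ],
        columns=[
            "pattern", "fixed_count", "span", "k_query", "n_query",
            "k_ref", "n_ref", "fold", "p_value", "mode",
            "k_query_unique", "k_ref_unique",
        ],
    )
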
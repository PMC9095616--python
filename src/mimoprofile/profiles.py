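"""Immunoprofile comparison and summary metrics.

Samples are compared by the cosine similarity of their top-2500 peptide
abundance vectors (CSI); per-patient antibody-response maps use the top
immunodominant epitopes, mean-centered and autoscaled (Z-scores) across
the patient's paired samples, optionally capped at the 97.5th percentile
for display; treatment effects are summarized as log10 abundance ratios
and competition effects as relative abundances.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .discovery import EpitopePattern, as_pattern, pattern_abundance
from .repertoire import PeptideRepertoire, RepertoireError

#: Number of top peptides entering the cosine similarity index.
DEFAULT_TOP_N = 2500

#: Number of immunodominant epitopes kept per sample.
DEFAULT_TOP_K = 50

#: Display cap for per-patient Z-score maps.
DEFAULT_CAP_PERCENTILE = 97.5


def top_n_peptides(
    rep: PeptideRepertoire, n: int = DEFAULT_TOP_N
) -> list[tuple[str, float]]:
    """The n highest-abundance peptides, ties broken lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(rep.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:n]


def cosine_similarity(
    rep_a: PeptideRepertoire,
    rep_b: PeptideRepertoire,
    n: int = DEFAULT_TOP_N,
    full_values: bool = False,
) -> float:
    """Cosine similarity index (CSI) of two samples' top-n peptide profiles.

    Axes are the union of each sample's top-n peptides. By default a
    sample contributes its abundance only for peptides inside its own
    top-n list (zero elsewhere), tying both magnitude and membership to
    the top list; with ``full_values`` the full-repertoire abundance is
    used on the union axes instead. Returns 0 when either vector is
    all-zero; identical samples give exactly 1.
    """
    if not rep_a.counts or not rep_b.counts:
        raise RepertoireError("cosine_similarity: empty repertoire")
    top_a = dict(top_n_peptides(rep_a, n))
    top_b = dict(top_n_peptides(rep_b, n))
    axes = sorted(set(top_a) | set(top_b))
    if full_values:
        va = np.array([rep_a.counts.get(p, 0.0) for p in axes])
        vb = np.array([rep_b.counts.get(p, 0.0) for p in axes])
    else:
        va = np.array([top_a.get(p, 0.0) for p in axes])
        vb = np.array([top_b.get(p, 0.0) for p in axes])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(va, vb) / (na * nb))


def csi_matrix(
    reps: list[PeptideRepertoire], n: int = DEFAULT_TOP_N
) -> pd.DataFrame:
    """Symmetric CSI matrix over a list of samples."""
    ids = [r.sample_id for r in reps]
    out = pd.DataFrame(np.eye(len(reps)), index=ids, columns=ids)
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            v = cosine_similarity(reps[i], reps[j], n=n)
            out.iat[i, j] = v
            out.iat[j, i] = v
    return out


def top_k_epitopes(
    epitopes: list[EpitopePattern | str],
    reps: list[PeptideRepertoire],
    k: int = DEFAULT_TOP_K,
    rank_sample: str | None = None,
    count_mode: str = "reads",
) -> list[tuple[EpitopePattern, float]]:
    """The k most abundant (immunodominant) epitopes.

    Ranking abundance is taken in the designated sample (``rank_sample``;
    by default the first repertoire, conventionally the post-treatment
    one); ties are broken lexicographically by pattern.
    """
    if not reps:
        raise ValueError("no repertoires given")
    if rank_sample is None:
        rank_rep = reps[0]
    else:
        by_id = {r.sample_id: r for r in reps}
        if rank_sample not in by_id:
            raise KeyError(f"rank_sample {rank_sample!r} not among repertoires")
        rank_rep = by_id[rank_sample]
    scored = [
        (as_pattern(p), pattern_abundance(p, rank_rep, count_mode=count_mode))
        for p in epitopes
    ]
    scored.sort(key=lambda t: (-t[1], t[0].symbols))
    return scored[:k]


def abundance_matrix(
    epitopes: list[EpitopePattern | str],
    reps: list[PeptideRepertoire],
    count_mode: str = "reads",
) -> pd.DataFrame:
    """Epitope x sample abundance matrix (absent values are 0)."""
    patterns = [as_pattern(p) for p in epitopes]
    data = {
        rep.sample_id: [
            pattern_abundance(p, rep, count_mode=count_mode) for p in patterns
        ]
        for rep in reps
    }
    return pd.DataFrame(data, index=[p.symbols for p in patterns])


def zscore_map(
    matrix: pd.DataFrame,
    cap_percentile: float = DEFAULT_CAP_PERCENTILE,
    apply_cap: bool = True,
    symmetric_cap: bool = False,
) -> pd.DataFrame:
    """Mean-center and autoscale one patient's epitope x sample sub-matrix.

    One mean and one sample standard deviation (n-1 denominator) are
    computed over all entries; z = (x - mean) / sd. With ``apply_cap``,
    z-values above the patient's ``cap_percentile`` percentile are set to
    that percentile (upper-sided cap; ``symmetric_cap`` also floors at
    the mirrored lower percentile).
    """
    values = matrix.to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to autoscale")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise ValueError("constant matrix")
    z = (values - mean) / sd
    if apply_cap:
        hi = float(np.percentile(z, cap_percentile))
        z = np.minimum(z, hi)
        if symmetric_cap:
            lo = float(np.percentile(z, 100.0 - cap_percentile))
            z = np.maximum(z, lo)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def abundance_ratio(post: float, pre: float) -> float:
    """log10((post + 1) / (pre + 1)): treatment-induced abundance change.

    0 means unchanged reactivity; the +1 offsets keep zero abundances
    defined. Antisymmetric under swapping post and pre.
    """
    if post < 0 or pre < 0:
        raise ValueError("abundances must be non-negative")
    return math.log10((post + 1.0) / (pre + 1.0))


def competition_relative_abundance(competed: float, uncompeted: float) -> float:
    """Abundance in the competition sample relative to its uncompeted parent."""
    if uncompeted <= 0:
        raise ValueError("uncompeted abundance must be positive")
    if competed < 0:
        raise ValueError("competed abundance must be non-negative")
    return competed / uncompeted
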
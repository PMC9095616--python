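"""Group-differentiation statistics and biomarker panel selection.

Per-epitope discrimination between two sample groups is assessed with
the Wilcoxon rank-sum test (normal approximation with midranks,
tie-corrected variance and continuity correction) and an ROC analysis
in which the operating threshold maximizes Youden's index
J = sensitivity + specificity - 1. Markers passing sensitivity and
specificity floors are ranked, and small marker subsets are combined in
an unpenalized logistic regression scored by AUC (the rank-statistic /
Mann-Whitney formulation). No cross-validation is performed: reported
performance is apparent performance on the input samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from itertools import combinations

from scipy import stats

from .discovery import EpitopePattern, as_pattern


class BiomarkerError(ValueError):
    """Invalid biomarker-analysis input."""


@dataclass
class MarkerPerformance:
    """Per-epitope ROC summary at the Youden-optimal threshold."""

    pattern: EpitopePattern | None
    threshold: float
    sensitivity: float
    specificity: float
    youden: float
    wilcoxon_p: float = float("nan")

    def __post_init__(self) -> None:
        expected = self.sensitivity + self.specificity - 1.0
        if abs(self.youden - expected) > 1e-9:
            raise BiomarkerError("youden != sensitivity + specificity - 1")


@dataclass
class CombinedModel:
    """A fitted logistic combination of markers with its ROC summary."""

    markers: list[str]
    coefficients: np.ndarray  # intercept first
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    converged: bool
    warnings: list[str] = field(default_factory=list)


def _as_binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == bool:
        y = y.astype(int)
    uniq = set(np.unique(y).tolist())
    if not uniq.issubset({0, 1}):
        raise BiomarkerError(f"labels must be binary 0/1, got {sorted(uniq)}")
    if len(uniq) < 2:
        raise BiomarkerError("both classes must be present")
    return y.astype(int)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with continuity correction.

    Returns the rank-sum statistic W of the first sample (midranks for
    ties) and the two-sided p from the normal approximation with
    tie-corrected variance and continuity correction 0.5 (the base-R
    ``wilcox.test(correct=TRUE)`` convention). When every value is
    identical across both groups, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise BiomarkerError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if np.unique(pooled).size == 1:
        return w, 1.0
    _, p = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return w, float(p)


def roc_points(scores, labels) -> list[tuple[float, float, float]]:
    """ROC operating points under the rule "positive when score >= threshold".

    One point per candidate threshold: every distinct score value plus
    +infinity (the all-negative call). Sensitivity and specificity are
    exact confusion-matrix fractions.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels)
    if s.shape != y.shape:
        raise BiomarkerError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    thresholds = sorted(set(s.tolist())) + [math.inf]
    points = []
    for t in thresholds:
        called = s >= t
        sens = float((called & (y == 1)).sum()) / n_pos
        spec = float((~called & (y == 0)).sum()) / n_neg
        points.append((t, sens, spec))
    return points


def youden_optimal(scores, labels) -> MarkerPerformance:
    """The ROC point maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity, then lower threshold.
    """
    points = roc_points(scores, labels)
    best = max(points, key=lambda p: (p[1] + p[2] - 1.0, p[2], -_finite(p[0])))
    t, sens, spec = best
    return MarkerPerformance(
        pattern=None, threshold=t, sensitivity=sens, specificity=spec,
        youden=sens + spec - 1.0,
    )


def _finite(t: float) -> float:
    return t if math.isfinite(t) else float(np.finfo(float).max)


def auc(scores, labels) -> float:
    """Area under the ROC curve, rank-statistic (Mann-Whitney) formulation.

    The fraction of (positive, negative) pairs in which the positive
    sample scores strictly higher, counting ties as one half.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    ranks = stats.rankdata(s)
    r_pos = float(ranks[y == 1].sum())
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def rank_markers(
    matrix: pd.DataFrame,
    labels: dict[str, int] | pd.Series,
    min_sens: float = 0.72,
    min_spec: float = 0.67,
    k: int = 15,
) -> list[MarkerPerformance]:
    """Rank epitopes by group discrimination at their Youden-optimal cutoff.

    ``matrix`` is epitopes x samples (abundances); ``labels`` maps sample
    id to 0 (control) / 1 (case). Markers must exceed the sensitivity and
    specificity floors strictly; survivors are ranked by descending
    Youden's J, ties by ascending Wilcoxon p then pattern string, and the
    top ``k`` returned (possibly fewer).
    """
    lab = pd.Series(labels)
    lab = lab.reindex(matrix.columns)
    if lab.isna().any():
        missing = list(matrix.columns[lab.isna()])
        raise BiomarkerError(f"labels missing for samples {missing}")
    y = _as_binary_labels(lab.to_numpy())
    out: list[MarkerPerformance] = []
    for pattern, row in matrix.iterrows():
        scores = row.to_numpy(dtype=float)
        perf = youden_optimal(scores, y)
        if perf.sensitivity > min_sens and perf.specificity > min_spec:
            perf.pattern = as_pattern(pattern)
            _, p = wilcoxon_rank_sum(scores[y == 1], scores[y == 0])
            perf.wilcoxon_p = p
            out.append(perf)
    out.sort(key=lambda m: (-m.youden, m.wilcoxon_p, m.pattern.symbols))
    return out[:k]


def log10p1(values) -> np.ndarray:
    """The log10(x + 1) feature transform used before logistic fits."""
    return np.log10(np.asarray(values, dtype=float) + 1.0)


def marker_features(
    matrix: pd.DataFrame, markers: list[str], transform: str = "log10p1"
) -> pd.DataFrame:
    """Samples x markers feature table from an epitope x sample matrix."""
    if transform not in ("log10p1", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    sub = matrix.loc[list(markers)].T.astype(float)
    if transform == "log10p1":
        sub = np.log10(sub + 1.0)
    return sub


def fit_logistic(
    features: pd.DataFrame | np.ndarray,
    labels,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CombinedModel:
    """Unpenalized logistic regression by iteratively reweighted least squares.

    ``features`` is samples x markers, conventionally on the log10(x+1)
    scale. Constant and duplicate columns are dropped with a warning.
    Convergence: log-likelihood change < ``tol``; on complete separation
    the fit runs to the iteration cap, is flagged ``converged=False``,
    and scores/AUC/operating point are still reported (the ROC summary is
    invariant to the diverging coefficient scale).
    """
    if isinstance(features, pd.DataFrame):
        names = [str(c) for c in features.columns]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    y = _as_binary_labels(labels)
    if X.shape[0] != y.size:
        raise BiomarkerError("feature rows and labels differ in length")
    if int(y.sum()) < 2 or int((1 - y).sum()) < 2:
        raise BiomarkerError("need at least 2 samples per class")

    warn_msgs: list[str] = []
    keep: list[int] = []
    seen_cols: list[np.ndarray] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0.0:
            warn_msgs.append(f"dropped constant feature {names[j]!r}")
            continue
        if any(np.array_equal(col, c) for c in seen_cols):
            warn_msgs.append(f"dropped duplicate feature {names[j]!r}")
            continue
        keep.append(j)
        seen_cols.append(col)
    for msg in warn_msgs:
        warnings.warn(msg, stacklevel=2)
    if not keep:
        raise BiomarkerError("no informative features remain")
    Xk = X[:, keep]
    kept_names = [names[j] for j in keep]

    n, m = Xk.shape
    design = np.column_stack([np.ones(n), Xk])
    beta = np.zeros(m + 1)
    ll_old = -math.inf
    converged = False
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        mu_c = np.clip(mu, 1e-12, 1.0 - 1e-12)
        ll = float(y @ np.log(mu_c) + (1 - y) @ np.log(1.0 - mu_c))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        wd = design * w[:, None]
        try:
            beta = np.linalg.solve(design.T @ wd, design.T @ (w * z))
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(design.T @ wd, design.T @ (w * z),
                                       rcond=None)
    # A perfect fit (all fitted probabilities at their labels) means the
    # MLE does not exist: complete separation, coefficients diverging.
    eta = design @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    if np.all(np.abs(y - mu) < 1e-6):
        converged = False
    scores = design @ beta
    model_auc = auc(scores, y)
    op = youden_optimal(scores, y)
    if not converged:
        warn_msgs.append("non-convergence (possible complete separation)")
    return CombinedModel(
        markers=kept_names,
        coefficients=beta,
        auc=model_auc,
        sensitivity=op.sensitivity,
        specificity=op.specificity,
        threshold=op.threshold,
        converged=converged,
        warnings=warn_msgs,
    )


def best_subset(
    matrix: pd.DataFrame,
    labels: dict[str, int] | pd.Series,
    candidates: list[str],
    max_size: int = 3,
    transform: str = "log10p1",
) -> CombinedModel:
    """Exhaustive small-subset logistic search maximizing AUC.

    Fits every non-empty candidate subset of size <= ``max_size`` and
    returns the highest-AUC model; ties prefer the smaller subset, then
    lexicographic marker order.
    """
    if len(candidates) > 20:
        raise BiomarkerError("exhaustive subset search limited to 20 candidates")
    if not candidates:
        raise BiomarkerError("no candidate markers")
    lab = pd.Series(labels).reindex(matrix.columns)
    if lab.isna().any():
        raise BiomarkerError("labels missing for some samples")
    y = lab.to_numpy()
    best: tuple | None = None
    for size in range(1, max_size + 1):
        for subset in combinations(sorted(candidates), size):
            feats = marker_features(matrix, list(subset), transform=transform)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_logistic(feats, y)
            key = (-model.auc, size, tuple(subset))
            if best is None or key < best[0]:
                best = (key, model)
    return best[1]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional extension column)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj


def markers_to_frame(markers: list[MarkerPerformance]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "pattern": m.pattern.symbols if m.pattern else "",
                "threshold": m.threshold,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "youden": m.youden,
                "wilcoxon_p": m.wilcoxon_p,
            }
            for m in markers
        ],
        columns=["pattern", "threshold", "sensitivity", "specificity",
                 "youden", "wilcoxon_p"],
    )
    if len(df):
        df["wilcoxon_p_bh"] = benjamini_hochberg(df["wilcoxon_p"].to_numpy())
    else:
        df["wilcoxon_p_bh"] = []
    return df
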
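"""Functional similarity between annotation sets and the CAFA-style
evaluation suite (Fmax, AUPR, AUROC, coverage, IC-weighted Fmax,
Friedman/Nemenyi method comparison).

All set arguments are assumed true-path propagated with aspect roots
excluded; that convention is what makes precision/recall over GO terms
comparable across methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .ontology import AnnotationSet, InformationContent

__all__ = [
    "SimilarityConfig",
    "EvaluationResult",
    "protein_f1",
    "functional_similarity",
    "same_function",
    "fmax_sweep",
    "aupr",
    "auroc",
    "coverage",
    "icw_fmax",
    "friedman_nemenyi",
    "evaluate",
    "write_report",
    "DEFAULT_THRESHOLDS",
]

#: CAFA-convention threshold grid: 0.00, 0.01, ..., 1.00.
DEFAULT_THRESHOLDS = np.round(np.linspace(0.0, 1.0, 101), 2)

_METRICS = ("f1", "jaccard", "weighted_f1", "weighted_jaccard")


@dataclass(frozen=True)
class SimilarityConfig:
    """How protein-pair functional similarity is measured.

    ``cutoff`` is the threshold above which (strictly) two proteins count
    as having the same function for triplet mining.
    """

    metric: str = "f1"
    cutoff: float = 0.5
    ic_weights: InformationContent | Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValueError(f"unknown similarity metric {self.metric!r}")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must lie in [0,1]")
        if self.metric.startswith("weighted") and self.ic_weights is None:
            raise ValueError(f"{self.metric} requires ic_weights")


@dataclass
class EvaluationResult:
    """Per-aspect evaluation summary for one prediction method."""

    fmax: float
    t_star: float
    aupr: float
    auroc: float
    coverage: float
    icw_fmax: float | None = None
    curve: list[tuple[float, float, float]] = field(default_factory=list)
    per_protein_f1: dict[str, float] = field(default_factory=dict)


def protein_f1(pred: Iterable[str], truth: Iterable[str]) -> float:
    """F1-score between a predicted and a native GO term set.

    precision = |pred ∩ truth| / |pred|, recall = |pred ∩ truth| / |truth|.
    Returns 0 for an empty prediction or an empty intersection; an empty
    truth set leaves recall undefined and raises.
    """
    pred, truth = frozenset(pred), frozenset(truth)
    if not truth:
        raise ValueError("empty truth set: recall undefined")
    if not pred:
        return 0.0
    tp = len(pred & truth)
    if tp == 0:
        return 0.0
    # 2pr/(p+r) simplifies to 2*tp / (|pred| + |truth|)
    return 2.0 * tp / (len(pred) + len(truth))


def _ic_sum(terms: Iterable[str], ic: Mapping[str, float]) -> float:
    return float(sum(ic[t] for t in terms))


def functional_similarity(
    a: Iterable[str], b: Iterable[str], cfg: SimilarityConfig | None = None
) -> float:
    """Similarity of two propagated GO term sets in [0, 1].

    f1: 2|a∩b|/(|a|+|b|); jaccard: |a∩b|/|a∪b|; the weighted variants
    replace set cardinalities with information-content sums.  Two empty
    sets give 0.
    """
    cfg = cfg or SimilarityConfig()
    a, b = frozenset(a), frozenset(b)
    if not a and not b:
        return 0.0
    if cfg.metric == "f1":
        denom = len(a) + len(b)
        return 2.0 * len(a & b) / denom if denom else 0.0
    if cfg.metric == "jaccard":
        return len(a & b) / len(a | b)
    ic = cfg.ic_weights
    assert ic is not None
    if cfg.metric == "weighted_f1":
        denom = _ic_sum(a, ic) + _ic_sum(b, ic)
        return 2.0 * _ic_sum(a & b, ic) / denom if denom > 0 else 0.0
    denom = _ic_sum(a | b, ic)
    return _ic_sum(a & b, ic) / denom if denom > 0 else 0.0


def same_function(
    a: Iterable[str], b: Iterable[str], cfg: SimilarityConfig | None = None
) -> bool:
    """Whether two proteins count as functionally identical for triplet
    mining: similarity strictly greater than the cutoff."""
    cfg = cfg or SimilarityConfig()
    return functional_similarity(a, b, cfg) > cfg.cutoff


def _counts_at_threshold(
    scores: Mapping[str, Mapping[str, float]],
    truth: AnnotationSet,
    t: float,
    weights: Mapping[str, float] | None,
):
    """Per-protein (tp, n_pred, n_truth) at threshold t, count or IC-sum."""
    rows = []
    for protein, true_terms in truth.annotations.items():
        pred = {
            q for q, s in scores.get(protein, {}).items() if s >= t
        }
        if weights is None:
            tp = float(len(pred & true_terms))
            np_, nt = float(len(pred)), float(len(true_terms))
        else:
            tp = _ic_sum(pred & true_terms, weights)
            np_ = _ic_sum(pred, weights)
            nt = _ic_sum(true_terms, weights)
        rows.append((tp, np_, nt))
    return rows


def _pr_rc_at_threshold(rows, mode: str) -> tuple[float, float]:
    if mode == "micro":
        tp = sum(r[0] for r in rows)
        npred = sum(r[1] for r in rows)
        ntruth = sum(r[2] for r in rows)
        pr = tp / npred if npred > 0 else 0.0
        rc = tp / ntruth if ntruth > 0 else 0.0
        return pr, rc
    # cafa mode: precision averaged over proteins with >=1 prediction,
    # recall averaged over all proteins
    precisions = [tp / npred for tp, npred, _ in rows if npred > 0]
    recalls = [tp / ntruth for tp, _, ntruth in rows if ntruth > 0]
    pr = float(np.mean(precisions)) if precisions else 0.0
    rc = float(np.mean(recalls)) if recalls else 0.0
    return pr, rc


def fmax_sweep(
    scores: Mapping[str, Mapping[str, float]],
    truth: AnnotationSet,
    thresholds: Sequence[float] | None = None,
    mode: str = "cafa",
    weights: Mapping[str, float] | None = None,
) -> tuple[float, float, list[tuple[float, float, float]]]:
    """Sweep confidence thresholds and return (Fmax, t*, curve).

    At each threshold t the predicted set of a protein is every term with
    confidence >= t.  ``mode='micro'`` pools tp/fp/fn over all proteins;
    ``mode='cafa'`` averages precision over proteins with at least one
    prediction and recall over all proteins.  ``thresholds=None`` uses the
    0.01-step CAFA grid; pass ``'exact'`` to sweep every distinct score.
    The curve is a list of (t, precision, recall) for AUPR integration.
    """
    if mode not in ("micro", "cafa"):
        raise ValueError(f"unknown Fmax mode {mode!r}")
    if not truth.annotations or all(
        (len(v) == 0 for v in truth.annotations.values())
    ):
        raise ValueError("empty ground truth")
    if weights is not None:
        truth_ics = [
            _ic_sum(v, weights) for v in truth.annotations.values() if v
        ]
        if truth_ics and max(truth_ics) <= 0:
            raise ValueError("all ground-truth terms carry zero IC")
    if thresholds is None:
        grid = DEFAULT_THRESHOLDS
    elif isinstance(thresholds, str) and thresholds == "exact":
        distinct = {
            s for term_scores in scores.values() for s in term_scores.values()
        }
        grid = np.array(sorted(distinct | {0.0}))
    else:
        grid = np.asarray(thresholds, dtype=float)

    curve: list[tuple[float, float, float]] = []
    fmax, t_star = 0.0, float(grid[0])
    for t in grid:
        rows = _counts_at_threshold(scores, truth, float(t), weights)
        pr, rc = _pr_rc_at_threshold(rows, mode)
        curve.append((float(t), pr, rc))
        if pr + rc > 0:
            f1 = 2 * pr * rc / (pr + rc)
            if f1 > fmax:
                fmax, t_star = f1, float(t)
    return fmax, t_star, curve


def aupr(curve: Sequence[tuple[float, float, float]]) -> float:
    """Area under the precision-recall curve from a threshold sweep.

    Integrates the interpolated precision envelope: at recall level r the
    precision is the maximum precision among curve points with recall >= r
    (the standard non-increasing PR interpolation), integrated stepwise
    from recall 0 to the largest attained recall.
    """
    if len(curve) < 2:
        raise ValueError("need at least two curve points")
    pts = sorted(((rc, pr) for _, pr, rc in curve), key=lambda x: x[0])
    recalls = np.array([p[0] for p in pts])
    precisions = np.array([p[1] for p in pts])
    # max precision over points with recall >= r: suffix maximum
    envelope = np.maximum.accumulate(precisions[::-1])[::-1]
    area = 0.0
    prev_r = 0.0
    for r, p in zip(recalls, envelope):
        if r > prev_r:
            area += (r - prev_r) * p
            prev_r = r
    return float(area)


def auroc(
    scores: Mapping[str, Mapping[str, float]],
    truth: AnnotationSet,
    terms: Iterable[str] | None = None,
    per_term: bool = False,
):
    """AUROC of confidence scores against 0/1 term labels.

    Micro mode (default) ranks all (protein, term) pairs jointly; ties are
    handled by the average-rank (Mann-Whitney) convention of the
    underlying implementation.  ``per_term=True`` returns a dict of
    term -> AUROC over proteins (terms with one class are skipped).
    """
    term_list = sorted(terms) if terms is not None else sorted(truth.terms())
    proteins = sorted(truth.annotations)
    y = np.array(
        [
            [1 if q in truth.annotations[p] else 0 for q in term_list]
            for p in proteins
        ]
    )
    s = np.array(
        [[scores.get(p, {}).get(q, 0.0) for q in term_list] for p in proteins]
    )
    if per_term:
        out = {}
        for j, q in enumerate(term_list):
            col = y[:, j]
            if col.min() == col.max():
                continue
            out[q] = float(roc_auc_score(col, s[:, j]))
        return out
    flat_y, flat_s = y.ravel(), s.ravel()
    if flat_y.min() == flat_y.max():
        raise ValueError("AUROC undefined: labels are single-class")
    return float(roc_auc_score(flat_y, flat_s))


def coverage(
    scores: Mapping[str, Mapping[str, float]], proteins: Iterable[str]
) -> float:
    """Fraction of test proteins with at least one nonzero prediction."""
    proteins = list(proteins)
    if not proteins:
        raise ValueError("empty protein list")
    covered = sum(
        1
        for p in proteins
        if any(v > 0 for v in scores.get(p, {}).values())
    )
    return covered / len(proteins)


def icw_fmax(
    scores: Mapping[str, Mapping[str, float]],
    truth: AnnotationSet,
    ic: Mapping[str, float],
    thresholds: Sequence[float] | None = None,
    mode: str = "cafa",
) -> tuple[float, float]:
    """Information-content weighted Fmax: the threshold sweep of
    :func:`fmax_sweep` with tp/fp/fn counts replaced by IC sums, so
    shallow uninformative terms contribute little."""
    f, t, _ = fmax_sweep(scores, truth, thresholds, mode=mode, weights=ic)
    return f, t


def friedman_nemenyi(
    f1_matrix: np.ndarray,
    p_floor: float = 1e-3,
    p_ceiling: float = 0.9,
) -> tuple[float, np.ndarray]:
    """Friedman test plus Nemenyi post-hoc on a proteins x methods matrix
    of per-protein F1 scores.

    Returns (friedman_p, pairwise_p) where pairwise_p[i, j] is the Nemenyi
    p-value for methods i and j, computed from the studentized-range
    distribution of mean-rank differences and clamped to
    [p_floor, p_ceiling], the range in which the statistic is reliably
    approximated.  Within-protein ties receive average ranks.
    """
    x = np.asarray(f1_matrix, dtype=float)
    n, k = x.shape
    if k < 3:
        raise ValueError("Friedman test needs >= 3 methods")
    if n < 2:
        raise ValueError("Friedman test needs >= 2 proteins")
    if np.all(x.max(axis=1) == x.min(axis=1)):
        raise ValueError("all rows constant: Friedman statistic degenerate")
    _, friedman_p = stats.friedmanchisquare(*(x[:, j] for j in range(k)))

    ranks = np.vstack([stats.rankdata(row) for row in x])
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    pairwise = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            p = float(stats.studentized_range.sf(q, k, np.inf))
            p = min(max(p, p_floor), p_ceiling)
            pairwise[i, j] = pairwise[j, i] = p
    return float(friedman_p), pairwise


def evaluate(
    scores: Mapping[str, Mapping[str, float]],
    truth: AnnotationSet,
    test_proteins: Iterable[str] | None = None,
    ic: Mapping[str, float] | None = None,
    thresholds: Sequence[float] | None = None,
    mode: str = "cafa",
) -> EvaluationResult:
    """Full evaluation of one method on one aspect."""
    fmax, t_star, curve = fmax_sweep(scores, truth, thresholds, mode=mode)
    result = EvaluationResult(
        fmax=fmax,
        t_star=t_star,
        aupr=aupr(curve),
        auroc=auroc(scores, truth),
        coverage=coverage(
            scores, test_proteins if test_proteins is not None else truth.annotations
        ),
        curve=curve,
    )
    if ic is not None:
        result.icw_fmax = icw_fmax(scores, truth, ic, thresholds, mode=mode)[0]
    result.per_protein_f1 = {
        p: protein_f1(
            {q for q, s in scores.get(p, {}).items() if s >= t_star}, terms
        )
        for p, terms in truth.annotations.items()
        if terms
    }
    return result


def write_report(
    results: Mapping[str, Mapping[str, EvaluationResult]],
    path: str | Path,
) -> None:
    """Write a per-aspect TSV report: one row per (method, aspect)."""
    cols = ["method", "aspect", "fmax", "t_star", "aupr", "auroc", "coverage", "icw_fmax"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for method, per_aspect in results.items():
            for aspect, r in per_aspect.items():
                icw = "" if r.icw_fmax is None else f"{r.icw_fmax:.3f}"
                fh.write(
                    f"{method}\t{aspect}\t{r.fmax:.3f}\t{r.t_star:.2f}\t"
                    f"{r.aupr:.3f}\t{r.auroc:.3f}\t{r.coverage:.2f}\t{icw}\n"
                )
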
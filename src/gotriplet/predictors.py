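"""Turning evidence into per-protein GO confidence scores.

All predictors speak the same currency: a mapping protein -> term ->
confidence in [0, 1] (wrapped in :class:`ScoreVector`).  The main route
is guilt-by-association over the trained metric embedding (rank-weighted
k-nearest-neighbour label transfer) combined with the network's sigmoid
head; homology (consensus and single-template), naive-prior and
protein-protein-interaction predictors serve as baselines and as the
homology component of the composite score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ontology import AnnotationSet

__all__ = [
    "ScoreVector",
    "AlignmentHit",
    "PpiEdge",
    "CombinationWeights",
    "gba_scores",
    "combine_internal",
    "sagp_scores",
    "blast_baseline_scores",
    "ngp_scores",
    "ppigp_scores",
    "combine_composite",
    "read_hits_tsv",
    "read_ppi_tsv",
    "write_predictions",
    "read_predictions",
]


@dataclass
class ScoreVector:
    """Protein -> term -> confidence in [0, 1] for one GO aspect."""

    scores: dict[str, dict[str, float]]
    aspect: str
    postprocessed: bool = False

    def __post_init__(self) -> None:
        for p, terms in self.scores.items():
            for q, v in terms.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"score {v} for {p}/{q} outside [0,1]")

    def __getitem__(self, protein: str) -> dict[str, float]:
        return self.scores[protein]

    def get(self, protein: str) -> dict[str, float]:
        return self.scores.get(protein, {})

    def proteins(self) -> list[str]:
        return sorted(self.scores)

    def covered(self) -> frozenset[str]:
        return frozenset(
            p for p, t in self.scores.items() if any(v > 0 for v in t.values())
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a tabular sequence-search result."""

    query: str
    template: str
    identity: float  # percent, 0-100
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0,100]")
        if self.evalue < 0:
            raise ValueError("negative e-value")


@dataclass(frozen=True)
class PpiEdge:
    """Undirected protein-protein interaction with a confidence weight."""

    a: str
    b: str
    weight: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-loop on {self.a}")
        if self.weight < 0:
            raise ValueError("negative PPI weight")


@dataclass(frozen=True)
class CombinationWeights:
    """Weights of the two score combinations.

    ``w`` mixes the guilt-by-association and sigmoid-head scores of the
    network; ``beta`` (per aspect) mixes the network score with the
    homology consensus in the composite predictor.  The per-aspect betas
    default to the validation-tuned values 0.57 (MF), 0.60 (BP),
    0.67 (CC).
    """

    w: float = 0.5
    beta: Mapping[str, float] = field(
        default_factory=lambda: {"MF": 0.57, "BP": 0.60, "CC": 0.67}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0,1]")
        for aspect, b in self.beta.items():
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"beta[{aspect}]={b} outside [0,1]")


def gba_scores(
    query_embedding: np.ndarray,
    train_embeddings: Mapping[str, np.ndarray],
    train_annotations: AnnotationSet,
    k: int = 10,
) -> dict[str, float]:
    """Rank-weighted k-nearest-neighbour annotation transfer.

    The K training proteins closest (Euclidean) to the query in the
    trained metric space vote for their terms with weights
    w_k = 1 - (r_k - 1)/K, r_k the neighbour's rank; the confidence of a
    term is the weight fraction of neighbours annotated with it.  Distance
    ties break lexicographically on protein ID.
    """
    proteins = sorted(set(train_embeddings) & set(train_annotations.annotations))
    if k > len(proteins):
        raise ValueError(f"K={k} exceeds training size {len(proteins)}")
    if k < 1:
        raise ValueError("K must be >= 1")
    q = np.asarray(query_embedding, dtype=float)
    dists = [(float(np.linalg.norm(q - train_embeddings[p])), p) for p in proteins]
    dists.sort()  # (distance, protein ID) lexicographic
    top = dists[:k]
    weights = np.array([1.0 - r / k for r in range(k)])  # r_k-1 = 0..K-1
    total = float(weights.sum())
    votes: dict[str, float] = {}
    for (_, p), w in zip(top, weights):
        for term in train_annotations.annotations[p]:
            votes[term] = votes.get(term, 0.0) + w
    return {q_: v / total for q_, v in votes.items()}


def combine_internal(
    s_gba: Mapping[str, Mapping[str, float]],
    s_saf: Mapping[str, Mapping[str, float]],
    w: float = 0.5,
) -> dict[str, dict[str, float]]:
    """Convex combination w*gba + (1-w)*saf, elementwise over the union
    of scored terms (a term missing from one side scores 0 there)."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0,1]")
    if set(s_gba) != set(s_saf):
        raise ValueError("protein index mismatch between score vectors")
    out: dict[str, dict[str, float]] = {}
    for p in s_gba:
        terms = set(s_gba[p]) | set(s_saf[p])
        out[p] = {
            q: w * s_gba[p].get(q, 0.0) + (1.0 - w) * s_saf[p].get(q, 0.0)
            for q in terms
        }
    return out


def sagp_scores(
    hits: Sequence[AlignmentHit],
    template_annotations: AnnotationSet,
    top_n: int = 10,
    evalue_cutoff: float = 1e-3,
) -> dict[str, float]:
    """Consensus homology transfer over multiple templates.

    Retains hits with e-value <= cutoff and annotated templates, keeps the
    ``top_n`` by bitscore, and scores each term by the bitscore-weighted
    fraction of retained templates carrying it:
    s(q) = sum_i b_i * I_i(q) / sum_i b_i.  An empty retained list leaves
    the query uncovered (empty mapping).
    """
    retained = [
        h
        for h in hits
        if h.evalue <= evalue_cutoff
        and h.template in template_annotations.annotations
    ]
    retained.sort(key=lambda h: (-h.bitscore, h.template))
    retained = retained[:top_n]
    if not retained:
        return {}
    total = sum(h.bitscore for h in retained)
    if total <= 0:
        return {}
    votes: dict[str, float] = {}
    for h in retained:
        for q in template_annotations.annotations[h.template]:
            votes[q] = votes.get(q, 0.0) + h.bitscore
    return {q: v / total for q, v in votes.items()}


def blast_baseline_scores(
    hits: Sequence[AlignmentHit],
    template_annotations: AnnotationSet,
    evalue_cutoff: float = 1e-3,
) -> dict[str, float]:
    """Single-template baseline: s(q) = max over annotated templates
    carrying q of (sequence identity / 100)."""
    out: dict[str, float] = {}
    for h in hits:
        if h.evalue > evalue_cutoff:
            continue
        terms = template_annotations.annotations.get(h.template)
        if not terms:
            continue
        s = h.identity / 100.0
        for q in terms:
            if s > out.get(q, 0.0):
                out[q] = s
    return out


def ngp_scores(train_annotations: AnnotationSet) -> dict[str, float]:
    """Naive prior: each term scored by its training annotation frequency,
    identically for every query (coverage is always 1)."""
    n = len(train_annotations.annotations)
    if n == 0:
        raise ValueError("empty training set")
    counts: dict[str, int] = {}
    for terms in train_annotations.annotations.values():
        for q in terms:
            counts[q] = counts.get(q, 0) + 1
    return {q: c / n for q, c in counts.items()}


def ppigp_scores(
    query: str,
    edges: Sequence[PpiEdge],
    partner_annotations: AnnotationSet,
) -> dict[str, float]:
    """Confidence-weighted vote over a query's interaction partners.

    s(q) = sum_p w_p * I_p(q) / sum_p w_p over annotated partners; a
    protein with no annotated partner is left uncovered (empty mapping).
    """
    partners: dict[str, float] = {}
    for e in edges:
        other = e.b if e.a == query else e.a if e.b == query else None
        if other is None or other not in partner_annotations.annotations:
            continue
        partners[other] = max(partners.get(other, 0.0), e.weight)
    total = sum(partners.values())
    if total <= 0:
        return {}
    votes: dict[str, float] = {}
    for p, w in partners.items():
        for q in partner_annotations.annotations[p]:
            votes[q] = votes.get(q, 0.0) + w
    return {q: v / total for q, v in votes.items()}


def combine_composite(
    s_main: Mapping[str, Mapping[str, float]],
    s_homology: Mapping[str, Mapping[str, float]],
    aspect: str,
    weights: CombinationWeights | None = None,
) -> dict[str, dict[str, float]]:
    """Composite score beta*s_main + (1-beta)*s_homology with the
    aspect-specific beta; proteins uncovered by the homology component
    contribute 0 on that side."""
    weights = weights or CombinationWeights()
    beta = weights.beta[aspect]
    out: dict[str, dict[str, float]] = {}
    for p in s_main:
        hom = s_homology.get(p, {})
        terms = set(s_main[p]) | set(hom)
        out[p] = {
            q: beta * s_main[p].get(q, 0.0) + (1.0 - beta) * hom.get(q, 0.0)
            for q in terms
        }
    return out


# ---------------------------------------------------------------------------
# tabular I/O


def read_hits_tsv(path: str | Path) -> dict[str, list[AlignmentHit]]:
    """Read outfmt-6-style hits: qseqid, sseqid, pident, evalue, bitscore."""
    out: dict[str, list[AlignmentHit]] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            q, s, pident, evalue, bits = line.split("\t")[:5]
            out.setdefault(q, []).append(
                AlignmentHit(
                    query=q,
                    template=s,
                    identity=float(pident),
                    evalue=float(evalue),
                    bitscore=float(bits),
                )
            )
    return out


def read_ppi_tsv(path: str | Path) -> list[PpiEdge]:
    """Read a 3-column protein-A, protein-B, weight edge list."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            a, b, w = line.split("\t")[:3]
            edges.append(PpiEdge(a=a, b=b, weight=float(w)))
    return edges


def write_predictions(
    scores: Mapping[str, Mapping[str, float]],
    path: str | Path,
    floor: float = 0.01,
) -> None:
    """Write CAFA-style predictions: protein, term, score to 3 decimals;
    scores below ``floor`` are omitted."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in sorted(scores):
            for q in sorted(scores[p]):
                v = scores[p][q]
                if v >= floor:
                    fh.write(f"{p}\t{q}\t{v:.3f}\n")


def read_predictions(path: str | Path) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            p, q, v = line.split("\t")[:3]
            out.setdefault(p, {})[q] = float(v)
    return out
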
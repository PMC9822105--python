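"""Multi-view fusion network and triplet metric learning.

The predictor consumes, per protein, three fixed-width embedding vectors
(the mean-pooled outputs of the last three layers of a pre-trained
protein language model, treated here as opaque inputs).  Each view passes
through its own dense layer, the three hidden vectors are concatenated
and fused by a further dense layer whose output is both (a) the metric
embedding used for guilt-by-association transfer and (b) the input of a
sigmoid output head giving per-term confidence scores.

Training minimises a composite objective: a batch-hard triplet loss on
the metric embedding (pulling functionally similar proteins together and
pushing dissimilar ones apart by at least a margin) plus a weighted
binary cross-entropy on the sigmoid head.  The network and its Adam
optimisation are implemented directly on numpy arrays; at the problem
sizes this package targets that keeps the dependency surface small and
the runs bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .metrics import SimilarityConfig, same_function
from .ontology import AnnotationSet

__all__ = [
    "EmbeddingBundle",
    "ModelConfig",
    "TrainingConfig",
    "FusionNetwork",
    "TrainedModel",
    "mean_pool",
    "triplet_loss",
    "batch_hard_loss",
    "margin_violation_rate",
    "cross_entropy_loss",
    "composite_loss",
    "train_model",
    "ensemble_average",
]

_EPS = 1e-7  # cross-entropy clamp


def mean_pool(matrix: np.ndarray) -> np.ndarray:
    """Column mean of an L x D per-residue embedding matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValueError("mean_pool expects a non-empty L x D matrix")
    return matrix.mean(axis=0)


@dataclass
class EmbeddingBundle:
    """Per-protein triplets of pooled embedding vectors (3 x D each)."""

    vectors: dict[str, np.ndarray]
    dim: int

    def __post_init__(self) -> None:
        for pid, arr in self.vectors.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (3, self.dim):
                raise ValueError(
                    f"{pid}: expected shape (3, {self.dim}), got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{pid}: non-finite embedding values")
            self.vectors[pid] = arr

    def __contains__(self, pid: str) -> bool:
        return pid in self.vectors

    def __getitem__(self, pid: str) -> np.ndarray:
        return self.vectors[pid]

    def proteins(self) -> list[str]:
        return sorted(self.vectors)

    @classmethod
    def from_matrices(
        cls, matrices: Mapping[str, Sequence[np.ndarray]]
    ) -> "EmbeddingBundle":
        """Pool per-residue L x D matrices (three views per protein)."""
        vectors = {
            pid: np.stack([mean_pool(m) for m in views])
            for pid, views in matrices.items()
        }
        dim = next(iter(vectors.values())).shape[1]
        return cls(vectors=vectors, dim=dim)

    @classmethod
    def load_npz(cls, path: str | Path) -> "EmbeddingBundle":
        """Load a keyed archive: one 3 x D array per protein ID.

        This is the expected layout for language-model embeddings: for
        each protein, stack the mean-pooled final three hidden-layer
        outputs (e.g. ESM-1b layers 31-33, D = 1280) into a 3 x D array
        stored under the protein's ID.
        """
        with np.load(path) as data:
            vectors = {pid: np.asarray(data[pid], dtype=float) for pid in data.files}
        dim = next(iter(vectors.values())).shape[1]
        return cls(vectors=vectors, dim=dim)

    def save_npz(self, path: str | Path) -> None:
        np.savez(path, **self.vectors)

    def stacked(self, proteins: Sequence[str]) -> tuple[np.ndarray, ...]:
        """Three n x D view matrices in the given protein order."""
        arr = np.stack([self.vectors[p] for p in proteins])  # n x 3 x D
        return arr[:, 0, :], arr[:, 1, :], arr[:, 2, :]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the fusion network."""

    dim: int
    terms: tuple[str, ...]
    n1: int = 1024
    n2: int = 1024

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("hidden widths must be positive")
        if len(self.terms) == 0:
            raise ValueError("candidate term set is empty")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the composite triplet + cross-entropy training.

    Defaults: margin 1.0, functional-similarity cutoff 0.5, loss balance
    alpha 1.0 and K = 10 templates, each tunable against validation Fmax.
    """

    margin: float = 1.0
    cf: float = 0.5
    alpha: float = 1.0
    k_templates: int = 10
    seed: int = 0
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    n_runs: int = 10
    similarity_metric: str = "f1"
    sampler: str = "shuffle"  # or "similarity_aware"

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.sampler not in ("shuffle", "similarity_aware"):
            raise ValueError(f"unknown sampler {self.sampler!r}")

    def similarity_config(
        self, ic_weights: Mapping[str, float] | None = None
    ) -> SimilarityConfig:
        return SimilarityConfig(
            metric=self.similarity_metric, cutoff=self.cf, ic_weights=ic_weights
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class FusionNetwork:
    """Three per-view dense layers (ReLU), a linear fused layer producing
    the metric embedding, and a sigmoid output head over candidate terms."""

    VIEWS = 3

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        d, n1, n2, nq = config.dim, config.n1, config.n2, len(config.terms)
        self.params: dict[str, np.ndarray] = {}
        for v in range(self.VIEWS):
            self.params[f"W{v}"] = _glorot(rng, d, n1)
            self.params[f"b{v}"] = np.zeros(n1)
        self.params["Wa"] = _glorot(rng, self.VIEWS * n1, n2)
        self.params["ba"] = np.zeros(n2)
        self.params["Wo"] = _glorot(rng, n2, nq)
        self.params["bo"] = np.zeros(nq)

    def forward(
        self, views: Sequence[np.ndarray], cache: bool = False
    ):
        """Map three n x D view matrices to (embedding, scores).

        embedding: n x N2 metric-space vectors (fused layer output);
        scores: n x |Q| sigmoid confidences, strictly inside (0, 1).
        """
        if len(views) != self.VIEWS:
            raise ValueError(f"expected {self.VIEWS} views, got {len(views)}")
        views = [np.atleast_2d(np.asarray(v, dtype=float)) for v in views]
        for v in views:
            if v.shape[1] != self.config.dim:
                raise ValueError(
                    f"view width {v.shape[1]} != configured dim {self.config.dim}"
                )
        hs, pre = [], []
        for i, x in enumerate(views):
            a = x @ self.params[f"W{i}"] + self.params[f"b{i}"]
            pre.append(a)
            hs.append(np.maximum(a, 0.0))
        h = np.concatenate(hs, axis=1)
        z = h @ self.params["Wa"] + self.params["ba"]
        logits = z @ self.params["Wo"] + self.params["bo"]
        s = 1.0 / (1.0 + np.exp(-logits))
        if cache:
            return z, s, {"views": views, "pre": pre, "h": h}
        return z, s

    def embed(self, views: Sequence[np.ndarray]) -> np.ndarray:
        return self.forward(views)[0]

    def backward(
        self,
        cache: dict,
        d_z: np.ndarray,
        d_logits: np.ndarray,
    ) -> dict[str, np.ndarray]:
        """Gradients of the loss given upstream gradients on the metric
        embedding (d_z) and the output logits (d_logits)."""
        grads: dict[str, np.ndarray] = {}
        z_grad = d_z + d_logits @ self.params["Wo"].T
        # output head: logits = z @ Wo + bo; z itself feeds the head
        # recompute z from cache pieces
        h = cache["h"]
        z = h @ self.params["Wa"] + self.params["ba"]
        grads["Wo"] = z.T @ d_logits
        grads["bo"] = d_logits.sum(axis=0)
        grads["Wa"] = h.T @ z_grad
        grads["ba"] = z_grad.sum(axis=0)
        d_h = z_grad @ self.params["Wa"].T
        n1 = self.config.n1
        for i in range(self.VIEWS):
            d_hi = d_h[:, i * n1 : (i + 1) * n1] * (cache["pre"][i] > 0)
            grads[f"W{i}"] = cache["views"][i].T @ d_hi
            grads[f"b{i}"] = d_hi.sum(axis=0)
        return grads

    def save(self, path: str | Path) -> None:
        meta = {
            "dim": self.config.dim,
            "n1": self.config.n1,
            "n2": self.config.n2,
            "terms": list(self.config.terms),
            "seed": self.seed,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "FusionNetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        net = cls(
            ModelConfig(
                dim=meta["dim"],
                terms=tuple(meta["terms"]),
                n1=meta["n1"],
                n2=meta["n2"],
            ),
            seed=meta["seed"],
        )
        net.params = params
        return net


def triplet_loss(
    anchor: np.ndarray,
    positive: np.ndarray,
    negative: np.ndarray,
    margin: float = 1.0,
) -> float:
    """Single-triplet hinge loss max(d(a,p) + margin - d(a,n), 0) with
    Euclidean distances."""
    anchor, positive, negative = map(np.asarray, (anchor, positive, negative))
    d_pos = float(np.linalg.norm(anchor - positive))
    d_neg = float(np.linalg.norm(anchor - negative))
    # (d_pos - d_neg) first so equal distances cancel exactly
    return max((d_pos - d_neg) + margin, 0.0)


def _pair_masks(
    term_sets: Sequence[frozenset[str]], simcfg: SimilarityConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean positive/negative masks over a batch; anchors are never
    their own positives (self excluded by index)."""
    n = len(term_sets)
    pos = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if same_function(term_sets[i], term_sets[j], simcfg):
                pos[i, j] = pos[j, i] = True
    eye = np.eye(n, dtype=bool)
    neg = ~pos & ~eye
    return pos, neg


def _distance_matrix(z: np.ndarray) -> np.ndarray:
    sq = np.sum(z**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (z @ z.T)
    return np.sqrt(np.maximum(d2, 0.0))


def _batch_hard(
    z: np.ndarray,
    pos_mask: np.ndarray,
    neg_mask: np.ndarray,
    margin: float,
    want_grad: bool = False,
):
    """Batch-hard triplet loss and (optionally) its gradient on z.

    Per valid anchor x: max(d(x, hardest positive) + margin -
    d(x, hardest negative), 0), where the hardest positive is the
    farthest same-function protein and the hardest negative the closest
    different-function one; the loss is the mean over valid anchors.
    """
    n = z.shape[0]
    dist = _distance_matrix(z)
    valid = pos_mask.any(axis=1) & neg_mask.any(axis=1)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        raise ValueError("batch contains no anchor with both a positive and a negative")
    losses = np.zeros(idx.size)
    grad = np.zeros_like(z) if want_grad else None
    n_violations = 0
    for a, i in enumerate(idx):
        dp = np.where(pos_mask[i], dist[i], -np.inf)
        dn = np.where(neg_mask[i], dist[i], np.inf)
        p = int(np.argmax(dp))  # ties -> lowest index (protein order)
        q = int(np.argmin(dn))
        val = (dist[i, p] - dist[i, q]) + margin
        if val > 0:
            losses[a] = val
            n_violations += 1
            if want_grad:
                c = 1.0 / idx.size
                if dist[i, p] > 0:
                    g = c * (z[i] - z[p]) / dist[i, p]
                    grad[i] += g
                    grad[p] -= g
                if dist[i, q] > 0:
                    g = c * (z[i] - z[q]) / dist[i, q]
                    grad[i] -= g
                    grad[q] += g
    loss = float(losses.sum() / idx.size)
    if want_grad:
        return loss, grad, n_violations, idx.size
    return loss, n_violations, idx.size


def batch_hard_loss(
    embeddings: np.ndarray,
    term_sets: Sequence[Iterable[str]],
    margin: float = 1.0,
    simcfg: SimilarityConfig | None = None,
    warn_skipped: bool = True,
) -> float:
    """Batch-hard triplet loss over a batch of metric embeddings.

    ``term_sets`` are the propagated GO annotations defining, through the
    functional-similarity cutoff, which proteins count as positives.
    Anchors lacking either a positive or a negative are skipped (with a
    warning); a batch with no valid anchor raises.
    """
    simcfg = simcfg or SimilarityConfig()
    term_sets = [frozenset(t) for t in term_sets]
    z = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if z.shape[0] != len(term_sets):
        raise ValueError("embeddings and term_sets length mismatch")
    pos, neg = _pair_masks(term_sets, simcfg)
    valid = pos.any(axis=1) & neg.any(axis=1)
    if warn_skipped and not valid.all():
        warnings.warn(
            f"skipping {int((~valid).sum())} anchors without a valid triplet",
            stacklevel=2,
        )
    loss, _, _ = _batch_hard(z, pos, neg, margin)
    return loss


def margin_violation_rate(
    embeddings: np.ndarray,
    term_sets: Sequence[Iterable[str]],
    margin: float = 1.0,
    simcfg: SimilarityConfig | None = None,
) -> float:
    """Fraction of valid anchors whose hardest triplet violates the margin."""
    simcfg = simcfg or SimilarityConfig()
    term_sets = [frozenset(t) for t in term_sets]
    z = np.atleast_2d(np.asarray(embeddings, dtype=float))
    pos, neg = _pair_masks(term_sets, simcfg)
    _, n_viol, n_valid = _batch_hard(z, pos, neg, margin)
    return n_viol / n_valid


def cross_entropy_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy (natural log) over proteins and terms,
    with scores clamped away from {0, 1} by 1e-7."""
    s = np.clip(np.asarray(scores, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(labels, dtype=float)
    return float(-np.mean(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)))


def composite_loss(
    embeddings: np.ndarray,
    scores: np.ndarray,
    term_sets: Sequence[Iterable[str]],
    labels: np.ndarray,
    margin: float = 1.0,
    alpha: float = 1.0,
    simcfg: SimilarityConfig | None = None,
) -> float:
    """Triplet loss plus alpha times cross-entropy."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    lt = batch_hard_loss(embeddings, term_sets, margin, simcfg, warn_skipped=False)
    lc = cross_entropy_loss(scores, labels)
    return lt + alpha * lc


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedModel:
    """A trained fusion network plus its training-set outputs."""

    network: FusionNetwork
    proteins: list[str]
    embeddings: dict[str, np.ndarray]
    saf_scores: dict[str, dict[str, float]]
    history: list[dict] = field(default_factory=list)

    def embed_bundle(self, bundle: EmbeddingBundle, proteins: Sequence[str] | None = None):
        """Metric embeddings and sigmoid-head scores for new proteins."""
        proteins = list(proteins) if proteins is not None else bundle.proteins()
        z, s = self.network.forward(bundle.stacked(proteins))
        terms = self.network.config.terms
        emb = {p: z[i] for i, p in enumerate(proteins)}
        saf = {
            p: {q: float(s[i, j]) for j, q in enumerate(terms)}
            for i, p in enumerate(proteins)
        }
        return emb, saf


def _batches(
    n: int,
    batch_size: int,
    rng: np.random.Generator,
    sampler: str,
    pos_mask: np.ndarray,
) -> list[np.ndarray]:
    if sampler == "shuffle" or n <= batch_size:
        perm = rng.permutation(n)
        return [perm[i : i + batch_size] for i in range(0, n, batch_size)]
    # similarity-aware: half the batch random, the other half a random
    # positive partner of each seed when one exists, guaranteeing triplets
    perm = rng.permutation(n)
    batches = []
    half = max(batch_size // 2, 1)
    for i in range(0, n, half):
        seeds = perm[i : i + half]
        extras = []
        for s in seeds:
            partners = np.flatnonzero(pos_mask[s])
            if partners.size:
                extras.append(int(rng.choice(partners)))
        batch = np.unique(np.concatenate([seeds, np.array(extras, dtype=int)]))
        batches.append(batch)
    return batches


def train_model(
    bundle: EmbeddingBundle,
    annotations: AnnotationSet,
    model_config: ModelConfig,
    training: TrainingConfig,
    validation: tuple[EmbeddingBundle, AnnotationSet] | None = None,
) -> TrainedModel:
    """Fit the fusion network by Adam on the composite objective.

    Deterministic given the seed.  With ``epochs=0`` returns the
    initialised network (useful for before/after comparisons).  When a
    validation split is given, validation Fmax of the sigmoid head is
    recorded per epoch in the history.
    """
    if not annotations.propagated:
        raise ValueError("training annotations must be propagated")
    proteins = sorted(set(bundle.vectors) & set(annotations.annotations))
    if not proteins:
        raise ValueError("no proteins shared between embeddings and annotations")
    rng = np.random.default_rng(training.seed)
    net = FusionNetwork(model_config, seed=training.seed)
    terms = model_config.terms
    term_index = {q: j for j, q in enumerate(terms)}

    views = bundle.stacked(proteins)
    labels = np.zeros((len(proteins), len(terms)))
    term_sets = []
    for i, p in enumerate(proteins):
        ts = annotations.annotations[p]
        term_sets.append(ts)
        for q in ts:
            j = term_index.get(q)
            if j is not None:
                labels[i, j] = 1.0

    simcfg = training.similarity_config()
    pos_mask, neg_mask = _pair_masks(term_sets, simcfg)

    opt = _Adam(net.params, training.learning_rate)
    history: list[dict] = []
    n = len(proteins)
    for epoch in range(training.epochs):
        epoch_t, epoch_c, n_batches = 0.0, 0.0, 0
        for batch in _batches(n, training.batch_size, rng, training.sampler, pos_mask):
            bx = [v[batch] for v in views]
            z, s, cache = net.forward(bx, cache=True)
            by = labels[batch]
            bpos = pos_mask[np.ix_(batch, batch)]
            bneg = neg_mask[np.ix_(batch, batch)]
            valid = bpos.any(axis=1) & bneg.any(axis=1)
            if valid.any():
                lt, d_z, _, _ = _batch_hard(
                    z, bpos, bneg, training.margin, want_grad=True
                )
            else:
                lt, d_z = 0.0, np.zeros_like(z)
            s_clamped = np.clip(s, _EPS, 1.0 - _EPS)
            lc = cross_entropy_loss(s, by)
            # d/dlogits of mean BCE = (s - y) / (n_batch * n_terms)
            d_logits = training.alpha * (s_clamped - by) / by.size
            grads = net.backward(cache, d_z, d_logits)
            loss = lt + training.alpha * lc
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            opt.step(net.params, grads)
            epoch_t += lt
            epoch_c += lc
            n_batches += 1
        record = {
            "epoch": epoch,
            "triplet_loss": epoch_t / max(n_batches, 1),
            "cross_entropy": epoch_c / max(n_batches, 1),
        }
        if validation is not None:
            record["val_fmax"] = _validation_fmax(net, *validation)
        history.append(record)

    z, s = net.forward(views)
    embeddings = {p: z[i] for i, p in enumerate(proteins)}
    saf = {
        p: {q: float(s[i, j]) for j, q in enumerate(terms)}
        for i, p in enumerate(proteins)
    }
    return TrainedModel(
        network=net,
        proteins=proteins,
        embeddings=embeddings,
        saf_scores=saf,
        history=history,
    )


def _validation_fmax(
    net: FusionNetwork, bundle: EmbeddingBundle, truth: AnnotationSet
) -> float:
    from .metrics import fmax_sweep

    proteins = sorted(set(bundle.vectors) & set(truth.annotations))
    _, s = net.forward(bundle.stacked(proteins))
    terms = net.config.terms
    scores = {
        p: {q: float(s[i, j]) for j, q in enumerate(terms)}
        for i, p in enumerate(proteins)
    }
    sub = AnnotationSet(
        annotations={p: truth.annotations[p] for p in proteins},
        aspect=truth.aspect,
        propagated=True,
    )
    f, _, _ = fmax_sweep(scores, sub)
    return f


def ensemble_average(
    runs: Sequence[Mapping[str, Mapping[str, float]]],
) -> dict[str, dict[str, float]]:
    """Elementwise mean of score vectors from repeated seeded runs.

    All runs must share the same protein and term index.
    """
    if not runs:
        raise ValueError("no runs to average")
    first = runs[0]
    keys = set(first)
    for r in runs[1:]:
        if set(r) != keys:
            raise ValueError("protein index mismatch between runs")
    out: dict[str, dict[str, float]] = {}
    for p in first:
        terms = set(first[p])
        for r in runs[1:]:
            if set(r[p]) != terms:
                raise ValueError(f"term index mismatch for protein {p}")
        out[p] = {
            q: float(sum(r[p][q] for r in runs) / len(runs)) for q in terms
        }
    return out
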
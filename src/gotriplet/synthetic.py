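"""Synthetic inputs for the whole pipeline.

Generates a toy GO-like DAG, true-path-consistent annotations organised
into functional clusters, per-protein embedding triplets whose geometry
encodes cluster membership, alignment hit tables and PPI edge lists —
everything the predictors consume — deterministically from a seed.

The generative model is deliberately minimal: proteins belong to
functional clusters anchored at DAG leaves (the cluster's annotation is
the leaf's ancestor closure), and each cluster owns a Gaussian centre in
embedding space whose separation from other centres scales with the
``signal`` parameter.  That is the smallest geometry in which triplet
metric learning has a measurable effect while nearest-neighbour transfer
remains analysable.  It does not model realistic sequence statistics,
term co-occurrence beyond shared ancestry, or language-model embedding
anisotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import EmbeddingBundle
from .ontology import ASPECT_ROOTS, AnnotationSet, GoTerm, OntologyDAG
from .predictors import AlignmentHit, PpiEdge

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dag",
    "generate_annotations",
    "generate_embeddings",
    "generate_hits",
    "generate_ppi",
    "generate_dataset",
    "write_obo",
    "write_gaf",
    "write_fasta",
    "write_hits_tsv",
    "write_ppi_tsv",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic world; the seed fully determines all output.

    ``signal`` is the ratio of between-cluster centre spread to the unit
    within-cluster spread: 0 means embeddings carry no functional
    information, large values make clusters linearly separable.
    """

    n_terms: int = 50
    branching: int = 3
    n_proteins: int = 200
    n_clusters: int = 4
    dim: int = 32
    signal: float = 4.0
    noise_rate: float = 0.0
    orphan_fraction: float = 0.1
    unseen_cluster_fraction: float = 0.0
    max_cluster_similarity: float = 0.5
    aspect: str = "BP"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ValueError("need at least root + one child")
        if self.signal < 0:
            raise ValueError("signal must be nonnegative")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0,1]")


def _term_id(i: int) -> str:
    # synthetic accessions in the 9xxxxxx range, clear of real GO ids
    return f"GO:9{i:06d}"


def generate_dag(cfg: SyntheticConfig) -> OntologyDAG:
    """Random rooted DAG: the real aspect root plus synthetic terms.

    Term i's parents are drawn from earlier terms (acyclic by
    construction): one guaranteed parent, plus a second with probability
    rising with ``branching``.
    """
    rng = np.random.default_rng(cfg.seed)
    root = ASPECT_ROOTS[cfg.aspect]
    ns = cfg.aspect
    ids = [root] + [_term_id(i) for i in range(1, cfg.n_terms)]
    terms: dict[str, GoTerm] = {
        root: GoTerm(id=root, namespace=ns, parents=frozenset(), name="root")
    }
    p_second = min(0.15 * cfg.branching, 0.9)
    for i in range(1, cfg.n_terms):
        # bias parent choice toward recent terms to get depth
        lo = max(0, i - 2 * cfg.branching)
        parent = ids[int(rng.integers(lo, i))]
        parents = {parent}
        if i > 1 and rng.random() < p_second:
            second = ids[int(rng.integers(0, i))]
            if second != ids[i]:
                parents.add(second)
        terms[ids[i]] = GoTerm(
            id=ids[i],
            namespace=ns,
            parents=frozenset(parents),
            name=f"synthetic term {i}",
        )
    return OntologyDAG(terms=terms, roots={ns: root})


def _closure(dag: OntologyDAG, term: str, include_root: bool = False) -> frozenset[str]:
    s = {term} | set(dag.ancestors(term))
    if not include_root:
        s -= set(dag.roots.values())
    return frozenset(s)


def _pick_anchor_closures(dag, leaves, cfg, rng):
    """Greedily pick cluster anchor leaves whose closures are pairwise
    functionally distinct (F1 similarity <= max_cluster_similarity), so
    clusters represent genuinely different functions; falls back to the
    least-similar remaining leaf when the DAG is too shallow to satisfy
    the bound."""

    def f1(a: frozenset, b: frozenset) -> float:
        return 2 * len(a & b) / (len(a) + len(b)) if a or b else 0.0

    order = list(rng.permutation(leaves))
    closures = {leaf: _closure(dag, leaf) for leaf in leaves}
    picked = [order.pop(0)]
    while len(picked) < cfg.n_clusters:
        ok = [
            leaf
            for leaf in order
            if all(
                f1(closures[leaf], closures[p]) <= cfg.max_cluster_similarity
                for p in picked
            )
        ]
        if ok:
            choice = ok[0]
        else:  # shallow DAG: take the most distinct leaf available
            choice = min(
                order,
                key=lambda leaf: max(f1(closures[leaf], closures[p]) for p in picked),
            )
        picked.append(choice)
        order.remove(choice)
    return [closures[leaf] for leaf in picked]


def generate_annotations(
    dag: OntologyDAG, cfg: SyntheticConfig
) -> tuple[AnnotationSet, dict[str, int]]:
    """Cluster-anchored, true-path-closed annotations plus cluster labels.

    Each cluster is anchored at a distinct random leaf; a member protein's
    annotation is the leaf's ancestor closure (root excluded).  With
    probability ``noise_rate`` a protein additionally receives the closure
    of one random extra term.  Output is propagated by construction.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    leaves = sorted(dag.leaves(cfg.aspect))
    if len(leaves) < cfg.n_clusters:
        raise ValueError(
            f"DAG has {len(leaves)} leaves < {cfg.n_clusters} clusters"
        )
    cluster_terms = _pick_anchor_closures(dag, leaves, cfg, rng)
    non_root = sorted(set(dag.terms) - set(dag.roots.values()))

    annotations: dict[str, frozenset[str]] = {}
    labels: dict[str, int] = {}
    for i in range(cfg.n_proteins):
        pid = f"P{i:05d}"
        c = int(rng.integers(cfg.n_clusters))
        labels[pid] = c
        terms = set(cluster_terms[c])
        if cfg.noise_rate > 0 and rng.random() < cfg.noise_rate:
            extra = non_root[int(rng.integers(len(non_root)))]
            terms |= _closure(dag, extra)
        annotations[pid] = frozenset(terms)
    return (
        AnnotationSet(annotations=annotations, aspect=cfg.aspect, propagated=True),
        labels,
    )


def generate_embeddings(
    labels: dict[str, int], cfg: SyntheticConfig
) -> EmbeddingBundle:
    """Three noisy views per protein around its cluster's Gaussian centre.

    Centres are drawn from N(0, signal^2 I); each view adds independent
    unit-variance noise, so the three views are correlated copies of the
    cluster signal.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n_clusters = max(labels.values()) + 1 if labels else 0
    centers = rng.normal(0.0, cfg.signal, size=(n_clusters, cfg.dim))
    vectors: dict[str, np.ndarray] = {}
    for pid in sorted(labels):
        c = centers[labels[pid]]
        vectors[pid] = c + rng.normal(0.0, 1.0, size=(3, cfg.dim))
    return EmbeddingBundle(vectors=vectors, dim=cfg.dim)


def generate_hits(
    labels: dict[str, int],
    queries: Sequence[str],
    templates: Sequence[str],
    cfg: SyntheticConfig,
) -> dict[str, list[AlignmentHit]]:
    """Alignment hits linking queries to template proteins.

    Same-cluster hits carry high identity (60-95%) and bitscore;
    cross-cluster hits low identity (10-35%).  A seeded
    ``orphan_fraction`` of queries receives no hits at all, exercising
    coverage < 1 downstream.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    out: dict[str, list[AlignmentHit]] = {}
    templates = sorted(templates)
    for q in sorted(queries):
        if rng.random() < cfg.orphan_fraction:
            out[q] = []
            continue
        hits = []
        for t in templates:
            if t == q:
                continue
            same = labels[t] == labels[q]
            if same:
                if rng.random() < 0.8:
                    identity = float(rng.uniform(60.0, 95.0))
                else:
                    continue
            else:
                if rng.random() < 0.05:
                    identity = float(rng.uniform(10.0, 35.0))
                else:
                    continue
            bitscore = identity * 3.0 + float(rng.uniform(0.0, 10.0))
            evalue = float(10.0 ** (-identity / 10.0))
            hits.append(
                AlignmentHit(
                    query=q,
                    template=t,
                    identity=identity,
                    bitscore=bitscore,
                    evalue=evalue,
                )
            )
        out[q] = hits
    return out


def generate_ppi(
    labels: dict[str, int], cfg: SyntheticConfig
) -> list[PpiEdge]:
    """PPI edges drawn preferentially within clusters (heavier weights),
    with sparse light cross-cluster edges; some proteins stay isolated."""
    rng = np.random.default_rng(cfg.seed + 4)
    proteins = sorted(labels)
    isolated = {
        p for p in proteins if rng.random() < cfg.orphan_fraction
    }
    edges: list[PpiEdge] = []
    for i, a in enumerate(proteins):
        if a in isolated:
            continue
        for b in proteins[i + 1 :]:
            if b in isolated:
                continue
            same = labels[a] == labels[b]
            p_edge = 0.15 if same else 0.005
            if rng.random() < p_edge:
                w = float(rng.uniform(0.6, 0.99)) if same else float(
                    rng.uniform(0.1, 0.4)
                )
                edges.append(PpiEdge(a=a, b=b, weight=w))
    return edges


@dataclass
class SyntheticDataset:
    """A complete, self-consistent synthetic study."""

    config: SyntheticConfig
    dag: OntologyDAG
    annotations: AnnotationSet
    labels: dict[str, int]
    embeddings: EmbeddingBundle
    hits: dict[str, list[AlignmentHit]]
    ppi: list[PpiEdge]
    train_proteins: list[str]
    test_proteins: list[str]

    def subset_annotations(self, proteins: Sequence[str]) -> AnnotationSet:
        return AnnotationSet(
            annotations={p: self.annotations.annotations[p] for p in proteins},
            aspect=self.annotations.aspect,
            propagated=True,
        )


def generate_dataset(
    cfg: SyntheticConfig, test_fraction: float = 0.25
) -> SyntheticDataset:
    """Generate everything and split train/test.

    When ``unseen_cluster_fraction`` > 0, that fraction of clusters is
    reserved entirely for the test split, emulating generalisation to
    proteins from species absent from training.
    """
    dag = generate_dag(cfg)
    annotations, labels = generate_annotations(dag, cfg)
    embeddings = generate_embeddings(labels, cfg)
    rng = np.random.default_rng(cfg.seed + 5)
    proteins = sorted(labels)
    n_unseen = int(round(cfg.unseen_cluster_fraction * cfg.n_clusters))
    unseen = set(
        rng.choice(cfg.n_clusters, size=n_unseen, replace=False).tolist()
    ) if n_unseen else set()
    eligible_test = [p for p in proteins if labels[p] in unseen]
    rest = [p for p in proteins if labels[p] not in unseen]
    n_test = max(int(round(test_fraction * len(proteins))), 1)
    extra_needed = max(n_test - len(eligible_test), 0)
    perm = rng.permutation(len(rest))
    extra = [rest[i] for i in perm[:extra_needed]]
    test = sorted(eligible_test + extra)
    train = sorted(set(proteins) - set(test))
    hits = generate_hits(labels, queries=test, templates=train, cfg=cfg)
    ppi = generate_ppi(labels, cfg)
    return SyntheticDataset(
        config=cfg,
        dag=dag,
        annotations=annotations,
        labels=labels,
        embeddings=embeddings,
        hits=hits,
        ppi=ppi,
        train_proteins=train,
        test_proteins=test,
    )


# ---------------------------------------------------------------------------
# writers: the exact text formats the real pipeline reads


_NS_NAME = {
    "MF": "molecular_function",
    "BP": "biological_process",
    "CC": "cellular_component",
}


def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    """Serialise a DAG as OBO 1.2 that :func:`~gotriplet.ontology.parse_obo`
    round-trips."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for acc in sorted(dag.terms):
            term = dag.terms[acc]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term.id}\n")
            fh.write(f"name: {term.name or term.id}\n")
            fh.write(f"namespace: {_NS_NAME[term.namespace]}\n")
            for p in sorted(term.parents):
                fh.write(f"is_a: {p}\n")


def write_gaf(annotations: AnnotationSet, path: str | Path) -> None:
    """Serialise annotations as minimal GAF 2.2 rows (IDA evidence)."""
    letter = {"MF": "F", "BP": "P", "CC": "C"}[annotations.aspect]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for p in sorted(annotations.annotations):
            for q in sorted(annotations.annotations[p]):
                cols = [
                    "SYNTH", p, p, "enables", q, "SYNTH:0", "IDA", "",
                    letter, p, "", "protein", "taxon:0000", "20260101",
                    "SYNTH", "", "",
                ]
                fh.write("\t".join(cols) + "\n")


def write_fasta(proteins: Sequence[str], path: str | Path, seed: int = 0) -> None:
    """Random amino-acid sequences, purely for ID bookkeeping."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    with open(path, "w", encoding="utf-8") as fh:
        for p in sorted(proteins):
            length = int(rng.integers(80, 300))
            seq = "".join(rng.choice(alphabet, size=length))
            fh.write(f">{p}\n")
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")


def write_hits_tsv(
    hits: dict[str, list[AlignmentHit]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for q in sorted(hits):
            for h in hits[q]:
                fh.write(
                    f"{h.query}\t{h.template}\t{h.identity:.1f}\t"
                    f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
                )


def write_ppi_tsv(edges: Sequence[PpiEdge], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in edges:
            fh.write(f"{e.a}\t{e.b}\t{e.weight:.3f}\n")
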
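"""Gene Ontology DAG handling: OBO/GAF parsing, true-path propagation,
hierarchical score post-processing and information content.

The Gene Ontology is a directed acyclic graph in three aspects (molecular
function, biological process, cellular component).  Annotation obeys the
true-path rule: a protein annotated with a term is implicitly annotated
with every ancestor of that term up to the aspect root.  All downstream
machinery in this package (functional similarity, evaluation, score
combination) assumes annotation sets are closed under that rule and that
prediction scores are hierarchically consistent (a parent's confidence is
at least the confidence of any of its children).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "ASPECT_ROOTS",
    "GoTerm",
    "OntologyDAG",
    "AnnotationSet",
    "OboParseError",
    "OntologyIntegrityError",
    "parse_obo",
    "read_gaf",
    "read_annotation_tsv",
    "propagate_annotations",
    "postprocess_scores",
    "information_content",
]

#: Canonical root accession of each GO aspect.
ASPECT_ROOTS = {
    "MF": "GO:0003674",
    "BP": "GO:0008150",
    "CC": "GO:0005575",
}

_NAMESPACE_TO_ASPECT = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}

#: GAF aspect column letters.
_GAF_ASPECT = {"F": "MF", "P": "BP", "C": "CC"}

#: Experimental evidence codes accepted by default when reading GAF files.
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"}
)

_GO_ID_RE = re.compile(r"^GO:\d{7}$")


class OboParseError(ValueError):
    """Raised for a malformed OBO stanza; names the offending line."""


class OntologyIntegrityError(ValueError):
    """Raised when the parsed ontology violates a structural invariant."""


@dataclass(frozen=True)
class GoTerm:
    """A single GO term with its within-aspect parent set."""

    id: str
    namespace: str  # one of MF / BP / CC
    parents: frozenset[str] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        if not _GO_ID_RE.match(self.id):
            raise ValueError(f"malformed GO accession: {self.id!r}")
        if self.id in self.parents:
            raise ValueError(f"term {self.id} lists itself as a parent")


@dataclass
class OntologyDAG:
    """The GO hierarchy restricted to is_a / part_of edges.

    ``graph`` holds child -> parent edges; ``roots`` maps each aspect
    present in the ontology to its root accession.
    """

    terms: dict[str, GoTerm]
    roots: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for p in term.parents:
                g.add_edge(term.id, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyIntegrityError(f"ontology graph has a cycle: {cycle}")
        self.graph = g

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms or accession in self.alt_ids

    def canonical(self, accession: str) -> str:
        """Map an alt_id to its canonical accession (identity otherwise)."""
        return self.alt_ids.get(accession, accession)

    def parents(self, accession: str) -> frozenset[str]:
        return self.terms[self.canonical(accession)].parents

    def children(self, accession: str) -> frozenset[str]:
        return frozenset(self.graph.predecessors(self.canonical(accession)))

    def ancestors(self, accession: str) -> frozenset[str]:
        """All strict ancestors of a term (excluding the term itself)."""
        return frozenset(nx.descendants(self.graph, self.canonical(accession)))

    def aspect_of(self, accession: str) -> str:
        return self.terms[self.canonical(accession)].namespace

    def aspect_terms(self, aspect: str) -> frozenset[str]:
        return frozenset(
            t for t, term in self.terms.items() if term.namespace == aspect
        )

    def leaves(self, aspect: str | None = None) -> frozenset[str]:
        out = (t for t in self.terms if self.graph.in_degree(t) == 0)
        if aspect is not None:
            out = (t for t in out if self.terms[t].namespace == aspect)
        return frozenset(out)

    def topological_order(self) -> list[str]:
        """Terms ordered so every child precedes its parents."""
        return list(nx.topological_sort(self.graph))


@dataclass
class AnnotationSet:
    """Protein -> set of GO accessions, for a single aspect."""

    annotations: dict[str, frozenset[str]]
    aspect: str
    propagated: bool = False

    def __len__(self) -> int:
        return len(self.annotations)

    def __getitem__(self, protein: str) -> frozenset[str]:
        return self.annotations[protein]

    def __iter__(self):
        return iter(self.annotations)

    def items(self):
        return self.annotations.items()

    def proteins(self) -> list[str]:
        return sorted(self.annotations)

    def terms(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.annotations.values():
            out |= s
        return frozenset(out)


def _prescan_obo(path: Path) -> None:
    """Reject obviously malformed lines with a line-numbered error.

    OBO files are line-oriented: blank lines, comments (``!``), stanza
    headers (``[Term]``) and ``key: value`` pairs.  Anything else is a
    malformed stanza line.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("[") and line.endswith("]"):
                continue
            if ":" in line:
                continue
            raise OboParseError(f"{path}:{lineno}: malformed OBO line: {line!r}")


def parse_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyDAG`.

    Keeps is_a and part_of edges only; drops obsolete terms and
    cross-aspect edges; records alt_id -> canonical mappings.
    """
    path = Path(path)
    _prescan_obo(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - obonet's own message
        raise OboParseError(f"failed to parse {path}: {exc}") from exc

    namespaces: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns not in _NAMESPACE_TO_ASPECT:
            raise OntologyIntegrityError(
                f"term {node} has missing/unknown namespace {ns!r}"
            )
        namespaces[node] = _NAMESPACE_TO_ASPECT[ns]

    terms: dict[str, GoTerm] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        parents: set[str] = set()
        for p in data.get("is_a", []):
            if p in namespaces and namespaces[p] == namespaces[node]:
                parents.add(p)
        for rel in data.get("relationship", []):
            rel_type, _, target = rel.partition(" ")
            target = target.strip()
            if (
                rel_type == "part_of"
                and target in namespaces
                and namespaces[target] == namespaces[node]
            ):
                parents.add(target)
        parents.discard(node)
        terms[node] = GoTerm(
            id=node,
            namespace=namespaces[node],
            parents=frozenset(parents),
            name=data.get("name", ""),
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    roots = {
        aspect: acc for aspect, acc in ASPECT_ROOTS.items() if acc in terms
    }
    dag = OntologyDAG(terms=terms, roots=roots, alt_ids=alt_ids)

    # every non-root term must reach its aspect root
    for acc, term in terms.items():
        if acc in roots.values():
            continue
        root = roots.get(term.namespace)
        if root is not None and root not in dag.ancestors(acc) and term.parents:
            raise OntologyIntegrityError(
                f"term {acc} cannot reach its aspect root {root}"
            )
    return dag


def read_gaf(
    path: str | Path,
    aspect: str,
    evidence_codes: Iterable[str] = EXPERIMENTAL_EVIDENCE_CODES,
) -> AnnotationSet:
    """Read a GAF 2.1/2.2 file into a raw (unpropagated) annotation set.

    Uses columns 2 (protein id), 5 (GO id), 7 (evidence code) and
    9 (aspect letter); rows are kept only when the evidence code is in the
    whitelist (default: the eight experimental codes) and the aspect
    matches.  NOT-qualified rows are dropped.
    """
    whitelist = frozenset(evidence_codes)
    annotations: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("!") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            protein, qualifier, go_id, evidence, asp = (
                cols[1],
                cols[3],
                cols[4],
                cols[6],
                cols[8],
            )
            if "NOT" in qualifier.split("|"):
                continue
            if evidence not in whitelist:
                continue
            if _GAF_ASPECT.get(asp) != aspect:
                continue
            annotations.setdefault(protein, set()).add(go_id)
    return AnnotationSet(
        annotations={p: frozenset(s) for p, s in annotations.items()},
        aspect=aspect,
        propagated=False,
    )


def read_annotation_tsv(path: str | Path, aspect: str) -> AnnotationSet:
    """Plain two-column protein<TAB>GO-accession fallback reader."""
    annotations: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            protein, go_id = line.split("\t")[:2]
            annotations.setdefault(protein, set()).add(go_id)
    return AnnotationSet(
        annotations={p: frozenset(s) for p, s in annotations.items()},
        aspect=aspect,
        propagated=False,
    )


def propagate_annotations(
    raw: AnnotationSet,
    dag: OntologyDAG,
    include_root: bool = False,
    strict: bool = False,
) -> AnnotationSet:
    """Close every protein's term set under the parent relation.

    Implements the true-path rule: annotation with a term implies
    annotation with all its ancestors.  Roots are excluded unless
    ``include_root``.  Unknown accessions are dropped with a warning, or
    raise ``KeyError`` when ``strict``.  Idempotent.
    """
    roots = frozenset(dag.roots.values())
    out: dict[str, frozenset[str]] = {}
    for protein, terms in raw.annotations.items():
        closed: set[str] = set()
        for acc in terms:
            if acc not in dag:
                if strict:
                    raise KeyError(
                        f"unknown GO accession {acc} for protein {protein}"
                    )
                warnings.warn(
                    f"dropping unknown GO accession {acc} ({protein})",
                    stacklevel=2,
                )
                continue
            canonical = dag.canonical(acc)
            closed.add(canonical)
            closed |= dag.ancestors(canonical)
        if not include_root:
            closed -= roots
        out[protein] = frozenset(closed)
    return AnnotationSet(annotations=out, aspect=raw.aspect, propagated=True)


def postprocess_scores(
    scores: Mapping[str, Mapping[str, float]],
    dag: OntologyDAG,
    include_root: bool = False,
) -> dict[str, dict[str, float]]:
    """Enforce hierarchical consistency on prediction scores.

    The post-processed confidence of a term is the maximum of its own
    score and the post-processed scores of all its direct children,
    computed in reverse-topological (child-first) order.  Terms absent
    from a protein's score map are treated as zeros, so a scored child
    can lift an unscored parent.  Idempotent; never decreases a score.
    Aspect roots are dropped from the output unless ``include_root``,
    matching the root-exclusion convention of the evaluation.
    """
    order = dag.topological_order()  # children before parents
    roots = frozenset(dag.roots.values())
    out: dict[str, dict[str, float]] = {}
    for protein, term_scores in scores.items():
        for term, val in term_scores.items():
            if not (0.0 <= val <= 1.0):
                raise ValueError(
                    f"score {val} for {protein}/{term} outside [0,1]"
                )
        post: dict[str, float] = dict(term_scores)
        for term in order:
            best = post.get(term, 0.0)
            for child in dag.children(term):
                cv = post.get(child, 0.0)
                if cv > best:
                    best = cv
            if best > 0.0:
                post[term] = best
        out[protein] = {
            t: v
            for t, v in post.items()
            if v > 0.0 and (include_root or t not in roots)
        }
    return out


class InformationContent(dict):
    """Term -> IC map that answers unseen terms with a ceiling value."""

    def __init__(self, data: Mapping[str, float], ceiling: float):
        super().__init__(data)
        self.ceiling = ceiling

    def __missing__(self, term: str) -> float:
        return self.ceiling


def information_content(
    train: AnnotationSet,
    dag: OntologyDAG | None = None,
    base: float = 2.0,
    unseen: str | float = "ceiling",
) -> InformationContent:
    """Per-term information content from a propagated training corpus.

    IC(q) = -log_base(n_q / N) with n_q the number of training proteins
    annotated (after propagation) with q and N the corpus size.  Terms
    never seen in training answer with a ceiling IC of -log_base(1/(N+1))
    by default, or the given numeric ceiling.
    """
    if not train.propagated:
        raise ValueError("information_content requires a propagated AnnotationSet")
    n = len(train.annotations)
    if n == 0:
        raise ValueError("empty training set")
    counts: dict[str, int] = {}
    for terms in train.annotations.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    log = math.log
    ic = {t: -log(c / n) / log(base) for t, c in counts.items()}
    ceiling = (
        -log(1.0 / (n + 1)) / log(base) if unseen == "ceiling" else float(unseen)
    )
    if dag is not None:
        for t in dag.terms:
            ic.setdefault(t, ceiling)
    return InformationContent(ic, ceiling)
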
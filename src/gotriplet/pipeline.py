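"""End-to-end prediction workflows over the library primitives.

These helpers wire the standard route together: train one model per seed
on the training split, score held-out queries by the convex combination
of guilt-by-association and sigmoid-head confidences, average the score
vectors over the seeded replica runs, optionally mix in the homology
consensus, and enforce hierarchical consistency on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .model import (
    EmbeddingBundle,
    ModelConfig,
    TrainedModel,
    TrainingConfig,
    ensemble_average,
    train_model,
)
from .ontology import AnnotationSet, OntologyDAG, postprocess_scores
from .predictors import (
    AlignmentHit,
    CombinationWeights,
    ScoreVector,
    combine_composite,
    combine_internal,
    gba_scores,
    sagp_scores,
)

__all__ = ["candidate_terms", "predict_queries", "run_pipeline"]


def candidate_terms(
    annotations: AnnotationSet, dag: OntologyDAG | None = None
) -> tuple[str, ...]:
    """Ordered candidate term set: every non-root term seen in training."""
    terms = set(annotations.terms())
    if dag is not None:
        terms -= set(dag.roots.values())
    return tuple(sorted(terms))


def predict_queries(
    model: TrainedModel,
    query_bundle: EmbeddingBundle,
    queries: Sequence[str],
    train_annotations: AnnotationSet,
    k: int = 10,
    w: float = 0.5,
) -> dict[str, dict[str, float]]:
    """One run's scores for queries: w*gba + (1-w)*saf per protein."""
    emb, saf = model.embed_bundle(query_bundle, queries)
    s_gba = {
        p: gba_scores(emb[p], model.embeddings, train_annotations, k=k)
        for p in queries
    }
    return combine_internal(s_gba, {p: saf[p] for p in queries}, w=w)


@dataclass
class PipelineResult:
    scores: ScoreVector
    models: list[TrainedModel]
    sagp: ScoreVector | None = None
    composite: ScoreVector | None = None


def run_pipeline(
    dag: OntologyDAG,
    train_annotations: AnnotationSet,
    bundle: EmbeddingBundle,
    queries: Sequence[str],
    model_config: ModelConfig | None = None,
    training: TrainingConfig | None = None,
    weights: CombinationWeights | None = None,
    hits: Mapping[str, Sequence[AlignmentHit]] | None = None,
    postprocess: bool = True,
) -> PipelineResult:
    """Train ``training.n_runs`` seeded replicas and score the queries.

    When ``hits`` is given, the homology consensus is computed per query
    and mixed in with the aspect-specific beta to give the composite
    score.  All score vectors are hierarchy-post-processed unless
    ``postprocess=False``.
    """
    training = training or TrainingConfig()
    weights = weights or CombinationWeights()
    aspect = train_annotations.aspect
    if model_config is None:
        model_config = ModelConfig(
            dim=bundle.dim, terms=candidate_terms(train_annotations, dag)
        )

    runs, models = [], []
    for r in range(training.n_runs):
        cfg_r = replace(training, seed=training.seed + r)
        model = train_model(bundle, train_annotations, model_config, cfg_r)
        models.append(model)
        runs.append(
            predict_queries(
                model,
                bundle,
                queries,
                train_annotations,
                k=training.k_templates,
                w=weights.w,
            )
        )
    averaged = ensemble_average(runs)
    if postprocess:
        averaged = postprocess_scores(averaged, dag)
    result = PipelineResult(
        scores=ScoreVector(scores=averaged, aspect=aspect, postprocessed=postprocess),
        models=models,
    )

    if hits is not None:
        s_sagp = {p: sagp_scores(hits.get(p, []), train_annotations) for p in queries}
        composite = combine_composite(averaged, s_sagp, aspect, weights)
        if postprocess:
            s_sagp = postprocess_scores(s_sagp, dag)
            composite = postprocess_scores(composite, dag)
        result.sagp = ScoreVector(scores=s_sagp, aspect=aspect, postprocessed=postprocess)
        result.composite = ScoreVector(
            scores=composite, aspect=aspect, postprocessed=postprocess
        )
    return result
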
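"""Subtype prediction for individual test samples.

Pipeline per sample: ssGSEA against the species GMT, restriction to the
genesets shared with the training reference (the cross-platform /
cross-species harmonization step; mouse samples meet the human reference
through the shared GO-term namespace, not through gene symbols), descending-
ES ranking of the surviving genesets, and unweighted k-nearest-neighbor
voting in rank space. The winning vote fraction is the confidence; at or
above 80 % of votes the call is high-confidence, below it the sample is
flagged as an intermediate genotype.

Each sample is classified from its own profile alone — batch composition,
replicates, and reference-tissue samples play no role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import predictions_frame
from .reference import TrainingReference, rerank_rows
from .ssgsea import EnrichmentMatrix, ssgsea
from .types import (
    HIGH_CONFIDENCE_PERCENT,
    SUBTYPES,
    ExpressionMatrix,
    GeneSetCollection,
    MBSubtypeError,
)

logger = logging.getLogger(__name__)

#: Warn (do not fail) when fewer than this many genesets survive harmonization.
DEFAULT_MIN_OVERLAP = 10

METRICS = ("euclidean", "manhattan")


@dataclass
class PredictionResult:
    """One sample's k-NN vote tally and subtype call."""

    sample_id: str
    votes: dict[str, int]
    confidence_percent: float
    predicted: str
    call_class: str
    neighbors: list[tuple[str, float]]
    provenance: dict | None = None

    def __post_init__(self) -> None:
        k = len(self.neighbors)
        if sum(self.votes.values()) != k:
            raise MBSubtypeError("votes must sum to k")
        expected_call = (
            "high_confidence"
            if self.confidence_percent >= HIGH_CONFIDENCE_PERCENT
            else "intermediate"
        )
        if self.call_class != expected_call:
            raise MBSubtypeError(
                f"call_class {self.call_class!r} inconsistent with "
                f"confidence {self.confidence_percent}"
            )


def harmonize_genesets(
    test_es: EnrichmentMatrix,
    ref: TrainingReference,
    rerank: bool = True,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[EnrichmentMatrix, TrainingReference, list[str]]:
    """Restrict test and reference to their common genesets, in reference order.

    By default the reference rank rows are *re-ranked* over the surviving
    genesets — ranks are only meaningful within a fixed geneset universe, so
    stale full-space ranks would not be comparable to the test side's ranks
    (``rerank=False`` keeps the subsetted ranks for comparison purposes).
    """
    test_names = set(test_es.geneset_names)
    common = [n for n in ref.geneset_names if n in test_names]
    if not common:
        raise MBSubtypeError(
            "no genesets shared between test enrichment matrix and reference"
        )
    if len(common) < min_overlap:
        logger.warning(
            "only %d genesets shared between test and reference (floor %d); "
            "predictions may be unstable",
            len(common), min_overlap,
        )
    idx = [ref.geneset_names.index(n) for n in common]
    sub_ranks = ref.rank_matrix[:, idx]
    new_ranks = rerank_rows(sub_ranks) if rerank else sub_ranks
    new_ref = TrainingReference(
        geneset_names=common,
        sample_ids=list(ref.sample_ids),
        labels=list(ref.labels),
        rank_matrix=new_ranks,
        hyperparams=dict(ref.hyperparams),
        provenance=ref.provenance,
    ) if rerank else _subset_reference_unchecked(ref, common, new_ranks)
    return test_es.subset(common), new_ref, common


def _subset_reference_unchecked(
    ref: TrainingReference, names: list[str], ranks: np.ndarray
) -> TrainingReference:
    # bypass the row-sum invariant: stale subsetted ranks are not rankings
    new = TrainingReference.__new__(TrainingReference)
    new.geneset_names = list(names)
    new.sample_ids = list(ref.sample_ids)
    new.labels = list(ref.labels)
    new.rank_matrix = np.asarray(ranks, dtype=float)
    new.hyperparams = dict(ref.hyperparams)
    new.provenance = ref.provenance
    return new


def knn_predict(
    test_rank_vector: np.ndarray,
    ref: TrainingReference,
    k: int,
    metric: str = "euclidean",
    sample_id: str = "sample",
) -> PredictionResult:
    """Vote among the k nearest reference samples in geneset-rank space.

    All tie-breaks are deterministic: equal distances at the k-th position
    fall to lexicographically smaller reference sample ids; vote ties fall
    to the label with the smaller mean neighbor distance, then to canonical
    label order.
    """
    vec = np.asarray(test_rank_vector, dtype=float)
    if vec.shape != (len(ref.geneset_names),):
        raise MBSubtypeError(
            f"test rank vector has length {vec.shape}, reference expects "
            f"{len(ref.geneset_names)} genesets"
        )
    if k > ref.n_samples:
        raise MBSubtypeError(f"k={k} exceeds the {ref.n_samples} reference samples")
    if metric not in METRICS:
        raise MBSubtypeError(f"metric must be one of {METRICS}, got {metric!r}")
    diff = ref.rank_matrix - vec[None, :]
    if metric == "euclidean":
        dist = np.sqrt((diff ** 2).sum(axis=1))
    else:
        dist = np.abs(diff).sum(axis=1)

    order = sorted(range(ref.n_samples), key=lambda i: (dist[i], ref.sample_ids[i]))
    nearest = order[:k]
    neighbors = [(ref.sample_ids[i], float(dist[i])) for i in nearest]

    votes = {s: 0 for s in SUBTYPES}
    for i in nearest:
        votes[ref.labels[i]] += 1
    max_votes = max(votes.values())
    tied = [s for s in SUBTYPES if votes[s] == max_votes]
    if len(tied) > 1:
        mean_dist = {
            s: float(np.mean([dist[i] for i in nearest if ref.labels[i] == s]))
            for s in tied
        }
        best = min(mean_dist.values())
        tied = [s for s in tied if mean_dist[s] == best]
    predicted = tied[0]  # canonical label order breaks any remaining tie

    confidence = 100.0 * max_votes / k
    call = (
        "high_confidence" if confidence >= HIGH_CONFIDENCE_PERCENT else "intermediate"
    )
    return PredictionResult(
        sample_id=sample_id,
        votes=votes,
        confidence_percent=confidence,
        predicted=predicted,
        call_class=call,
        neighbors=neighbors,
    )


def _classify(
    expr: ExpressionMatrix,
    ref: TrainingReference,
    collection: GeneSetCollection,
    k: int | None,
    metric: str,
    rerank: bool,
    min_overlap: int,
) -> list[PredictionResult]:
    alpha = float(ref.hyperparams.get("alpha", 0.25))
    es_mode = str(ref.hyperparams.get("es_mode", "integrated"))
    k = int(k if k is not None else ref.hyperparams.get("k", 5))

    test_es = ssgsea(expr, collection, alpha=alpha, es_mode=es_mode)
    test_es, ref_common, common = harmonize_genesets(
        test_es, ref, rerank=rerank, min_overlap=min_overlap
    )
    provenance = {
        "alpha": alpha,
        "es_mode": es_mode,
        "k": k,
        "metric": metric,
        "geneset_overlap": len(common),
        "species": collection.species,
    }
    results = []
    for j, sid in enumerate(test_es.sample_ids):
        rank_vec = rankdata(-test_es.es[:, j], method="average")
        res = knn_predict(rank_vec, ref_common, k=k, metric=metric, sample_id=sid)
        res.provenance = provenance
        results.append(res)
    return results


def classify_human(
    expr: ExpressionMatrix,
    ref: TrainingReference,
    human_gmt: GeneSetCollection,
    k: int | None = None,
    metric: str = "euclidean",
    rerank: bool = True,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[PredictionResult]:
    """Classify human expression profiles against the reference.

    Samples are processed independently; a profile's call never changes with
    batch composition.
    """
    return _classify(expr, ref, human_gmt, k, metric, rerank, min_overlap)


def classify_mouse(
    expr: ExpressionMatrix,
    ref: TrainingReference,
    mouse_gmt: GeneSetCollection,
    k: int | None = None,
    metric: str = "euclidean",
    rerank: bool = True,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[PredictionResult]:
    """Classify mouse expression profiles against the (human-trained) reference.

    The mouse GMT must share the reference's term namespace (e.g. GO BP term
    names); its member symbols are mouse genes. Harmonization operates on
    term names only — no gene-level ortholog translation happens at predict
    time.
    """
    return _classify(expr, ref, mouse_gmt, k, metric, rerank, min_overlap)


def summarize_by_sample(results: list[PredictionResult]) -> pd.DataFrame:
    """Sample-centric view: the prediction table plus mean neighbor distance."""
    if not results:
        raise MBSubtypeError("no prediction results to summarize")
    df = predictions_frame(results)
    df["mean_neighbor_distance"] = [
        float(np.mean([d for _, d in r.neighbors])) for r in results
    ]
    return df


def summarize_by_subtype(
    results: list[PredictionResult],
) -> tuple[pd.Series, dict[str, list[float]]]:
    """Subtype-centric view across samples (replicate sets, cohorts).

    Returns predicted-subtype counts over the canonical label order, and the
    confidence values of the samples called as each subtype.
    """
    if not results:
        raise MBSubtypeError("no prediction results to summarize")
    counts = pd.Series(0, index=list(SUBTYPES), name="n_samples")
    confidences: dict[str, list[float]] = {s: [] for s in SUBTYPES}
    for r in results:
        counts[r.predicted] += 1
        confidences[r.predicted].append(r.confidence_percent)
    return counts, confidences
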
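"""Single-sample gene set enrichment (ssGSEA).

For one sample, genes are ranked by expression (tie-averaged ranks, largest
rank for the highest-expressed gene). For a gene set S the enrichment score
walks the genes in decreasing-expression order and integrates the difference
between two empirical distribution functions:

    ES(S) = sum_i [ P_in^w(i) - P_out(i) ]

where P_in^w(i) is the weighted fraction of set members encountered up to
position i, with gene g weighted by r_g^alpha (r_g its rank value), and
P_out(i) is the plain fraction of non-members encountered. The integrated
(summed) running difference is the ssGSEA statistic; the classical
maximum-deviation statistic is available as ``es_mode="max"``.

Because the score depends on the expression vector only through its ranks,
any strictly increasing per-sample transform of expression leaves every ES
bit-identical — the property downstream classification relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .types import ExpressionMatrix, GeneSetCollection, MBSubtypeError

logger = logging.getLogger(__name__)

#: Default rank-weighting exponent for the weighted ECDF.
DEFAULT_ALPHA = 0.25

ES_MODES = ("integrated", "max")


class DegenerateProfileError(MBSubtypeError, ValueError):
    """All expression values tied: no meaningful gene ranking exists."""


class GeneSetCoverageError(MBSubtypeError, ValueError):
    """A gene set's overlap with the measured genes is empty or total."""


@dataclass
class RankedProfile:
    """Per-sample gene ranking: the first (and only sample-specific) ssGSEA step.

    ``gene_order`` lists genes by decreasing expression, ties kept in input
    order; ``rank_values`` are the tie-averaged ranks aligned to
    ``gene_order`` (so rank_values[0] is the largest).
    """

    sample_id: str
    gene_order: list[str]
    rank_values: np.ndarray

    def __post_init__(self) -> None:
        self.rank_values = np.asarray(self.rank_values, dtype=float)
        if len(self.gene_order) != len(self.rank_values):
            raise MBSubtypeError("gene_order / rank_values length mismatch")


def rank_genes(expr: ExpressionMatrix, sample_id: str) -> RankedProfile:
    """Rank one sample's genes: values 1..G ascending in expression, ties averaged.

    An all-tied (constant) profile still ranks — every gene at the average —
    but carries no ordering information; enrichment scoring rejects it.
    """
    x = expr.column(sample_id)
    order = np.argsort(-x, kind="stable")  # decreasing; ties in input order
    ranks = rankdata(x, method="average")
    return RankedProfile(
        sample_id=sample_id,
        gene_order=[expr.gene_ids[i] for i in order],
        rank_values=ranks[order],
    )


def enrichment_score(
    profile: RankedProfile,
    gene_set: list[str] | set[str],
    alpha: float = DEFAULT_ALPHA,
    es_mode: str = "integrated",
) -> float:
    """Enrichment score of one gene set in one ranked profile.

    Set members absent from the profile are ignored. The set must hit at
    least one measured gene and leave at least one gene outside it
    (otherwise P_out is undefined).
    """
    if es_mode not in ES_MODES:
        raise MBSubtypeError(f"es_mode must be one of {ES_MODES}, got {es_mode!r}")
    if np.all(profile.rank_values == profile.rank_values[0]):
        raise DegenerateProfileError(
            f"sample {profile.sample_id!r}: all expression values tied; "
            "enrichment is undefined"
        )
    members = set(gene_set)
    in_set = np.fromiter(
        (g in members for g in profile.gene_order), dtype=bool, count=len(profile.gene_order)
    )
    return float(_score_from_mask(in_set[None, :], profile.rank_values, alpha, es_mode)[0])


def _score_from_mask(
    in_set: np.ndarray, rank_values: np.ndarray, alpha: float, es_mode: str
) -> np.ndarray:
    """Vectorized ES for a (n_sets x G) membership mask over one ranked profile."""
    n_genes = in_set.shape[1]
    n_in = in_set.sum(axis=1)
    if np.any(n_in == 0):
        raise GeneSetCoverageError("geneset has no measured genes")
    if np.any(n_in == n_genes):
        raise GeneSetCoverageError(
            "geneset covers every measured gene; complement is empty"
        )
    weights = np.where(in_set, rank_values[None, :] ** alpha, 0.0)
    p_in = np.cumsum(weights, axis=1) / weights.sum(axis=1, keepdims=True)
    p_out = np.cumsum(~in_set, axis=1) / (n_genes - n_in)[:, None]
    diff = p_in - p_out
    if es_mode == "integrated":
        return diff.sum(axis=1)
    # max mode: signed value at the largest absolute running deviation
    idx = np.argmax(np.abs(diff), axis=1)
    return diff[np.arange(diff.shape[0]), idx]


@dataclass
class EnrichmentMatrix:
    """Genesets x samples matrix of enrichment scores."""

    geneset_names: list[str]
    sample_ids: list[str]
    es: np.ndarray
    alpha: float = DEFAULT_ALPHA
    es_mode: str = "integrated"

    def __post_init__(self) -> None:
        self.es = np.asarray(self.es, dtype=float)
        if self.es.shape != (len(self.geneset_names), len(self.sample_ids)):
            raise MBSubtypeError(
                f"ES shape {self.es.shape} does not match "
                f"{len(self.geneset_names)} genesets x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.es)):
            raise MBSubtypeError("non-finite enrichment score")

    def subset(self, names: list[str]) -> "EnrichmentMatrix":
        idx = [self.geneset_names.index(n) for n in names]
        return EnrichmentMatrix(
            list(names), list(self.sample_ids), self.es[idx, :], self.alpha, self.es_mode
        )


def ssgsea(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    es_mode: str = "integrated",
) -> EnrichmentMatrix:
    """ssGSEA over every (geneset, sample) pair.

    Each sample is scored independently from its own ranking alone, so the
    result for a sample never depends on which other samples share the
    matrix. Genesets with no measured genes — or covering the whole measured
    universe — are dropped with a logged warning; if none survive, an error
    is raised.
    """
    universe = set(expr.gene_ids)
    n_genes = expr.n_genes
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}

    kept_names: list[str] = []
    masks: list[np.ndarray] = []
    for name in collection.names:
        members = collection.members(name)
        measured = [g for g in members if g in universe]
        n_unmeasured = len(members) - len(measured)
        if n_unmeasured:
            logger.debug(
                "geneset %s: %d of %d member genes unmeasured",
                name, n_unmeasured, len(members),
            )
        if not measured:
            logger.warning("dropping geneset %s: no measured genes", name)
            continue
        if len(measured) == n_genes:
            logger.warning(
                "dropping geneset %s: covers all %d measured genes", name, n_genes
            )
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[[gene_pos[g] for g in measured]] = True
        kept_names.append(name)
        masks.append(mask)

    if not kept_names:
        raise GeneSetCoverageError(
            "no geneset has a usable overlap with the measured genes"
        )
    n_dropped = len(collection) - len(kept_names)
    if n_dropped:
        logger.warning("dropped %d of %d genesets", n_dropped, len(collection))

    mask_matrix = np.vstack(masks)  # n_sets x G, in input gene order
    es = np.empty((len(kept_names), expr.n_samples), dtype=float)
    for j, sample_id in enumerate(expr.sample_ids):
        x = expr.values[:, j]
        if np.all(x == x[0]):
            raise DegenerateProfileError(
                f"sample {sample_id!r}: all expression values tied; "
                "gene ranking is undefined"
            )
        order = np.argsort(-x, kind="stable")
        ranks = rankdata(x, method="average")[order]
        es[:, j] = _score_from_mask(mask_matrix[:, order], ranks, alpha, es_mode)
    return EnrichmentMatrix(kept_names, list(expr.sample_ids), es, alpha, es_mode)
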
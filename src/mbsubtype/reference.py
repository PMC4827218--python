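"""Training reference: discriminative-geneset selection and the rank-space
matrix that k-NN prediction votes against.

The reference is built from any labeled cohort in three steps: ssGSEA over
the species GMT, selection of the genesets that best separate the subtype
classes (Kruskal-Wallis H on ES by default — rank-based, like everything
downstream), and per-sample ranking of the surviving genesets in descending
ES order. Only the rank matrix, labels and hyperparameters are kept; the
training expression never needs to be redistributed with the model.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kruskal, rankdata

from . import __version__ as _pkg_version
from .ssgsea import DEFAULT_ALPHA, ES_MODES, EnrichmentMatrix, ssgsea
from .types import ExpressionMatrix, GeneSetCollection, MBSubtypeError, validate_subtype

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1
_MAGIC = "#mbsubtype-reference"

DEFAULT_K = 5
DEFAULT_N_TOP = 100


class ReferenceFormatError(MBSubtypeError, ValueError):
    """A serialized reference file is truncated, malformed, or version-mismatched."""


def rank_transform(es: EnrichmentMatrix, geneset_subset: list[str]) -> np.ndarray:
    """Per-sample descending-ES ranks over ``geneset_subset``.

    Returns a (samples x genesets) float matrix where rank 1 marks the
    geneset with the highest ES in that sample; ties are averaged.
    """
    if not geneset_subset:
        raise MBSubtypeError("geneset subset is empty")
    missing = [n for n in geneset_subset if n not in es.geneset_names]
    if missing:
        raise MBSubtypeError(f"genesets not in enrichment matrix: {missing[:5]}")
    sub = es.subset(list(geneset_subset))
    # rankdata is ascending, so negate: highest ES -> rank 1
    return rankdata(-sub.es, method="average", axis=0).T.astype(float)


def rerank_rows(rank_matrix: np.ndarray) -> np.ndarray:
    """Re-rank each row over its own columns (used after geneset filtering).

    Ranks are a monotone image of the underlying ES values, so ranking the
    surviving ranks reproduces exactly the ranks that the surviving genesets'
    ES values would have produced, ties included.
    """
    return rankdata(rank_matrix, method="average", axis=1).astype(float)


def select_discriminative_genesets(
    es: EnrichmentMatrix,
    labels: dict[str, str],
    n_top: int,
    statistic: str = "kruskal",
) -> list[str]:
    """Pick the ``n_top`` genesets whose ES best separates the subtype classes.

    The separation statistic is Kruskal-Wallis H across the label groups;
    genesets with constant ES score 0. Ordering is by decreasing H with
    deterministic tie-break by geneset name.
    """
    if statistic != "kruskal":
        raise MBSubtypeError(f"unknown selection statistic {statistic!r}")
    if n_top < 1:
        raise MBSubtypeError("n_top must be >= 1")
    if n_top > len(es.geneset_names):
        raise MBSubtypeError(
            f"n_top={n_top} exceeds the {len(es.geneset_names)} available genesets"
        )
    missing = [s for s in es.sample_ids if s not in labels]
    if missing:
        raise MBSubtypeError(f"unlabeled samples: {missing[:5]}")
    classes = sorted({labels[s] for s in es.sample_ids})
    if len(classes) < 2:
        raise MBSubtypeError("need at least 2 distinct classes to rank genesets")
    group_idx = [
        [j for j, s in enumerate(es.sample_ids) if labels[s] == c] for c in classes
    ]

    scored: list[tuple[float, str]] = []
    for i, name in enumerate(es.geneset_names):
        groups = [es.es[i, idx] for idx in group_idx]
        if np.all(es.es[i, :] == es.es[i, 0]):
            h = 0.0
        else:
            h = float(kruskal(*groups).statistic)
        scored.append((h, name))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [name for _, name in scored[:n_top]]


@dataclass
class TrainingReference:
    """Everything prediction needs: geneset rank vectors + labels + hyperparams.

    ``rank_matrix`` is samples x genesets; each row is a tie-averaged
    ranking of the genesets by descending ES for that training sample.
    """

    geneset_names: list[str]
    sample_ids: list[str]
    labels: list[str]
    rank_matrix: np.ndarray
    hyperparams: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.rank_matrix = np.asarray(self.rank_matrix, dtype=float)
        n_samples, n_sets = self.rank_matrix.shape
        if n_samples != len(self.sample_ids) or n_sets != len(self.geneset_names):
            raise MBSubtypeError("rank_matrix shape inconsistent with name lists")
        if len(self.labels) != n_samples:
            raise MBSubtypeError("one label per reference sample required")
        for lab in self.labels:
            validate_subtype(lab)
        if len(set(self.labels)) < 2:
            raise MBSubtypeError("reference must cover at least 2 classes")
        expected = n_sets * (n_sets + 1) / 2.0
        sums = self.rank_matrix.sum(axis=1)
        if not np.allclose(sums, expected):
            raise MBSubtypeError(
                "rank_matrix rows are not valid tie-averaged rankings "
                f"(row sums must equal {expected})"
            )
        k = self.hyperparams.get("k")
        if k is not None and k > n_samples:
            raise MBSubtypeError(f"k={k} exceeds the {n_samples} reference samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def build_reference(
    expr: ExpressionMatrix,
    labels: dict[str, str],
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    k: int = DEFAULT_K,
    n_top: int = DEFAULT_N_TOP,
    es_mode: str = "integrated",
    selection_statistic: str = "kruskal",
    provenance: str = "",
) -> TrainingReference:
    """Train a reference on a labeled cohort: ssGSEA -> geneset selection -> ranks.

    Every step is deterministic, so rebuilding from the same inputs yields an
    identical reference; and because every step is rank-based, per-sample
    monotone transforms of the expression leave the reference unchanged.
    """
    missing = [s for s in expr.sample_ids if s not in labels]
    if missing:
        raise MBSubtypeError(f"unlabeled expression samples: {missing[:10]}")
    if es_mode not in ES_MODES:
        raise MBSubtypeError(f"es_mode must be one of {ES_MODES}")
    es = ssgsea(expr, collection, alpha=alpha, es_mode=es_mode)
    chosen = select_discriminative_genesets(
        es, labels, n_top=n_top, statistic=selection_statistic
    )
    rank_matrix = rank_transform(es, chosen)
    return TrainingReference(
        geneset_names=chosen,
        sample_ids=list(expr.sample_ids),
        labels=[labels[s] for s in expr.sample_ids],
        rank_matrix=rank_matrix,
        hyperparams={
            "alpha": alpha,
            "k": k,
            "n_top": n_top,
            "es_mode": es_mode,
            "selection_statistic": selection_statistic,
        },
        provenance=provenance or f"built by mbsubtype {_pkg_version}",
    )


# ---------------------------------------------------------------------------
# Serialization: a single self-describing TSV archive with block headers
# ---------------------------------------------------------------------------

_HP_TYPES = {"alpha": float, "k": int, "n_top": int}


def save_reference(ref: TrainingReference, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_MAGIC}\tformat_version={FORMAT_VERSION}\n")
        fh.write("[hyperparams]\n")
        for key, val in ref.hyperparams.items():
            fh.write(f"{key}\t{val}\n")
        fh.write("[provenance]\n")
        fh.write(ref.provenance.replace("\n", " ") + "\n")
        fh.write("[genesets]\n")
        for name in ref.geneset_names:
            fh.write(name + "\n")
        fh.write("[samples]\n")
        for sid, lab, row in zip(ref.sample_ids, ref.labels, ref.rank_matrix):
            ranks = "\t".join("%.17g" % v for v in row)
            fh.write(f"{sid}\t{lab}\t{ranks}\n")
        fh.write("[end]\n")


def load_reference(path: str | os.PathLike) -> TrainingReference:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(_MAGIC):
        raise ReferenceFormatError(f"{path}: not a reference archive")
    header = lines[0].split("\t")
    if len(header) != 2 or not header[1].startswith("format_version="):
        raise ReferenceFormatError(f"{path}: malformed header line")
    version = header[1].split("=", 1)[1]
    if version != str(FORMAT_VERSION):
        raise ReferenceFormatError(
            f"{path}: format version {version} not supported "
            f"(this build reads version {FORMAT_VERSION})"
        )
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in lines[1:]:
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], [])
        elif current is not None:
            current.append(line)
    required = ("hyperparams", "provenance", "genesets", "samples", "end")
    missing = [s for s in required if s not in sections]
    if missing:
        raise ReferenceFormatError(
            f"{path}: truncated or malformed archive, missing sections {missing}"
        )
    hyperparams: dict = {}
    for line in sections["hyperparams"]:
        key, _, val = line.partition("\t")
        hyperparams[key] = _HP_TYPES.get(key, str)(val)
    provenance = "\n".join(sections["provenance"]).strip()
    geneset_names = [n for n in sections["genesets"] if n]
    sample_ids: list[str] = []
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in sections["samples"]:
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2 + len(geneset_names):
            raise ReferenceFormatError(
                f"{path}: sample row for {fields[0]!r} has {len(fields) - 2} "
                f"ranks, expected {len(geneset_names)}"
            )
        sample_ids.append(fields[0])
        labels.append(fields[1])
        rows.append([float(v) for v in fields[2:]])
    try:
        return TrainingReference(
            geneset_names=geneset_names,
            sample_ids=sample_ids,
            labels=labels,
            rank_matrix=np.array(rows, dtype=float),
            hyperparams=hyperparams,
            provenance=provenance,
        )
    except MBSubtypeError as exc:
        raise ReferenceFormatError(f"{path}: {exc}") from exc
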
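"""Core in-memory containers shared across the package.

Expression values are assumed to be normalized on some monotone-consistent
per-sample scale (log intensities, log CPM, VST...). Because every downstream
computation is rank-based, the particular scale is irrelevant as long as the
within-sample ordering of genes is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical medulloblastoma class labels, in canonical order. The four
#: consensus molecular subtypes plus a "Normal" (cerebellum-like) class.
SUBTYPES: tuple[str, ...] = ("WNT", "SHH", "Group3", "Group4", "Normal")

#: Vote fraction (percent) at or above which a call is reported as
#: high-confidence; lower winning fractions are flagged as intermediate.
HIGH_CONFIDENCE_PERCENT: float = 80.0


class MBSubtypeError(Exception):
    """Base class for all package errors."""


class ValidationError(MBSubtypeError, ValueError):
    """An in-memory object violates one of its invariants."""


def validate_subtype(label: str) -> str:
    if label not in SUBTYPES:
        raise ValidationError(
            f"unknown subtype label {label!r}; expected one of {SUBTYPES}"
        )
    return label


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized expression.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per row. Symbols are opaque, case-sensitive
        strings; no aliasing or ortholog translation is attempted here.
    sample_ids
        Unique sample names, one per column.
    values
        Float array of shape ``(len(gene_ids), len(sample_ids))``; all
        entries must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 2:
            raise ValidationError("expression matrix needs at least 2 genes")
        if len(self.sample_ids) < 1:
            raise ValidationError("expression matrix needs at least 1 sample")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene ids: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_index(sample_id)]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class GeneSetCollection:
    """Named gene sets for one species, GMT-style.

    ``sets`` maps set name -> (description, member gene symbols). Member
    lists must be deduplicated and non-empty; insertion order is preserved
    and meaningful (it is the on-disk order).
    """

    species: str
    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in ("human", "mouse"):
            raise ValidationError(
                f"species must be 'human' or 'mouse', got {self.species!r}"
            )
        for name, (desc, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")
            if any(not g for g in members):
                raise ValidationError(f"gene set {name!r} has an empty gene symbol")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return list(self.sets[name][1])

    def __len__(self) -> int:
        return len(self.sets)

    def translate(self, mapping: dict[str, str], species: str) -> "GeneSetCollection":
        """Map every member symbol through ``mapping`` (e.g. an ortholog map).

        Symbols missing from the map are dropped; a set losing all members
        raises. Term names are untouched — the cross-species bridge is the
        shared term namespace, not the gene symbols.
        """
        new_sets: dict[str, tuple[str, list[str]]] = {}
        for name, (desc, members) in self.sets.items():
            seen: list[str] = []
            for g in members:
                if g in mapping and mapping[g] not in seen:
                    seen.append(mapping[g])
            if not seen:
                raise ValidationError(
                    f"gene set {name!r} has no members left after translation"
                )
            new_sets[name] = (desc, seen)
        return GeneSetCollection(species, new_sets)


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        (dupes if x in seen else seen).add(x)
    return dupes
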
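"""Synthetic labeled cohorts and paired species genesets.

The generator emulates the data structure the classifier assumes: each
subtype up-regulates a disjoint block of signature genesets on top of an
i.i.d. Gaussian noise background. A ``mixing`` fraction blends a second
subtype's signature into each sample to emulate intermediate genotypes
(heterogeneous tumours between two subtypes). Paired human/mouse GMTs share
term names — the cross-species bridge — while mouse member symbols are a
deterministic, invertible transform of the human symbols recorded in an
ortholog map.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a
fixed seed reproduces cohorts bit-identically across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ExpressionMatrix, GeneSetCollection, MBSubtypeError, validate_subtype


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Expression is drawn on a log-like scale: baseline N(0, noise_sd) per
    gene and sample, with a sample's class adding ``signal_shift`` (in SD
    units of the noise) to the genes of its signature genesets. With
    ``mixing`` > 0 the shift is split: (1-mixing) to the sample's own class
    signature and mixing to the next class's (cyclically), so mixing=0.5
    sits exactly between two subtypes.

    Genesets partition the gene pool into disjoint consecutive blocks: the
    first ``signature_sets_per_class`` x n_classes sets are class
    signatures, the remainder are unshifted background sets.
    """

    n_per_class: int = 30
    classes: tuple[str, ...] = ("WNT", "SHH", "Group3", "Group4", "Normal")
    n_genes: int = 600
    n_genesets: int = 40
    genes_per_set: int = 15
    signature_sets_per_class: int = 3
    signal_shift: float = 3.0
    noise_sd: float = 1.0
    mixing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.classes:
            validate_subtype(c)
        if len(set(self.classes)) != len(self.classes):
            raise MBSubtypeError("classes must be distinct")
        for name in ("n_per_class", "n_genes", "n_genesets", "genes_per_set",
                     "signature_sets_per_class"):
            if getattr(self, name) < 1:
                raise MBSubtypeError(f"{name} must be positive")
        if not 0.0 <= self.mixing <= 1.0:
            raise MBSubtypeError("mixing must be in [0, 1]")
        if self.noise_sd <= 0:
            raise MBSubtypeError("noise_sd must be positive")
        if self.n_genesets * self.genes_per_set > self.n_genes:
            raise MBSubtypeError(
                f"{self.n_genesets} genesets x {self.genes_per_set} genes "
                f"exceed the {self.n_genes}-gene pool"
            )
        if self.signature_sets_per_class * len(self.classes) > self.n_genesets:
            raise MBSubtypeError(
                "not enough genesets for "
                f"{self.signature_sets_per_class} signatures per class"
            )

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"GENE{str(i + 1).zfill(width)}" for i in range(self.n_genes)]

    def signature_sets(self, cls: str) -> list[str]:
        """Names of the signature genesets of one class."""
        c = list(self.classes).index(cls)
        s = self.signature_sets_per_class
        return [_set_name(j) for j in range(c * s, (c + 1) * s)]

    def signature_genes(self, cls: str) -> list[str]:
        genes = self.gene_ids
        c = list(self.classes).index(cls)
        s = self.signature_sets_per_class
        g = self.genes_per_set
        return genes[c * s * g: (c + 1) * s * g]

    def mixing_partner(self, cls: str) -> str:
        """The class whose signature bleeds into ``cls`` samples when mixing > 0."""
        order = list(self.classes)
        return order[(order.index(cls) + 1) % len(order)]


def _set_name(j: int) -> str:
    return f"GO_BP_SET{str(j + 1).zfill(4)}"


def make_genesets(config: SimulationConfig, species: str = "human") -> GeneSetCollection:
    """The GMT implied by the config: disjoint consecutive gene blocks."""
    genes = config.gene_ids
    g = config.genes_per_set
    n_sig = config.signature_sets_per_class * len(config.classes)
    sets: dict[str, tuple[str, list[str]]] = {}
    for j in range(config.n_genesets):
        if j < n_sig:
            cls = config.classes[j // config.signature_sets_per_class]
            desc = f"signature_{cls}"
        else:
            desc = "background"
        sets[_set_name(j)] = (desc, genes[j * g: (j + 1) * g])
    return GeneSetCollection(species=species, sets=sets)


def _class_template(config: SimulationConfig, cls: str) -> np.ndarray:
    """Mean expression vector of one class (before noise)."""
    template = np.zeros(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(config.gene_ids)}
    own = [gene_pos[g] for g in config.signature_genes(cls)]
    template[own] += config.signal_shift * (1.0 - config.mixing)
    if config.mixing > 0:
        partner = config.mixing_partner(cls)
        other = [gene_pos[g] for g in config.signature_genes(partner)]
        template[other] += config.signal_shift * config.mixing
    return template


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, dict[str, str], GeneSetCollection]:
    """Draw a labeled cohort of ``n_per_class`` samples per class.

    Returns the expression matrix, the sample->subtype label table, and the
    (human) geneset collection whose signature blocks carry the signal.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_per_class * len(config.classes)
    values = np.empty((config.n_genes, n_total))
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    j = 0
    for cls in config.classes:
        template = _class_template(config, cls)
        for rep in range(config.n_per_class):
            sid = f"{cls}_{rep + 1:03d}"
            values[:, j] = template + rng.normal(0.0, config.noise_sd, config.n_genes)
            sample_ids.append(sid)
            labels[sid] = cls
            j += 1
    expr = ExpressionMatrix(config.gene_ids, sample_ids, values)
    return expr, labels, make_genesets(config, "human")


def mouse_symbol(human_symbol: str, prefix: str = "m") -> str:
    """Deterministic human->mouse symbol transform used by the paired GMTs."""
    return prefix + human_symbol.lower()


def generate_species_pair(
    config: SimulationConfig,
    ortholog_prefix: str = "m",
    mouse_term_dropout: float = 0.0,
) -> tuple[GeneSetCollection, GeneSetCollection, dict[str, str]]:
    """Paired human/mouse GMTs with a common term namespace plus ortholog map.

    Mouse member symbols are ``ortholog_prefix + human.lower()``; the
    returned map goes mouse symbol -> human symbol. ``mouse_term_dropout``
    removes that fraction of terms from the mouse GMT only (rounded down,
    chosen from the end of the background sets first so class signatures
    survive), emulating incomplete cross-species annotation.
    """
    if not 0.0 <= mouse_term_dropout < 1.0:
        raise MBSubtypeError("mouse_term_dropout must be in [0, 1)")
    human = make_genesets(config, "human")
    ortholog_map = {
        mouse_symbol(g, ortholog_prefix): g for g in config.gene_ids
    }
    inverse = {v: k for k, v in ortholog_map.items()}
    n_drop = int(mouse_term_dropout * len(human))
    keep = human.names[: len(human) - n_drop] if n_drop else human.names
    mouse_sets = {
        name: (human.sets[name][0], [inverse[g] for g in human.sets[name][1]])
        for name in keep
    }
    mouse = GeneSetCollection(species="mouse", sets=mouse_sets)
    return human, mouse, ortholog_map


def translate_to_mouse(
    expr: ExpressionMatrix, ortholog_map: dict[str, str]
) -> ExpressionMatrix:
    """Relabel a cohort's genes with their mouse symbols (exact 1:1 map)."""
    inverse = {v: k for k, v in ortholog_map.items()}
    missing = [g for g in expr.gene_ids if g not in inverse]
    if missing:
        raise MBSubtypeError(f"genes without mouse ortholog: {missing[:5]}")
    return ExpressionMatrix(
        [inverse[g] for g in expr.gene_ids], list(expr.sample_ids), expr.values
    )


def generate_replicate_set(
    config: SimulationConfig,
    n_replicates: int,
    template_class: str | None = None,
) -> ExpressionMatrix:
    """Independent replicate draws from a single class template.

    Emulates repeated profiling of one model system (e.g. a mouse model
    line); with ``config.mixing`` > 0 the template sits between two subtype
    signatures and some replicates fall below the high-confidence threshold.
    """
    if n_replicates < 1:
        raise MBSubtypeError("n_replicates must be >= 1")
    cls = template_class if template_class is not None else config.classes[0]
    if cls not in config.classes:
        raise MBSubtypeError(f"template class {cls!r} not in config.classes")
    rng = np.random.default_rng(config.seed)
    template = _class_template(config, cls)
    values = (
        template[:, None]
        + rng.normal(0.0, config.noise_sd, (config.n_genes, n_replicates))
    )
    sample_ids = [f"{cls}_rep{r + 1:03d}" for r in range(n_replicates)]
    return ExpressionMatrix(config.gene_ids, sample_ids, values)
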
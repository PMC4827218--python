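# Methods

## Problem and model

Medulloblastoma comprises four consensus molecular subtypes (WNT, SHH,
Group3, Group4) with distinct biology and prognosis; model systems and
patient samples both need per-sample subtype assignment. The classifier
treats subtyping as nearest-neighbor search in a *geneset rank space*:

1. ssGSEA converts one expression profile into an enrichment score per
   geneset, using only that profile's internal gene ranking;
2. genesets are ranked per sample by descending ES;
3. the sample's geneset-rank vector is matched against a labeled reference
   of such vectors by Euclidean (optionally Manhattan) distance, and the
   k nearest reference samples vote.

Working in rank space has two consequences that are the method's core
guarantees, and both are enforced by tests:

- **Monotone invariance.** Any strictly increasing per-sample transform of
  expression (log base, scaling, quantile-monotone normalizations) leaves
  every prediction bit-identical. Input therefore only needs to be
  "normalized" in the weak sense of within-sample rank consistency.
- **Single-sample independence.** Every step uses one sample's profile at a
  time, so a call never depends on batch composition, replicates, or a
  reference tissue sample.

## ssGSEA statistic

For gene ranks r_g (tie-averaged, 1..G ascending in expression) and geneset
S, genes are walked in decreasing-expression order (ties resolved by input
gene order, deterministically) and

ES(S) = Σ_{i=1..G} [ P_in^w(i) − P_out(i) ]

with P_in^w the r^α-weighted ECDF of set members and P_out the unweighted
ECDF of non-members. This *integrated* running difference is the default
(`es_mode="integrated"`); the classical signed maximum deviation is
available as `es_mode="max"`. Both the weight exponent and the mode are
configuration rather than constants because downstream k-NN consumes only
the ES *ranks*; defaults are α = 0.25 and the integrated sum, the standard
choices for this statistic's family.

Edge rules: set members absent from the measured genes are ignored (counted
in logs); a set with no measured member, or covering every measured gene,
has no defined score — the scalar scorer raises, the matrix scorer drops
such sets with a warning and raises only if none survive. An all-tied
(constant) expression profile carries no ranking information and is a hard
error rather than a silent uniform rank.

## Reference training

`build_reference` = ssGSEA → discriminative-geneset selection → rank
transform. Selection scores each geneset by the Kruskal–Wallis H statistic
of its ES across the label classes — a distribution-free, rank-based
statistic chosen to match the rank-based pipeline — and keeps the `n_top`
(default 100) highest, ties broken by geneset name. Constant-ES genesets
score 0. Any labeled cohort with ≥ 2 classes can train a reference; the
canonical five-class label set (WNT, SHH, Group3, Group4, Normal) is the
prediction surface, but a reference may cover any subset of it.

The serialized reference is a single versioned plain-text archive
(hyperparameter block, geneset list, labeled rank matrix) — diffable and
language-neutral; a version mismatch or truncation is an explicit load
error.

## Prediction

Harmonization intersects the test ES genesets with the reference's, in
reference order, then **re-ranks** the reference rows over the surviving
sets (default). Re-ranking rather than subsetting is the coherent choice:
rank values are only meaningful within a fixed geneset universe, and
because ranks are a monotone image of the ES values, re-ranking the stored
ranks reproduces exactly the ranks the surviving genesets' ES would have
given. The legacy subset behavior is available behind `rerank=False`.
Overlaps below 10 genesets log a warning but proceed.

k-NN uses k = 5 unweighted votes by default. Tie-breaks are all
deterministic: distance ties at the k-th position go to the
lexicographically smaller reference sample id; vote ties go to the label
with smaller mean neighbor distance, then to canonical label order. The
winning vote fraction (0–100 %) is the confidence; ≥ 80 % is a
high-confidence call, below it the sample is reported as an intermediate
genotype. With k = 5 the confidence grid is {20, 40, 60, 80, 100}.

PCA appears only in the visualization layer: test rank vectors are
projected into the principal components of the centered reference rank
matrix for plotting. Classification always operates in the full rank space.

## Synthetic cohorts

The generator stands in for the original (non-redistributable) clinical
training cohort and emulates exactly the structure the classifier assumes:
a gene pool partitioned into disjoint consecutive geneset blocks, the first
`signature_sets_per_class` blocks per class forming that class's signature;
baseline expression i.i.d. Normal(0, noise_sd) on a log-like scale; class
samples shifted by `signal_shift` (in noise-SD units) on their signature
genes. `mixing` ∈ [0,1] splits the shift between the sample's class and the
next class in the list, emulating intermediate genotypes; mixing = 0.5 is
maximally ambiguous. Gaussian noise makes expression ties almost surely
absent, keeping rank arithmetic exact in tests.

Defaults — five balanced classes, 30 samples per class, 600 genes, 40
genesets of 15 genes (3 signature sets per class), shift 3, noise SD 1 —
are the study conditions used throughout the test suite and the acceptance
script; they produce strong but not trivial class separation (held-out
recovery ≥ 95 % at high confidence, as the suite asserts). All randomness
flows through NumPy's `default_rng` (PCG64), a named, portable PRNG, so a
fixed seed reproduces cohorts bit-identically across platforms.

What the generator does *not* emulate: platform-specific noise
(microarray saturation, RNA-seq counts), batch effects, correlated genes
within sets, real GO term content, or realistic class imbalance. Passing
tests therefore demonstrate the algorithm's correctness and its invariances,
not clinical accuracy; accuracy on real cohorts depends on the reference
cohort a user trains on.

## Paired species genesets

`generate_species_pair` emits human and mouse GMTs with identical term
names; mouse member symbols are `"m" + lower(human symbol)`, an invertible
transform recorded in the returned ortholog map. This supports the
cross-species equivalence check: a mouse cohort produced by translating a
human cohort's symbols yields bit-identical ES matrices and predictions via
either route, because ssGSEA sees the same membership structure. A
`mouse_term_dropout` fraction removes terms from the mouse GMT only
(background sets first), emulating incomplete cross-species annotation and
exercising the harmonization filter.

## Numerical choices

- Tie handling everywhere is average rank (scipy `rankdata`), with walk
  order in the running sum fixed by input gene order.
- ES equality in oracle tests is asserted to 1e−10 absolute; rank and
  prediction invariances are asserted bit-exact (they involve no numerics
  beyond identical float operations).
- Expression and rank values are serialized with `%.17g`, which round-trips
  IEEE doubles exactly.
- The chi-square null-calibration check uses α = 0.01 over 500 null
  samples against the balanced reference class proportions.

## Problem sizes

Test and acceptance runs use the generator defaults above (150-sample
training cohorts; 100 held-out samples; 500 samples for null calibration;
oracle-equivalence fixtures of 500 genes × 30 genesets × 10 samples ×
100 replicates). These sizes give stable statistics while keeping any
single check within seconds on one CPU.

## Known limitations

- Confidences are raw vote fractions, not calibrated probabilities; there
  is no rejection option beyond the intermediate flag.
- Gene identifiers are opaque case-sensitive strings; symbol aliasing and
  probe-to-gene collapsing are the user's preprocessing responsibility.
- The discriminative-geneset statistic and count are configurable defaults,
  not a re-derivation of any particular published reference's geneset list;
  users reproducing published analyses must train on the corresponding
  cohort.
- `es_mode="max"` exists for comparison but the integrated mode is the
  statistic the pipeline is designed and tested around.
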
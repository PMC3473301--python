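# Methods

This note records the modeling choices, defaults and numerical conventions
behind `codingseq`, and what the synthetic experiments do and do not show.

## Training-set construction

The bitscore distance d(i,j) = 1 − (s(i;j)+s(j;i))/(s(i;i)+s(j;j)) is
clamped to [0, 1]; a missing reciprocal hit counts as bitscore 0, pushing
the distance toward 1. Graph clustering is transitive (connected
components), so two members of one cluster may be farther apart than the
edge threshold; this is intentional — conservation is evidenced by a chain
of similar sequences. A cluster is a highly conserved ORF (HCO) only if it
covers *every* genome of the species; multiple ORFs from one genome are
allowed in a cluster (the coverage condition alone governs). Medoid sums
use the distance function over all member pairs, not only graph edges.

Defaults: threshold t = 0.3 (cluster members roughly 70% similar), at most
400 Positives per species (uniform seeded sample when exceeded). Start
codons are ATG/GTG/TTG (common prokaryotic starts; configurable), stop
codons TAA/TAG/TGA (standard code only).

Preprocessing removes *all leading* start codons and every in-frame stop.
Removing only the literal first start codon would not be idempotent when
the following codon is itself in the start set; treating stripping as a
projection costs at most the rare legitimate Met/Val/Leu codon directly
after the start and makes repeated preprocessing harmless.

The "interior" from which the five out-of-frame Negatives are read is the
Positive's original span (offsets +1 and +2 on the same strand; offsets 0,
1, 2 on the reverse complement, 0-based half-open coordinates); endpoint
removal is handled by the stripping step, not by trimming margins. A frame
that strips to nothing is dropped with a warning.

Fold splitting is stratified by class so every training fold keeps the 1:5
Positive:Negative design; stratification is a variance-control choice and
can matter for small species.

## IMM

Each class has chains of orders 0..K. Pseudo-counts: with m observed
positions (transitions and initiations) in the class, m/4 pseudo-
observations are added, divided evenly over contexts (and target frames for
DNA) and over target symbols by the class's empirical 0-order distribution.
The spread distribution carries a uniform admixture of 1e-6 so every fitted
probability is strictly positive even for symbols absent from the class
data; at order 0 the spreading is then a fixed point of the empirical
distribution up to ~1e-6. A context never observed at order k reproduces
the spread distribution exactly.

Interpolation weights are global per order and estimated by EM on the
mixture-of-orders likelihood of the training data itself (no held-out
split). For fixed component probabilities this likelihood is concave in the
weights, so the EM result is initialization-independent; iterations stop
when the absolute log-likelihood gain falls below 1e-8 (cap 2000
iterations — boundary solutions, where all weight drifts to one order,
approach the optimum sublinearly and need several hundred). The first k
positions of a sequence lack a full pretext and are scored by the
highest-order chain they can support, consistent with interpolating down to
order 0.

Classification compares total log-probabilities at threshold 0 (pure
likelihood ratio; exact ties called Negative). No class-prior term is added
by default — the 1:5 design is available via `use_prior=True`, which adds
log(n_pos/n_neg).

Default maximum orders K: DNA 4, protein 2, codon 1, chosen so the three
models estimate a comparable number of parameters (4092 / 8420 / 3782);
word-frequency features use lengths 1..K+1 so the CPPLS feature dimension
matches exactly.

## CPPLS

No closed-form reference implementation was available, so the component
construction is authored here: for each component, loading weights
w_j(γ) ∝ sign(ρ_j)·|ρ_j|^(γ/(1−γ))·σ_j^((1−γ)/γ) with ρ the column–response
correlations and σ the column standard deviations of the deflated
predictors (both rescaled to max 1 before powering for overflow safety; the
direction is unchanged). γ = 0 and γ = 1 are the single-variable limits
(max σ, max |ρ|). γ is chosen per component from the grid
{0.5} ∪ {1/11, …, 10/11} by maximizing the canonical correlation between
the candidate score and the response (for a single response: its absolute
Pearson correlation). At γ = 0.5 the weights are proportional to the
covariances X'y, i.e. classical PLS — verified against an independent
NIPALS implementation to ~1e-15.

Deflation is the standard X ← X − t p'; coefficients are
β̂ = W(P'W)⁻¹q with intercept ȳ − x̄'β̂. The number of components A is
selected by a seeded stratified 5-fold inner cross-validation minimizing
held-out misclassification (squared error for continuous responses), ties
to the smallest A, capped at A_max = 10 and n − 1. Features are per-length
relative word frequencies with no further scaling — the power step subsumes
variance weighting. The decision threshold is fixed at 0, the midpoint of
the ±1 coding, with +1 meaning Positive throughout.

## Evaluation

Per fold: percent correct, sensitivity (Positives identified) and
specificity (Negatives identified), all in percent. Score-density overlap
is the shared area of the two per-class Gaussian kernel density estimates
on a common grid (degenerate constant samples are treated as point masses).

The mixed-effect ANOVA takes one fold-averaged, arcsine-transformed value
per (method, representation, species) cell — for 12 species this leaves the
design's 55 residual degrees of freedom; fold-level rows are deliberately
not the default cell value. Sums of squares are the classical balanced-
design marginal-means forms; every F, including the random species term, is
taken against the residual mean square. Variance components follow the
method of moments, σ̂_e² = MS_residual and
σ̂_s² = max(0, (MS_species − MS_residual)/6), truncated at zero. Tukey
comparisons use the studentized-range distribution with the residual df;
the variance comparison is a plain two-sided F-test.

## Synthetic data

The generator emulates the structure the real training data would have: per
species a codon-usage distribution drawn from a Dirichlet whose base
measure tilts codons toward a genomic GC target (mean concentration 5 per
codon by default — a realistic, clearly detectable codon bias), per family
an ancestral gene (i.i.d. codons from that usage, start prepended, stop
appended, lengths 100–400 codons), per strain a copy with each interior
codon resampled from the usage with probability equal to the divergence.
Codon-level mutation keeps the frame and can never create a premature stop.
Negatives are derived exactly as in the real pipeline, by reading each
Positive out of frame.

The toy all-against-all scorer counts distinct shared 8-mers (sparse
incidence product), with the self-score being a sequence's own 8-mer count.
Its distance is a much harsher function of divergence than an
alignment-derived bitscore: a codon-resample rate δ maps to a distance of
roughly 1 − (1−δ)^6.6 (measured: δ = 0.02 → ≈ 0.13, δ = 0.05 → ≈ 0.29,
δ = 0.10 → ≈ 0.49). The default divergence is therefore 0.02, which places
within-family distances comfortably below the clustering threshold 0.3
while between-family distances stay above 0.95 — the regime the clustering
invariants describe. At divergence ≥ 0.1 this scorer's distances exceed the
threshold and clusters cannot form; only a gentler (alignment-like) scorer
would tolerate that much divergence at t = 0.3.

What the generator does *not* emulate: phylogenetic structure among
strains, indels, intergenic DNA, overlapping genes, paralogy, horizontal
transfer, and amino-acid-level selection. Passing tests therefore show the
machinery is correct and powered under clean planted structure, not that
real-genome performance figures transfer.

## Problem sizes in the checks

The deep end-to-end checks use sizes chosen for quick, reliable runs:
classifier accuracy on the high-contrast codon fixture at the full 400
Positives / 2000 Negatives design (both classifiers reach ≥ 99% 10-fold CV
accuracy); the null fixture (both classes from one usage) at 150 Positives,
where accuracy settles near the 5/6 majority rate — the test accepts
75–90%, since finite-sample overfitting costs either classifier a few
points below 83.3 without indicating real signal; planted-family recovery
on 2 species × 4 strains × 30 families; ANOVA power on a full 12-species
planted table. The pipeline smoke test runs 2 species × 3 strains × 25
families with 3 folds.

## Known limitations

- The IMM's training-data-estimated interpolation weights favor the highest
  order (they maximize training likelihood); with few Positives this can
  cost sensitivity. A held-out weighting scheme would mitigate it but is
  not what the EM-on-training formulation specifies.
- CPPLS γ is optimized per component; a single global γ is not offered.
- Only the standard genetic code and ACGT sequences are supported;
  ambiguity characters are rejected by design.
- REML/unbalanced mixed models are out of scope; the ANOVA requires the
  complete balanced design.
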
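# Methods

`aspasep` asks a single question of two groups of protein sequences —
here bacterial versus fungal L-asparaginases (EC 3.5.1.1), an enzyme of
pharmaceutical (ALL chemotherapy) and food-industry (acrylamide
mitigation) interest: **are the two groups distinguishable from sequence
alone, and by which features?**  The pipeline answers it in five stages:
redundancy reduction, physicochemical description, pseudo amino acid
composition (PseAAC) featurization, per-feature ROC screening, and
cross-validated multi-classifier evaluation.

## Redundancy reduction

Public sequence sets are dominated by near-identical database entries,
which would let any classifier "memorize" rather than discriminate.
The reduction is greedy clustering in the CD-HIT style: sequences are
sorted by length (descending, ties by input order); each sequence joins
the first representative it matches at or above the identity cutoff
(default 0.95) or founds a new cluster.  Identity is defined exactly —
not by CD-HIT's short-word heuristics — as the number of identical
matched positions in an optimal global alignment (match +1, mismatch 0,
linear gap −1) divided by the shorter sequence's length.  A provably
safe screen (matched positions cannot exceed the shared residue
multiset) skips alignments that cannot reach the cutoff; results are
identical with the screen off, which the tests assert.

Reproducing any specific CD-HIT clustering bit-for-bit is a non-goal:
the representative sets agree where the identity definitions agree, and
our definition is the documented, exact one.

## Physicochemical descriptors

Per sequence: length, molecular weight (average residue masses plus one
water, 18.015 Da), theoretical pI, instability index, aliphatic index,
GRAVY, Arg+Lys and Asp+Glu counts, and the 20 residue frequencies.
Conventions follow Expasy ProtParam:

* **GRAVY** — mean Kyte–Doolittle hydropathy; positive values mean
  hydrophobic character (the standard sign convention).
* **Aliphatic index** — Ikai's weighted mole percent,
  X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu); a thermostability proxy.
* **Instability index** — (10/L)·Σ DIWV(x_i, x_{i+1}) over consecutive
  dipeptides (Guruprasad weights); < 40 is called "stable".
* **Theoretical pI** — root of the Henderson–Hasselbalch net charge
  (N/C termini plus D, E, C, Y, H, K, R side chains) found by bisection
  on [0, 14] to 0.002 pH units.  The default pKa set is Bjellqvist with
  the residue-specific terminal pKa adjustments ProtParam applies; the
  EMBOSS set is selectable (`pka_set="emboss"`).  The charge is strictly
  decreasing in pH and the termini guarantee a sign change, so the root
  exists and is unique.
* **Charged counts** — "positively charged" is Arg+Lys by default
  (ProtParam convention); `include_his=True` adds His.

Non-goals: extinction coefficients, half-life, atomic composition.

## Pseudo amino acid composition

Type-I PseAAC converts a sequence of length L into 20+λ components.
Three residue property scales — Chou's hydrophobicity (Tanford-derived),
Hopp–Woods hydrophilicity, and side-chain mass, shipped as a JSON data
file with literature provenance — are each standard-converted to mean 0
and population s.d. 1 over the 20 residues.  Tier-k sequence-order
factors average the squared scale differences of residues k apart:

    θ_k = (1/(L−k)) Σ_i (1/3) Σ_scales (H_i − H_{i+k})²

and the feature vector is x_u = f_u/(1 + w Σθ) for the 20 composition
components (f_u = counts/L) and x_{20+k} = w·θ_k/(1 + w Σθ).  Defaults
λ = 5, w = 0.05 (the canonical PseAAC defaults; λ must stay below the
shortest sequence, and both are recorded in the output sidecar).
Components are non-negative and sum to 1; w → 0 recovers plain amino
acid composition.  Equivalence with a brute-force transcription of the
formulas is asserted to 1e-10 on random sequences.

Type-II (amphiphilic) PseAAC and dipeptide composition are out of scope.

## Per-feature ROC screening

For each numeric feature the package reports the Mann–Whitney AUC
(probability a positive-class value exceeds a negative-class value, ties
half-credited; computed from midranks via exact integer arithmetic, so
AUC(pos,neg) + AUC(neg,pos) = 1 exactly) and the **best single-threshold
accuracy**: the maximum over all candidate thresholds (midpoints of
consecutive sorted unique values, ±∞) and both orientations of the
fraction classified correctly.  This maximization is the only way a
per-feature "accuracy" is well-defined without a pre-committed
threshold, and it makes the result invariant to which class is called
positive and to monotone rescaling of the feature.  A feature is flagged
discriminative when that accuracy exceeds 0.80 (configurable), the
conventional acceptability bar for a binary classification.  Ties in
the maximization break toward the lowest threshold, greater-is-positive
first, making reports deterministic.

Confidence intervals and DeLong tests are non-goals.

## Classification

Four classifier families run on the PseAAC matrix under stratified
5-fold cross-validation (default seed 17; leave-one-out by flag):

* **OET-KNN** (authored here): each of the k = 5 nearest training
  neighbors (Euclidean; distance ties broken by training-row index)
  with class q contributes a Dempster–Shafer mass m({q}) = α·exp(−γ_q·d²)
  with the remainder on the whole frame; α = 0.95 and γ_q = 1/(mean
  squared within-class distance of q on the training fold), a published
  heuristic.  Masses combine by Dempster's rule; the larger combined
  singleton belief wins, ties to the lower class index.
* **Covariance discriminant** (authored here): per-class Gaussian with
  its own covariance; score −Mahalanobis² − log|Σ_c| + 2·log prior.  A
  ridge of 1e-6·trace(Σ)/dim keeps the collinear PseAAC columns (they
  sum to 1) invertible.
* **SVM** (RBF, C = 1) and **random forest** (200 trees), backed by
  scikit-learn with the fold seed.

Features are standardized with training-fold statistics for the
distance-based OET-KNN and the SVM; trees and the (affine-equivariant)
covariance discriminant see raw features.  Confusion counts are pooled
across folds and ACC, MCC, Sn, Sp computed from the pooled counts; MCC
is defined as 0 when a marginal factor vanishes (the formula is 0/0
there).  AUC is reported as mean ± s.d. over fold-wise Mann–Whitney
AUCs of each model's decision scores (pignistic probability for
OET-KNN, score difference for the discriminant, decision function /
class probability for SVM / forest).

Hyperparameter search, calibration and multi-class support are
non-goals.

## Synthetic benchmark

Real asparaginase sets come from a moving database with no fixed
accession list, so the testbed is generative.  Each class profile draws
i.i.d. residues from a 20-way composition, lengths from a truncated
normal (floor 20), optionally plants a class-specific motif (a synthetic
stand-in string, not a real asparaginase motif) at a uniform position,
and emits near-duplicates (≤ ⌊0.02·L⌋ substitutions, hence identity
≥ 0.98) at a configurable rate.  A manifest records every draw.

The reference configuration mirrors the qualitative contrasts reported
for bacterial vs fungal asparaginases:

* lengths 330 ± 30 vs ≈414 ± 30 residues — the gap is chosen in closed
  form so the length feature's Bayes single-threshold accuracy is
  exactly 0.92 (fungal proteins longer and heavier);
* Cys/Glu elevated in the fungal class and Gly/Ser in the bacterial,
  each gap calibrated to ≈0.85 Bayes accuracy via the binomial sampling
  s.d. of a per-sequence frequency at the design length (the "moderately
  separating" regime); Trp is pinned identical in both classes as the
  at-chance control;
* a bacterial-only planted motif (90% of sequences).

Because residues are i.i.d., the generator does **not** emulate real
homology structure, domain architecture, positional conservation or
phylogenetic correlation; passing tests demonstrate that the pipeline
recovers differences of the configured kinds and magnitudes, not that
real asparaginases are separable.  Base frequencies are SwissProt-like
averages, renormalized to sum exactly to 1.

With n = 300 sequences/class the recovery checks assert: measured
length accuracy within ±0.04 of the configured 0.92; a null
configuration (identical profiles) at AUC 0.5 ± 0.05; all four
classifiers above pooled ACC 0.90 and MCC 0.80 on PseAAC features.
These sizes keep the full suite under half a minute while leaving the
binomial sampling error well inside the asserted bands.

## Numerical and design notes

* Descriptors use the published average residue masses, Kyte–Doolittle,
  DIWV and aliphatic coefficients via Biopython's curated tables; the
  three PseAAC scales are packaged JSON with sources.
* Reports are written with fixed float formatting and sorted JSON keys;
  with a fixed seed, reruns are byte-identical (asserted in tests).
* Degenerate inputs fail loudly: empty sequences, non-standard residues
  under the strict policy, sequences shorter than λ (error or logged
  drop), single-class tables, folds exceeding the smaller class,
  constant property scales, all-zero confusion counts.
* The residue policy for B/J/O/U/X/Z/* defaults to dropping the whole
  record, keeping descriptor and feature matrices aligned; masking and
  strict modes are available.  No minimum-length filter is applied
  beyond the λ constraint.
* Secondary-structure fractions and motif-level descriptors computed by
  external tools can be fed to the ROC stage as ordinary labeled TSV
  columns; the pipeline does not wrap those tools.
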
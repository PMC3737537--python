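# Methods

## Scope and pipeline

The package classifies transcribed small-RNA loci into six ncRNA functional
classes (lincRNA, miRNA, scRNA, C/D box snoRNA, snRNA, transposon-derived)
from aligned small RNA-seq reads. The pipeline is: read ingestion (BAM or
BED6, optionally restricted to uniquely mapping reads) → coverage-based locus
segmentation → label assignment by annotation overlap → a fixed 25-feature
representation per locus → random-forest modelling with backwards feature
elimination, cross-validation, permutation baselines, selection-stability
reports and proximity MDS.

All coordinates are 0-based half-open internally (BED-native); BAM records
are converted on read. Identical reads are collapsed to one record with a
multiplicity, and every downstream count is multiplicity-weighted, so
collapsed and expanded inputs are exactly equivalent (tested).

## Locus segmentation

Loci are maximal intervals where the strand-pooled, multiplicity-weighted
coverage is at least `min_coverage`, after merging intervals separated by at
most `max_gap` bases. Defaults are `min_coverage=1`, `max_gap=0` — the most
permissive setting, in which every covered base belongs to some locus; both
are exposed on the CLI because appropriate values depend on sequencing depth.
A locus takes the strand carrying the majority of assigned read multiplicity
(ties go to `+`, a pure convention: the tie carries no information). Loci
with fewer than 15 assigned reads are discarded by default — a quality floor
below which the entropy and length-spectrum estimates are too noisy to be
meaningful.

## Labelling

Each locus receives the class of the annotation it overlaps by the most
base pairs, considering only annotations from the active class vocabulary and
(by default) the same strand. Ties are broken by a fixed class priority
(miRNA > C/D box snoRNA > snRNA > scRNA > transposon > lincRNA, then
annotation name), ordered so that shorter, more specific annotation types win
against broad host transcripts. Loci overlapping nothing in the vocabulary
are labelled `unknown` and form the prediction-only pool. tRNA and rRNA are
accepted in the vocabulary for a three-class comparison mode but excluded
from the default six-class set, since those classes are trivially identified
by sequence homology.

## Features

| feature | definition | units |
|---|---|---|
| `L14`…`L30` | log2-odds of pseudocounted span proportions p_L, with f_L = Σ_k N_{L,k} / Length(i) | log-odds (base 2) |
| `antisense` | log2 ((n_as + α) / (n_s + α)) | log-odds |
| `pos_entropy5p/3p` | Shannon entropy of 5′/3′ read end positions | bits |
| `nuc_A/C/G/T` | log2 (f_b / 0.25), expression-weighted | log-odds |
| `mfe` | folding score of locus ± 40 bp flank | kcal/mol (vienna) or −pairs (nussinov) |

Numerical choices, and why:

- **N_{L,k} is coverage-style**: a read of span L contributes one count at
  every locus base it covers, because the defining ratio sums over bases and
  divides by the locus length — under that reading f_L is depth × span per
  base, and the Length(i) divisor is natural. A `start`-counting mode (5′
  ends only) is available as a configuration switch.
- **Read length = reference span** (end − start). For BED input no other
  definition exists; for BAM this excludes soft-clipped bases.
- **Log-odds transform**: p_L are formed with a Jeffreys-style pseudocount
  α = 0.5 scaled to the per-base feature units (α / Length(i)), then mapped
  through log2(p / (1 − p)). The pseudocount keeps all 17 outputs finite for
  empty spans; a locus with no in-range sense reads yields the uniform value
  log2((1/17)/(16/17)) = −4 exactly.
- **Sense reads only** feed the length, entropy and nucleotide features;
  antisense reads feed only the antisense feature. This keeps each feature a
  statement about the locus's own product. Entropy uses
  multiplicity-weighted counts; read end positions falling outside the locus
  bounds still count (they are real cleavage sites), while only in-locus
  bases count toward N_{L,k}.
- **All logs base 2, entropies in bits.**
- **Folding backends**: `vienna` (RNAfold, default parameters, kcal/mol) is
  the default when the bindings are importable; `nussinov` is a
  base-pair-maximisation dynamic program (Watson–Crick + G·U pairing,
  minimum hairpin loop 3) returning −(max pairs) — monotone with stability
  but not an energy; `table` reads per-locus scores from a TSV. One matrix
  must use one backend throughout (model features must be homogeneous), and
  the assembler enforces that.

Feature invariants verified by tests: translation invariance, strand
symmetry under genome reverse-complement, multiplicity/duplicate
equivalence, entropy bounds, and agreement with independent brute-force
implementations of every formula to 1e-9.

## Modelling

- Random forests (scikit-learn), default `ntree=1000`,
  `mtry = floor(sqrt(p))`. An `mtry_factor` multiplier is exposed; the
  square-root default is used because, in our own and others' experience,
  performance is flat in this parameter while cost is not.
- **Feature elimination**: iteratively fit, rank features by
  out-of-bag permutation importance (mean decrease in per-tree OOB
  accuracy; Gini importance available as a cheaper option), drop the least
  important 35% (`drop_frac=0.35`, at least one), refit, down to two
  features. The returned set is the smallest whose OOB error is within
  `se_rule` (default 1) binomial standard errors of the trace minimum.
  Note the consequence, which is by design: among *redundant* informative
  features the 1-SE rule deliberately returns a small sufficient subset,
  so per-feature selection frequencies are only stable when features carry
  complementary signal.
- **Cross-validation**: stratified k-fold (default 10) by round-robin
  assignment within class, which degrades gracefully to leave-one-out for
  classes smaller than k; single-member classes are excluded with a
  warning. Feature selection is nested inside each training fold by
  default; a pooled mode (select once on all data) exists for comparison
  and exhibits the expected optimistic bias on null data (tested).
- **Permutation baseline**: labels permuted (class sizes preserved by
  construction), same CV pipeline with selection disabled for bounded
  cost; the mean accuracy approaches Σ_k p_k² for well-behaved
  classifiers under the null.
- **Proximity MDS**: P_ij = fraction of trees where i and j share a leaf;
  d_ij = sqrt(1 − P_ij); classical (Torgerson) scaling of the
  double-centred squared distances, up to 5 dimensions, with a stress
  statistic reported. RF proximities are not Euclidean, so low-dimensional
  stress is inherently moderate; rank agreement is high on small fixtures.
- **Determinism**: every stochastic operation takes a seed and is
  bit-reproducible; child seeds are drawn from a generator seeded by the
  caller, and CLI outputs are byte-identical across repeated runs.
- No class rebalancing by default: raw forests on imbalanced classes match
  standard practice for this task; balanced class weights sit behind a flag.

## Synthetic data

Each class is a `ClassProfile`: a span multinomial over 14–30 nt, 5′/3′
cleavage concentrations (the 5′ jitter is Gaussian with
sd = locus_length / end5_concentration, discretised), an antisense read
fraction, base-composition weights, and a Normal(mfe_mean, mfe_sd) folding
score used by the `table` backend. The stock profiles encode the qualitative
class signatures: miRNA — strong 22-nt peak, precise 5′ / sloppy 3′ ends,
strongly folding; C/D box snoRNA — short-or-long spans, ragged ends;
transposon — short spans, tight ends, weak folding, high antisense; lincRNA —
14–17 nt spans; scRNA — 27-nt peak, weak folding; snRNA — 14-nt peak.

Because read spans must keep the profile multinomial exactly (the span
histogram is itself a feature), the 3′ concentration is realised by
*rank-coupling* the 5′ jitter with the span (comonotone to widen the 3′
spread, antimonotone to narrow it) rather than by jittering the 3′ end; both
marginals are preserved. Loci are placed ≥ 100 bp apart on one synthetic
chromosome; reads are clipped (span-preserving) to the locus ± 10 bp; the
genome is uniform ACGT outside locus ± 60 bp neighbourhoods.

What the generator does **not** emulate: sequencing errors and quality
strings, multi-mapping reads, overlapping or nested gene models, expression
differences between tissues, chimeric or spliced reads, and any dependence of
the folding score on the actual synthetic sequence when the `table` backend
is used. Passing tests on synthetic data therefore demonstrate the
correctness and internal consistency of the pipeline and its statistical
machinery — not classification accuracy on real tissue data, where classes
are less cohesive, much more imbalanced, and contaminated by mislabelled
loci. With the stock profiles at full separability the six classes are
nearly perfectly separable by construction; `sweep_separability` interpolates
all profiles toward their pooled mean to produce continuously harder tasks,
down to exactly chance at scale 0.

## Problem sizes

The test-suite and acceptance-script runs use 200 loci per class
(~1200 loci, ~75k reads), 10-fold nested cross-validation with forests of
150 trees (80 during per-fold elimination), 25 label permutations, and 100
stability-selection runs at 60 trees — sizes chosen so the complete
verification runs in minutes on one CPU while keeping every estimate's
sampling error well inside the asserted margins. Forest-size sensitivity is
flat over this range (doubling `ntree` changes synthetic-data accuracies by
less than the fold-to-fold noise).

## Known limitations

- The segmenter loads all reads in memory; fine for small-RNA depths here,
  not tuned for billion-read inputs.
- OOB permutation importance relies on reconstructing per-tree bootstrap
  membership from scikit-learn internals (with a documented fallback); a
  future sklearn release could change the private helper's signature.
- The Nussinov backend's scores are not comparable to RNAfold energies and
  must never be mixed with them in one matrix (enforced).
- GTF parsing covers the common `key "value";` attribute format only.
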
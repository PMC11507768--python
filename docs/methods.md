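# Methods

This note records the package's models and procedures, the defaults and why
they are what they are, what the synthetic cohort does and does not emulate,
and the numerical choices a maintainer would want written down.  It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Featurization

**RNA-binding region (RBR).**  Domain annotations (RRM/KH, 1-based
inclusive in files) are extended by `flank = 15` residues per side, clipped
to the sequence, and overlapping or adjacent intervals are merged.  File
coordinates are converted to 0-based half-open exactly once, at the I/O
boundary.

**Peptide profile.**  Every 5-residue window inside a segment contributes
the five gapped templates obtained by placing the wildcard `X` at each
position; templates are position-specific strings (`AXAAA` ≠ `AAXAA`).
Windows never span merged-segment joins (a junction window is not a real
peptide) and windows containing an unknown residue `X` are skipped (an
unknown residue carries no evidence).  On `X`-free input the total count is
exactly 5 × Σ max(0, len − 4) over segments.

**7-mer vocabulary.**  Lexicographic over {A, C, G, U}; the standard
vocabulary removes the two restriction-site 7-mers (stored in the assay's
DNA alphabet, transliterated T→U), leaving 16,382 of 16,384.

**Probe-array quantification.**  Intensities are centred and
variance-normalized per sample column, then per probe row.  Row
normalization requires at least two samples and is skipped with a warning
for single-column arrays — centring a length-1 row would annihilate the
data.  Each 7-mer is scored by the mean of the inner 95% of the normalized
intensities of the probes *containing* it (containment is a set property;
`⌈0.025 n⌉` values are dropped from each tail, ties resolved by value then
probe order; if trimming would empty the set, the plain mean is used).
Scores are Z-transformed with the population (n-denominator) standard
deviation.  7-mers contained in no probe receive the minimum Z with a
warning.  Variance normalization divides by the standard deviation (not a
robust scale), and trimming is per-7-mer within the queried sample.

## The joint embedding

**Preprocessing.**  Zero-variance columns (detected exactly, by zero range)
are dropped; remaining columns are centred by their mean and scaled to unit
Euclidean norm.  All statistics (masks, means over *all* raw columns,
centred-column norms) are stored for query-time reuse and serialization.

**Dimension selection** takes the SVD of the preprocessed RNA block alone
and returns the smallest rank whose reconstruction leaves every training
row with Pearson r ≥ `pcc_min = 0.95` to its original; if the target is
unreachable the rank is returned with a warning.

**Joint factorization.**  The SVD of the column-concatenation `[P R]` is
ranked by the RNA-variance score s_i = σ_i²‖v_{R,i}‖² (these scores sum to
tr(R Rᵀ) exactly, which the tests assert to 1e-8).  Ties are broken by
original singular-value order, and each retained component's sign is fixed
so the largest-magnitude entry of its right singular vector is positive —
output is deterministic across BLAS implementations.

**Encoders.**  Query vectors are masked to the training vocabulary
(unseen features warned and ignored; a query with *no* overlap is an
error), centred with the stored means, scaled by the stored norms — the
decoder adds the means back, so symmetric treatment of queries is the only
self-consistent choice — and projected by a minimum-norm least-squares
solve (LAPACK gelsd).  The pseudoinverse route is never formed explicitly;
small fixtures can make V′ᵀV′ singular and the min-norm solution handles
that case.

**Distances and decoders.**  e-dist is cosine distance in the retained
space; a zero embedding is defined to be at distance 1 from everything
(neutral, never confident) with a warning.  The local decoder weights raw
training RNA profiles by ε* = exp(−γ ε²), γ = 25, over the neighborhood
ε* ≥ 0.01 (equivalently ε ≤ √(ln 100/γ) ≈ 0.429); weights are normalized,
so the reconstruction is a convex combination of neighborhood profiles, and
an empty neighborhood yields the zero profile flagged non-confident.
Global decoding is V′_block w rescaled by the stored column norms plus the
column means; dropped columns decode to their training mean.  Protein
queries default to local decoding; RNA queries decode the peptide block
globally.  The confidence rule is min e-dist < 0.127.  γ, the 0.01
neighborhood cutoff, and 0.127 are configurable model fields, kept at these
published defaults.

**Homolog augmentation.**  For RNA queries the peptide block can be built
from gapped homolog alignments (the caller selects homologs, typically in
the 50–99% identity band): at each alignment window start, windows with a
gap or unknown residue are skipped and each *distinct* remaining 5-mer
contributes weight 1/(number of distinct 5-mers at that position) to its
five templates.  A position therefore contributes total weight 1 no matter
how many (possibly duplicated) homologs cover it, and a single homolog
identical to the training RBR reproduces the unaugmented profile exactly.
Augmented profiles stay real-valued and are preprocessed identically to
counts.

**Model container.**  A NumPy `.npz` bundle of the arrays plus a JSON
metadata entry with a format-version tag; loading checks the tag and
reproduces every array bit-exactly.  The raw training RNA profiles are
stored in the bundle so a loaded model can run the local decoder.

## Residue importance

Leave-one-out RNA queries over a cohort give reconstructed peptide rows
p*; the stacked matrix is standardized column-wise (population sd; constant
columns → 0 with a warning; a single row is refused rather than silently
standardized).  For one protein, each template with occurrence count c > 0
in its RBR distributes p*_t / c per occurrence onto all five covered
positions, the wildcard position included (the simplest reading of
"overlapping peptides"; the alternative is a one-line change).  Residues in
no window stay 0.  Scores depend on the standardization cohort; the
leave-one-out cohort is the intended one, because a protein inside the
training set would otherwise see its own private (e.g. mutation-derived)
templates reconstructed and amplified — held out, those templates are
absent from the fold vocabulary and cannot score.  Interface evaluation
against externally supplied contact labels uses rank-based AUROC (ties
averaged) and average precision.

## Motifs and identity

*Specific 7-mers*: upper-tail normal p-value ≤ fwer/vocabulary size
(Bonferroni; default family-wise error 1%).  *PFM*: the top-10 7-mers
(ties lexicographic) are stacked without gaps — each next 7-mer at the
offset within ±6 maximizing identity to the running consensus, ties to the
smaller absolute then negative offset — and columns are normalized by their
coverage rather than by 10, which avoids spuriously flat flanks.  *PSAM*:
columns divided by their maximum.  *Scanning*: per-position score is the
product of PSAM entries over the window; the binding score sums positions
exceeding 10% of the maximum possible window score (1 for a max-normalized
PSAM).  A PSAM column with a zero frequency zeroes any window using that
base — inherent to products of raw frequencies; callers who need soft
matching should add pseudocounts to the PFM first.

*Pairwise identity* is a Gotoh three-state global alignment with BLOSUM62
(Biopython's table) and affine gaps: open 11, extend 1, a gap of length L
costing 11 + (L − 1), end gaps penalized.  Co-optimal alignments can
disagree on identity, so the DP objective is fully tie-broken —
lexicographically maximize (score, match count, −alignment columns),
packed into a single integer with non-interfering field widths — making the
reported identity well-defined and platform-independent.  Identity divides
matches by alignment length by default; the shorter-sequence denominator
used by some pipelines is an option.  The DP is quadratic in pure Python,
intended for domain-sized sequences (capped at 1,000 residues).

*RBR identity* aligns per-domain units (domain + flanks, unmerged).  Equal
domain counts: mean of corresponding pairs.  Unequal: maximum over
contiguous placements of the shorter onto the longer, domain classes
matching at every aligned pair — accounting for single-domain gain/loss.
*70% rule*: transfer the profile of the highest-identity reference,
confident iff identity ≥ 0.70, ties to the earlier reference with a
warning.  *MSA identity*: exact matches at both-ungapped columns divided by
alignment length.

## Synthetic cohort

The generator provides planted ground truth with the statistical features
the method relies on, chosen once:

* **Proteins**: 150 aa, one RRM-annotated 50-aa domain at [51, 100], a
  20-aa specificity block at [71, 90]; RBR = [36, 115] after 15-aa flanks.
* **Shared scaffold**: all families descend from one scaffold; only the
  block is family-private random sequence, and between-family scaffold
  drift (15%) is placed outside the RBR.  Two deliberate reasons: unrelated
  RRMs really do share most of their fold, and any family-wide in-RBR drift
  would be statistically indistinguishable from the specificity block — no
  method could, or should, separate them.
* **Members**: bands (0.95, 0.9, 0.65, 0.45, 0.25) of RBR identity to the
  founder, cycled; the block takes 0 hits at ≥ 0.8, exactly 1 in
  [0.5, 0.8), 4 in [0.3, 0.5), and is unprotected below 0.3 — specificity
  drifts gradually with divergence.
* **Effects**: each family has 2 private latent factors; each factor is a
  motif-like "core energy" field — the log summed Boltzmann weight of a
  random 4-wide position-weight core (per-position energies ~N(0, 1))
  scored over a random context containing the 7-mer.  Such fields are
  smooth across overlapping/shifted 7-mers, as motif-driven binding is;
  this matters because probe intensities sum overlapping windows, so
  quantification recovers a shift-smoothed field, and a rough (i.i.d.)
  planted field would be unrecoverable at any probe count.  Factors are
  orthogonalized across families (they would otherwise share base-
  composition structure).  Template loadings have a dominant shared
  component plus weaker modulation, so a partially degraded block keeps a
  positively correlated signal.  Effects are scaled so a full template set
  gives a unit-sd signal: losing determinants weakens the signal against
  the fixed noise floor instead of renormalizing it away.  A weak low-rank
  background (amplitude 0.2, rank 6, keyed per template by checksum) lets
  every RBR peptide modulate the profile slightly, as flanking residues
  modulate real affinity.  Profiles add Gaussian noise (default sd 0.1) and
  are row-Z-transformed.  Effects are additive — matching the embedding's
  linearity deliberately, so recovery failures indicate bugs, not model
  mismatch.
* **Probe arrays**: designed-length 40-nt random probes; intensity = sum of
  softmax-scaled affinities (temperature 2) over the probe's 7-mer windows
  + additive lognormal probe effect (σ = 0.1) + Gaussian noise with sd =
  sd(signal)/SNR (default SNR 3).  Benchmarks use 120,000 probes — half the
  real assay's ~241,000, which recovery does not need because the residual
  error is dominated by overlap smoothing, not sampling.
* **Benchmark splits**: 4-fold cross-validation over members, stratified by
  band, founders always in training.  Founders are family centroids:
  querying a centroid against its satellites yields the *best*
  reconstruction at a *moderate* e-dist, structurally inverting the
  accuracy-versus-distance relation; the scenario of interest is an
  uncharacterized homolog at graded divergence from a characterized
  relative.  Pooling folds (50 queries) stabilizes the rank statistics.

**What the cohort does not emulate** — and hence what passing tests do not
show about real data: real domains vary in length, number, and class
mixture; real specificity determinants are discontinuous in sequence and
3-D-structured rather than one contiguous block; real probe sets are
designed for coverage and low secondary structure, not sampled uniformly;
real profile noise is correlated across related 7-mers; and real cohorts
are far larger and phylogenetically structured.  The planted linear model
cannot detect failures that only a nonlinear sequence–specificity
relationship would expose.

## Numerical choices and degenerate inputs

Zero-variance detection is exact (zero range), not tolerance-based.
Population (n) standard deviations throughout.  Quantification trimming
falls back to the untrimmed mean when a group is too small to trim.
Constant probe rows (multi-sample case) are zeroed with a warning; a
constant sample column is an error.  Empty peptide profiles warn and embed
as an error only after vocabulary masking removes everything.  The e-dist
of a zero embedding is 1.  Component-score ties keep singular-value order.
PFM column sums are validated to 1e-6 on write.  Seeds: every generator
takes an explicit integer seed and is reproducible across platforms;
seeded quantities in tests are asserted with margins measured across many
seeds during design, at the thresholds stated in the test docstrings.

## Known limitations

The alignment DP is pure Python and quadratic — fine for RBD-sized units,
wrong tool for proteome-scale all-vs-all scans.  The local decoder requires
the raw training profiles (stored in the model bundle; ~8 MB for a
355-construct training set).  LOOCV drivers refit the model per fold with
no warm start.  The CLI loads the full 7-mer matrix in memory.  Residue
importance inherits its cohort dependence from the standardization step;
scores are comparable within one cohort only.
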
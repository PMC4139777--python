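# Methods

## Problem and model

`snosite` predicts which cysteine residues of a protein are
S-nitrosylation (SNO) sites from sequence-derived information alone. A
candidate site is represented by the peptide window of `2ξ + 1` residues
centered on the cysteine (default ξ = 10, i.e. 21-mers); positions that
fall outside the protein are padded with the dummy residue `X`.
Coordinates are 1-based everywhere, matching curated PTM site databases.

Each window is encoded as a 458-dimensional vector:

1. **Evolutionary conservation (400 features).** The per-protein PSSM
   from an iterative profile search (PSI-BLAST `-Q` ASCII output) gives a
   log-odds substitution score `E[i, j]` per sequence position `i` and
   target residue type `j`. The window's rows are aggregated into a
   20 × 20 matrix keyed by (source residue type, target type): the row of
   each non-padded position is **summed** into the row of its residue's
   type, and the matrix is flattened row-major. Sum, not mean, is used in
   each cell; an optional `normalize=True` divides each row by the count
   of window residues of that type. Padded positions contribute nothing,
   so an all-padding context yields zeros.
2. **Predicted secondary structure (9 features).** Three-state
   per-residue predictions (H/E/C, e.g. PSIPRED `.ss2`) are sliced to the
   window's non-padded positions; per state the encoder reports the
   residue total, the average maximal-run length (0 when the state is
   absent, avoiding 0/0), and the composition fraction. Runs truncated by
   the window boundary count as one run.
3. **Physicochemical properties (49 features).** A 49-property × 20
   amino-acid table is averaged over the window's non-padded residues.

Padding is excluded from the secondary-structure composition denominator
and the physicochemical average (denominator = non-X residue count);
treating padding as zero-valued sequence would bias terminal windows
toward 0. Both encoders take `denominator="window"` to divide by the full
window length instead, for users who prefer the fixed-length convention.

The canonical amino-acid axis order is alphabetical by one-letter code
(`ACDEFGHIKLMNPQRSTVWY`) in every matrix; files using other orders (the
PSI-BLAST `ARND…` layout, reordered property CSVs) are re-mapped by their
own header letters at parse time.

### Feature selection

Features are ranked by **symmetric relative entropy**
`D_KL(P‖Q) + D_KL(Q‖P)` between the class-conditional distributions of
each feature. The densities are estimated by histograms sharing one set
of equal-width edges over the pooled min–max range — default 20 bins,
Laplace pseudocount 1 per bin. The shared edges make the estimator
symmetric in its inputs and the pseudocount keeps both divergences
finite; divergences are reported in nats. A feature constant across both
classes scores 0. Ties in the ranking are broken by ascending original
index, making the ranking deterministic.

**Incremental feature selection (IFS)** then evaluates every prefix of
the ranked list by stratified 10-fold cross-validation of the KNN rule
and selects the prefix with the maximum mean MCC (smallest prefix among
ties). One CV partition is drawn once (seeded) and reused across all
prefix sizes, so the IFS curve reflects feature-set changes only.
Implementation note: within each fold the squared Euclidean distance
matrix is grown incrementally, adding one rank-ordered standardized
feature column per step; this makes the full sweep over all 458 prefix
sizes linear in the number of features and is verified in the tests to
agree exactly with an independent all-feature CV run at the final prefix.

### Classifier

k-nearest neighbors with Euclidean distance and majority vote, default
k = 9. Features are z-score standardized with training-fold statistics
before distances are taken (constant features get standard deviation 1,
leaving them at 0 after centering); without this the integer PSSM sums
would dominate the composition fractions. The score of a query is the
fraction of positive neighbors; the label is positive when the score
exceeds 0.5 (odd k cannot tie; an even-k tie at exactly 0.5 is resolved
to negative — the conservative call for a site predictor). Distance ties
at the k-th rank are broken by the lower training-row index, so
predictions are reproducible across runs and platforms.

### Evaluation

Sensitivity, specificity, accuracy and the Matthews correlation
coefficient from the confusion counts; MCC is the headline number
because SNO training sets are imbalanced. Cross-validation uses
stratified folds (plain random splitting can produce degenerate folds on
imbalanced data) and averages per-fold metrics; pooled-confusion
aggregation is also reported. A metric with a zero denominator is
returned as 0 with an explicit flag rather than raising, which keeps IFS
sweeps over uninformative prefixes running. Site-level CV splitting is
the default; windows from one protein may land in different folds.
Protein-level splitting can be emulated by preparing per-protein feature
matrices externally.

## Synthetic data

The generator exists so every stage is testable without external
searches or downloads. It emits mutually consistent fixture sets
(proteins with forced cysteines, integer PSSM-like profiles biased
toward self-conservation, run-length H/E/C strings, random site labels)
that round-trip through every parser, and two-class feature matrices
with planted signal. Default class sizes are 731 positive / 810 negative
sites, the shape of a typical curated SNO training set.

In the feature-matrix generator, `effect_size` is the **joint**
(block-level) Mahalanobis separation of the informative features: each
of the k informative columns is shifted by `effect_size/√k` within-class
standard deviations. Splitting the separation across the block keeps
every informative feature individually useful, so cross-validated
performance keeps improving as each one enters a growing subset; giving
each column the full separation instead saturates the classifier after
two or three features, after which the smallest-among-ties rule
truncates the optimal subset below the planted set. Per-column
log-normal scale factors give the matrix heterogeneous feature
magnitudes like the real encoder stack (the standardizer removes them).

What the generator does **not** emulate: real SNO sequence motifs,
amino-acid composition biases, alignment-derived correlation structure
between PSSM columns, or realistic secondary-structure transition
statistics. Passing tests therefore demonstrate the correctness and
statistical behavior of the machinery (encoders, ranking, IFS, KNN, CV),
not predictive performance on biological data — for that, real PSSMs and
secondary-structure predictions are required as inputs.

The bundled physicochemical table is likewise a synthetic stand-in
(49 deterministic pseudo-properties, frozen in
`src/snosite/data/physchem_properties_synthetic.csv`); the encoder
contract is independent of the table's values, and any curated 49 × 20
table can be supplied via `--property-table`.

## Numerical and design choices

- Histogram ranking: 20 bins, pseudocount 1, natural log. The bin count
  and log base are tunable; scores change monotonically enough that
  rankings are stable for moderate bin counts.
- All randomness (fold assignment, generators) flows from explicit
  integer seeds; every stage is byte-reproducible given the same seed.
- Simulation problem sizes used by the test suite and the acceptance
  script are scaled to desk scale as the package's own choice: parameter
  recovery uses 200+200 samples × 458 features × 20 replicate seeds;
  the label-permuted null uses 400+400 samples × 5 seeds. At these sizes
  the full IFS sweep finishes in a few seconds per replicate.
- Empty-bin KL conventions with the pseudocount disabled:
  `0·log(0/q) = 0`; `p>0` against `q=0` is infinite. The default
  pseudocount avoids the infinite case entirely.

## Known limitations

- Running PSI-BLAST and PSIPRED is out of scope; their outputs are
  inputs. The profile parser accepts the common ASCII dialects (with or
  without the weighted-percentage block) but not binary checkpoints.
- The IFS optimum is a greedy prefix of a filter ranking, not a search
  over subsets; correlated features can displace one another in the
  prefix.
- MCC-optimal subset selection inherits CV noise; at strong separation
  many prefixes tie near-perfectly and the reported optimum is the
  smallest of them by design.
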
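# Methods

## Problem and model

`acpda` classifies short peptides as anticancer (ACP) or not from sequence
alone.  The pipeline is: fixed-length normalization → concatenated
sequence encodings → mutual-information feature selection → feature-space
oversampling of the training split → a multilayer perceptron → stratified
five-fold cross-validation scored by ACC/PRE/SN/SP/MCC.  The modeling bet is
that, at benchmark sample sizes (hundreds of peptides), enlarging the
training set with slightly perturbed copies of real samples regularizes the
classifier more than the injected noise distorts the feature distribution.

## Encodings

**Length normalization.**  Sequences are padded with the letter `X` to
`L_X` residues, or truncated to their first `L_X` residues.  Truncation
keeps the N-terminus because the positional features are N-anchored.  `X`
is a first-class alphabet member that deliberately encodes "no
information": it maps to zeros in both per-position encoders and to an
all-zero column in the k-mer matrix, so padding can never masquerade as
sequence content.

**BPF.**  One-hot encoding of the first `k = 7` residues over the
alphabetical order `A C D E F G H I K L M N P Q R S T V W Y`; 140 binary
features.

**AAindex.**  Per position, the full vector of physicochemical index values
for that residue (position-major layout, stable feature names
`aai_pos{j}_{index_id}`).  The shipped default table is **synthetic**:
531 × 20 i.i.d. standard-normal entries from a fixed seed
(`synthetic_aaindex_table`).  A random table is a random injective
embedding of residue identity, which preserves every structural property
the pipeline and its tests rely on (dimensions, selection dynamics,
augmentation algebra, learnability of compositional signals) while carrying
no physicochemical meaning; real gap-free tables drop in via
`AAIndexTable.from_tsv` / `--aaindex-table`.  Encoders emit raw values —
no standardization — so substituted tables are seen by the classifier at
their native scales.

**k-mer sparse matrix.**  The 20 residues are collapsed to 7
physicochemical classes (`AGV | ILFP | YMTS | HNQW | RK | DE | C`; the
partition is configurable since reduced alphabets vary across the
literature), each length-`K` window (default `K = 3`) becomes a single 1 in
a `7^K × (L−K+1)` 0/1 matrix, and the matrix is reduced to the fixed
vector `σ₁u₁` from its leading singular triplet.  Numerical choices: the
SVD runs dense (LAPACK) because these matrices are tiny and iterative
sparse solvers are start-vector-dependent exactly when the leading singular
value is degenerate — which happens whenever all windows of a peptide are
distinct k-mers; the sign is fixed by making the largest-magnitude entry
(lowest index on ties) positive.  When the spectrum is degenerate the
triplet itself is not unique; the dense route at least makes the choice
deterministic and platform-stable for a given LAPACK.

## Feature selection

mRMR over the AAindex block only (BPF and k-mer blocks pass through).
Mutual information uses the plug-in estimator on features discretized into
three bins at `μ ± σ` (labels are already binary); the greedy criterion is
the difference scheme `MI(x;y) − mean_{s∈S} MI(x;s)` (MID; MIQ available),
with ties broken by lowest feature index so selection is fully
deterministic.  Selection is fitted **inside each training fold** — fitting
on pooled data before splitting leaks test information through the selected
set; a `leaky_selection` flag exists solely to reproduce pooled-fit
protocols.  The selected 50 columns index raw feature values; the
discretization never touches the data downstream.  Implementation detail:
candidate-vs-selected MI values are computed for all columns at once from
indicator-matrix products in float32 (counts are exact integers at these
sample sizes) with the probability arithmetic in float64, which makes the
vectorized path agree with naive counting to ~1e-15.

## Augmentation

`F_new = F_i ⊙ (1 + a·V)`, where `F_i` is drawn uniformly with replacement
from one class of the training split and `V` is redrawn per pseudosample:
zero on BPF columns (a 0/1 profile cannot absorb noise), uniform `[0,1)` on
the selected AAindex columns; k-mer columns, when present, are likewise
copied unchanged.  Defaults: `a = 0.005`, so each AAindex entry moves by a
relative amount in `[0, a)` away from zero with mean `a/2`; pseudosample
count is `round(n_fraction · class size)` (half-up), with `n_fraction` the
swept 100/200/300%.  Both classes are augmented independently with the same
fraction, preserving the class ratio.  Augmentation runs strictly after the
train/test split and after selection, in the 190-dimensional working space,
and every pseudosample records its source id; the cross-validation driver
asserts at runtime that no test sample ever appears among the sources.

## Classifiers and evaluation

MLP: 6 hidden layers × 100 relu units, L2 `alpha = 0.01`, adam at library
defaults, seeded per fold.  SVM/RF/DT/extra-trees run at library defaults
(seeded), echoed into every report.  Decision threshold is the library's
0.5; no tuning.  Folds are stratified (the benchmark classes are
near-balanced and small, where plain k-fold is unstable).  Metrics come
from per-fold confusion counts; a zero denominator yields NaN (never a
silent 0), and aggregates are unweighted fold means with NaN folds ignored.
The MCC numerator is the standard `TP·TN − FP·FN` (with the usual
four-factor denominator).  Features reach the classifier unstandardized by
default; `standardize=True` enables a per-fold `StandardScaler` (logged),
useful when substituted AAindex tables put features on wildly different
scales.

The parameter sweep covers `L_X ∈ {40,50,60} × N ∈ {100,200,300}%` and
flags the maximum-MCC cell (ties → smaller `L_X`, then smaller `N`).  The
feature ablation evaluates all seven non-empty block combinations without
augmentation.  The classifier comparison pairs augmented vs unaugmented
MCC per classifier under byte-identical folds.

## Synthetic data

`generate_dataset` emulates the shape of ACP benchmarks: class sizes in the
hundreds, lengths uniform on 10–60 residues (most benchmark peptides are
under 60 residues), negatives i.i.d. uniform over the 20 residues, and a
tunable N-terminal signal: with probability `signal_strength` per position,
each of the positives' first seven residues is drawn uniformly from
`{K,R,L,F,A}` (a cationic/hydrophobic set mimicking cationic amphipathic
ACPs — a modeling device, not a biological claim).  The signal sits at the
N-terminus so both the BPF and AAindex blocks can see it.  At
`signal_strength=1` the classes are almost surely separable from the first
seven positions (a uniform negative matches the enriched alphabet at all
seven positions with probability `(1/4)^7 ≈ 6·10⁻⁵`); at 0 the classes are
exchangeable and any honest pipeline must score MCC ≈ 0.  What the
generator does **not** model: residue autocorrelation, amphipathic
periodicity, secondary structure, realistic length–class dependence, or
homology between samples — so green tests certify the pipeline's mechanics
and leakage hygiene, not real-data accuracy.  `generate_feature_fixture`
supplies class-shifted Gaussian columns for exercising selection and
augmentation directly.

## Problem sizes used in the checks

The packaged checks run the full pipeline at 200+200 samples (full-signal
condition) and 100+100 samples × several seeds (null condition), with the
531-index table, `L_X = 40`, `m = 50` — large enough for the MCC bounds
(> 90 full-signal, ±10 around 0 null) to be stable across seeds while a
complete run stays in the tens of seconds on one core.  Unit tests use
reduced tables (11–60 indices) and tree classifiers where the property
under test does not depend on the classifier.

## Known limitations

- The default AAindex table is synthetic; absolute benchmark accuracy with
  it is not evidence about physicochemical feature quality.
- The SVD reduction of a degenerate-spectrum k-mer matrix is deterministic
  but basis-dependent across LAPACK builds.
- MLP training emits convergence warnings at small `max_iter` on hard
  folds; results are reported regardless (the seed is recorded).
- `nanmean` aggregation silently shrinks the effective fold count when a
  fold's metric is undefined; per-fold values are always retained in the
  report for inspection.
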
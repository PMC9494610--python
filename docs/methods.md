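# Methods

## The measurement model

The package treats the TCRβ CDR3 amino-acid sequence as a clonal barcode.
A clone observed in a patient's blood (PBMC) whose CDR3β also occurs among
the same patient's tumour-infiltrating lymphocytes (TILs) is taken to be
tumour-associated (a cTAT). Two sample-level summaries are built on that
definition — a sequence-level repertoire risk score (TRRS) and a
transcriptional signature score — and fused by logistic regression into a
single cancer-risk probability.

### Compartments and matching

Sharing is decided by exact string match. The default key is the CDR3β
amino-acid sequence alone; a stricter (V gene, CDR3, J gene) key is
available for sensitivity analysis. One key is used throughout the
pipeline (pool membership, classifier training, TRRS), because mixing
match keys between stages would make the TRRS numerator and denominator
incommensurable. Clone-level overlap proportions are count-weighted by
the tissue whose proportion is being reported; sequence-level proportions
count distinct CDR3s once. Empty repertoires yield missing (None)
proportions rather than 0, since 0 would be a claim, not an absence.

### Repertoire filtering

The default pipeline keeps productive rearrangements whose CDR3 contains
only the 20 standard residues (no `*`, `_`, `X`) and whose length lies in
12–17 inclusive, where the large majority of functional β chains fall.
Functional and length filters commute; order is irrelevant. Length
histograms can be computed before or after the length filter — both
orders are exposed because the choice changes what fraction of sequences
the 12–17 window captures.

### Diversity indices

Clonality is `1 − H/ln R` with Shannon entropy `H` in nats and richness
`R` (number of clones). It is undefined (0/0) for a single clone and is
returned as missing with a warning. The Gini coefficient is computed via
the sorted Lorenz form, algebraically identical to the pairwise
mean-absolute-difference definition `Σᵢⱼ|cᵢ−cⱼ|/(2nΣc)` (a property test
checks equality to 1e−12); no small-sample `n/(n−1)` correction is
applied by default, matching the uncorrected form most repertoire tools
report, with the correction available as an option. Group comparisons use
the two-sided Mann–Whitney U without multiple-testing correction across
panels; compartment-restricted indices renormalise counts within the
compartment.

## The sequence classifier

CDR3β sequences are one-hot encoded into 17 × 21 matrices: 20 amino-acid
channels plus a dedicated padding channel for rows beyond the sequence
end, so one network serves all lengths 12–17. The network is three
same-padded 1-D convolution layers (32/64/128 channels, kernel width 3,
ReLU), a global max-pool over positions, and a single sigmoid unit,
trained with Adam (learning rate 1e−3, batch 256) on binary
cross-entropy. Default training is 60 epochs — with the synthetic data
used here the loss/accuracy trace plateaus well before that, and shorter
schedules (25–40 epochs) are used in examples and routine checks. The
network is implemented directly on NumPy (im2col convolutions, exact
backprop), is float64 throughout, fully deterministic given the seed, and
serialises bit-exactly. Depth is the modelling commitment; channel
counts, kernel width and optimizer settings are declared defaults in
`CnnConfig`, not claims of optimality.

Training sets are balanced 1:1: positives are globally deduplicated cTAT
sequences minus anything in the healthy pool or in virus/bacteria
exclusion lists; negatives are a seeded uniform sample without
replacement from the (exclusion-filtered) pool. Cross-validation
partitions *patients*, not sequences, into folds — a sequence-level split
would let patient-specific repertoire quirks leak between train and test.
Negatives, which have no patient identity, are split at random. HLA
information is accepted as metadata and ignored by the model.

### Motif read-out

Sequences in the top and bottom 25% of predicted probability are compared
by positional amino-acid frequency, per length stratum and pooled across
lengths, with log2 odds `log2((f_high + pc)/(f_low + pc))` under a small
pseudocount. The pooled table is the primary read-out; frequency matrices
are returned as DataFrames suitable for heatmap rendering.

## TRRS

For one filtered PBMC sample, the numerator counts unique sequences whose
predicted TAT probability exceeds the cutoff (default .66, interpreted as
the per-sequence probability cutoff; the cutoff-on-TRRS reading is also
implementable by thresholding the returned scores) and the denominator
counts unique sequences present in the healthy reference pool. The score
is presence-based — clone counts never enter — so it is invariant to
sequencing depth differences that only rescale counts. A sequence may in
principle contribute to both numerator and denominator; the
mutually-exclusive variant is a one-line filter on the caller's side and
deliberately not the default, since the pool overlap is meant to measure
"ordinary repertoire content" independently of the classifier. Zero pool
overlap yields a missing score with a warning. Threshold scans predict
once per sample and re-threshold, so robustness analysis costs one model
pass. Risk groups split at the median with ties assigned high.

## Transcriptional signature

Per dataset, differential expression compares CD8⁺ TAT cells against
non-clonal cells (clone frequency exactly 1 and not TAT; cells at
frequency 2 belong to neither the clonal >2 nor the non-clonal =1 group
and are excluded) by two-sided Wilcoxon rank-sum per gene with
Benjamini–Hochberg control; a DE call needs adjusted p < .05 and
|log2FC| ≥ .25. Expression is assumed library-normalised and log2-scale,
so differences of group means are log2 fold changes. Datasets with fewer
than 20 cells in either group are skipped with a warning rather than
contributing noise to the recurrence count.

The signature keeps genes DE *with a consistent direction* in strictly
more than `min_datasets` (default 10, of 14) datasets: the
majority-direction support count itself must clear the threshold, and an
up/down tie excludes the gene. Bulk scoring z-scores each present gene
across samples (zero-variance genes contribute 0) and takes mean z of
up-genes minus mean z of down-genes; ≥ 50% of signature genes must be
present. Leave-one-dataset-out validation re-derives the signature from
the remaining datasets (recurrence threshold rescaled as
`floor(n·10/14)`), fits an L2-regularised logistic model on
standardised signature-gene expression, and reports held-out
TAT-vs-non-clonal AUC; permutation nulls permute labels against fixed
scores using the rank-sum identity for AUC. TIGS is the literal product
TMB × mean APM-gene expression per sample.

## Combined screen

TRRS and signature score are z-standardised and fitted by
maximum-likelihood logistic regression (statsmodels). Perfect separation
— common at the 17–50 sample sizes this screen targets — triggers a
fallback to a lightly ridge-penalised fit (α = 1e−4) with a warning.
Component comparison reports both leave-one-out cross-validated AUC
(pooled out-of-fold probabilities, shared fold assignment across feature
sets) and in-sample AUC; LOO is the default because the validation
cohorts the screen is designed for are small.

## Synthetic data: what it does and does not emulate

The simulators provide every input with recorded ground truth and full
determinism (config + seed → byte-identical output).

* **Repertoires.** CDR3s are a fixed `C…F` flank around a random core
  drawn from a plausible background composition (serine ≈ 7%); lengths
  12–17 with a unimodal peak at 14–15; clone counts are Zipf(exponent 2.0)
  truncated at `n_clones`, giving the heavy tails that make clonality and
  Gini non-trivial. Each PBMC clone is independently tumour-shared with
  probability `f`, so recovered overlap fluctuates binomially around the
  planted fraction.
* **The planted TAT motif** is a multi-position profile: serine at the
  second residue with p = .8 (the dominant, headline preference), plus
  weaker secondary preferences (G at position 5, p = .5; Q at position 7,
  p = .35). A profile rather than a single site is used because one
  stochastic binary position mathematically caps the achievable
  sequence-level AUC near .87 regardless of the classifier — too coarse a
  signal to exercise or discriminate model quality — while antigen-driven
  selection in real repertoires touches several CDR3 residues. The
  profile puts the Bayes-optimal AUC near .95.
* **Cohorts.** Every sample draws 35% of its clones from the healthy
  pool — public/shared TCRs are a genuine feature of human repertoires,
  and they give the TRRS denominator its mass. Tumour samples replace 5%
  of private clones (default) with motif-bearing sequences. The
  HCMV-like control group gets a handful (5% of clones) of strongly
  expanded clones with no motif, reproducing infection-driven expansion;
  a steeper Zipf exponent was rejected for this purpose because, under
  the count cap, it flattens rather than concentrates the distribution.
* **Expression.** Cells/samples are Gaussian noise in log2 space around a
  common baseline; TAT cells (or tumour samples) are shifted by ±1
  log2-unit on the planted genes (half up, half down). TAT cells are
  clonally expanded (frequency > 2) and mostly CD8⁺; most non-TAT cells
  are non-clonal.

What passing tests on this data do **not** show: robustness to real
repertoire sharing structure (public clones are far from uniform),
V(D)J-generation sequence statistics, single-cell dropout (which
mislabels shared clones as private), batch effects between expression
datasets, or compositional/UMI noise — the generator's noise is clean and
exchangeable where real data are not. Results on synthetic data validate
the machinery and its statistical calibration, not clinical performance.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; stochastic APIs take the seed as an argument.
* Clonality of one clone, TRRS with zero pool overlap, AUC of a
  single-class cohort, and proportions of an empty repertoire are all
  *missing*, each with a warning — never silently 0.
* Unencodable sequences in `predict` yield per-sequence NaN, not a batch
  failure; `predict` scores each distinct sequence once so duplicates are
  bit-identical.
* Zero-variance genes are untestable and never called DE; their z-score
  contribution to signature scoring is 0.
* Ties: risk-group split assigns median ties to high; an up/down
  direction tie excludes a gene from the signature; quantile cuts in the
  motif analysis use ≥/≤ so boundary sequences enter both extreme groups
  symmetrically.

## Known limitations

The classifier architecture is a minimal declared default, not a tuned
model; no HLA restriction is modelled; TCRα chains, nucleotide-level
clonotypes and non-exact (similarity-based) TCR matching are out of
scope; no rarefaction or depth normalisation is applied to diversity
indices; and headline performance numbers reported by the examples and
acceptance script describe synthetic, planted-signal data by design.
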
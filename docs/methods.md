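# Methods

## Scope and model

`tcrvae` fits probability distributions over T cell receptor β chains
represented as triples x = (V gene, J gene, CDR3 amino-acid sequence).  Two
families of models are implemented and compared:

1. **β-VAE models** (`basic`, `count_match`): a 20-dimensional latent
   variable z with standard-normal prior p(z), a diagonal-normal encoder
   q_φ(z|x), and a decoder p_θ(x|z) that factorises into categorical
   distributions over the V gene (67 classes), the J gene (13 classes) and
   each of 30 CDR3 sites (20 amino acids + gap).  The training loss is

       L(x) = R(x, z) + β · KL(q_φ(z|x) ‖ p(z)),

   where R is a weighted sum of reconstruction terms: categorical
   cross-entropy for V and for J, and the per-site cross-entropy averaged
   over the 30 padded CDR3 sites.  Because the components are separately
   weighted, L is not an evidence lower bound; it is a β-weighted,
   multi-head reconstruction objective.

2. **Recombination–selection baseline**: any generation-probability
   provider Pgen (the built-in simulator, or an external recombination
   engine implementing the same three-method contract) multiplied by a
   selection factor Q(V, J, CDR3 length).  The maximum-likelihood Q for a
   key is the ratio of its empirical frequency to its probability under the
   recombination model, truncated at `q_max` (default 100) for numerical
   stability.  Sampling from Pgen·Q uses rejection sampling with acceptance
   probability Q/q_max.

## Encoding

CDR3 sequences (length 1–30) are padded to 30 symbols with a contiguous
central gap block — ceil(L/2) residues on the left, floor(L/2) on the right
— and one-hot encoded over a 21-symbol alphabet (amino acids in alphabetical
one-letter order, gap last).  V and J genes are one-hot over the registry's
ordered gene lists.  The first model layer applies learned linear
embeddings: a 21→21 map shared across CDR3 sites, a 67→30 projection for V,
and a 13→13 map for J.  The deterministic encoding (this module) and the
learned embeddings (the model) are kept separate so that encodings are
reproducible without weights.

## Architectures and numerics

Both encoder and decoder use two dense layers of 100 ELU units (the layer
count is structural; the width is a default, configurable in `VaeConfig`).
The networks are implemented directly in NumPy with hand-derived exact
gradients (softmax cross-entropy, squared loss, closed-form KL, and the
reparameterization z = μ + σ·ε); gradient correctness is checked against
central finite differences in development.  Optimisation uses Adam
(lr 10⁻³, β = 0.9/0.999).  At these model sizes (≈0.2 M parameters) CPU
matrix multiplication is not a bottleneck.

`count_match` additionally conditions the decoder on germline context and
carries auxiliary heads:

- the germline CDR3 prefix of the input's V gene (right-gap-padded to 6
  symbols) and suffix of its J gene (left-gap-padded to 8) are one-hot
  encoded and concatenated to z at the decoder input;
- three linear heads predict the V-germline match count, J-germline match
  count, and CDR3 length, scored by squared loss against the true values.

The auxiliary heads shape training only; the probability of a sequence
under the model always uses the three categorical heads.  During
generation the decoder is evaluated twice: V and J are drawn with the
germline block zeroed, then the CDR3 is drawn after re-decoding with the
drawn genes' germline context.  The germline prefix/suffix table ships as
an editable CSV (`data/trb_germline_synthetic.csv`); the J-gene CDR3
suffixes follow the standard TRBJ annotations while the V-gene prefixes are
plausible synthetic approximations, since exact germline boundaries are a
data input rather than an algorithmic matter.

## Training protocol

The training set is split into true-training and validation parts
(validation fraction 0.1).  β follows a linear warm-up: 0 at epoch 0,
rising each epoch to its final value (default 0.75) at `warmup_epochs`
(default 20).  Training proper is preceded by `n_pretrain_phases` (default
3) short runs (default 10 epochs) from fresh random weights; the phase with
the best validation loss seeds the full run, which stops when validation
loss has not improved for `patience` (default 20) epochs or at `max_epochs`
(default 500), and restores the best-validation checkpoint rather than the
last epoch.  Checkpoint comparison always evaluates validation loss at the
final β so that warm-up epochs are scored on the same objective as later
ones.  All defaults are surfaced in `TrainConfig`; the pre-training counts,
patience and widths are declared defaults, not reconstructions of any
particular published run.  Seeds are split hierarchically (data split /
per-phase weight initialisation / shuffling) so components can be
reproduced independently.

A β-sweep utility trains one model per value over seven evenly spaced β
from 0.625 to 1.  `fit_loss_weights` solves the least-squares problem of
matching the weighted loss components to per-sequence log-likelihood
targets (the importance-sampling estimates below), clipping negative
weights to zero; default component weights are 1.

## Importance sampling (P_VAE)

The marginal P_VAE = p(x) = E_{z∼q(z|x)}[p(x|z) p(z) / q(z|x)] is estimated
with n draws from the encoder distribution.  All densities are evaluated
analytically; the average is computed with a max-shifted log-sum-exp, so a
zero-likelihood draw contributes −∞ cleanly.  The reported standard error
of the log estimate is the delta-method value sd(w)/(√n·mean(w)) on shifted
weights.  Per-sequence seeds derive from (master seed, sequence index),
making batch results independent of evaluation order.  The default is 500
draws; estimates from trained models are already stable near 100 draws
(measured by the stability study below).

## Synthetic recombination simulator

The simulator generates triples as germline-prefix + insertions +
germline-suffix: choose a V segment (with its germline CDR3 prefix) and
trim 0–1 residues from its 3′ end, choose a J segment (suffix, untrimmed in
the default spec), then insert 0–2 residues drawn from an insertion-biased
amino-acid distribution.  Working at the amino-acid level — real V(D)J
recombination trims and inserts nucleotides — keeps the model exactly
enumerable: `exact_pgen` sums the probabilities of every (V-trim, J-trim,
insertion) scenario consistent with an observed string, and
`exact_key_marginal` does the same per (V, J, length) key.  Draws whose
CDR3 length leaves [1, 30] are redrawn, and the enumeration divides by the
corresponding normalising mass, so sampler and oracle always agree.

The default spec uses 4 V and 3 J segments with real TRB gene names and
germline CDR3 parts, so simulated repertoires pass the standard
preprocessing filters.  Its pmfs are deliberately steep (V usage
.3/.3/.2/.2; J usage .4/.35/.25; V trims .85/.15; insertions .5/.35/.15):
one amino acid corresponds to a whole codon, so narrow trim/insertion
ranges cover the bulk of real junctional diversity, and — by a design-time
power analysis of multinomial sampling error — every reachable (V, J,
length) key then carries at least ≈330 expected counts in a 10⁵-sequence
repertoire.  That keeps Monte-Carlo error on frequency-based estimators
(fitted Q factors, key histograms) a few percent, well inside the effect
sizes studied.  The planted selection used in recovery studies applies
factors 2.5 (first V gene, CDR3 ≤ 10) and 0.5 (CDR3 ≥ 13) with q_max 4 —
effect sizes in the range reported for thymic selection.  A richer
`example_spec` (trims 0–2, insertions 0–4) serves the germline-consistency
vignette, which needs a three-insertion sequence to be reachable.

What the simulator does *not* emulate: D genes, nucleotide-level trimming
and insertion statistics, allelic variation, sequencing error, or
amino-acid-composition selection.  Tests passing on this simulator
establish method correctness (estimators converge to enumerable truths),
not biological realism of any fitted model.

## Selection-stack studies

Q factors are fitted with exact provider marginals where available, so the
only stochastic error is the empirical key frequency.  Fitted factors are
identifiable only up to the global normalisation of the selected
distribution; recovery is therefore assessed on Q·Z against the planted
factors, where Z is the planted partition function.  Synthetic studies fit
and resample with q_max = 8 — the truncation never binds (planted factors
≤ 2.5) and the rejection-sampling envelope stays tight; the default q_max
of 100 is intended for real-data scale mismatches.  Keys unseen at fit
time default to Q = 0 (the MLE), with a configurable floor for evaluation
settings that need finite log scores.

## Summary divergences

The divergence report computes 15 statistics: Jensen–Shannon divergence
(natural log) on acidity, aliphatic index, aromaticity, basicity,
bulkiness, CDR3 length, charge, GRAVY, nearest-neighbour Levenshtein,
pairwise Levenshtein, and polarity; ℓ1 divergence on CDR3 2-mer, CDR3
amino-acid, J gene and V gene frequencies.  Numeric summaries are binned
into 30 equal-width bins over the pooled range of the two samples, so the
comparison is symmetric in its arguments; JS values are comparable only
within this binning convention.  Levenshtein statistics subsample each side
to ≤ 2000 sequences (nearest-neighbour distances are then exact on the
subsample; pairwise distances are capped at 50,000 pairs); identical inputs
share one subsample so self-comparison is exactly zero.  Scales: GRAVY =
mean Kyte–Doolittle hydropathy; bulkiness = mean Zimmerman; polarity = mean
Grantham; aliphatic index = Ikai's formula 100·(fA + 2.9 fV + 3.9 (fI+fL));
aromaticity, acidity, basicity = F/W/Y, D/E and K/R/H fractions; charge =
net side-chain charge at pH 7 by Henderson–Hasselbalch with standard pKa
values (no terminal groups, as the CDR3 is an internal loop).

## Preprocessing

ImmunoSEQ-dialect TSVs are parsed with a configurable column map and
filtered in a fixed attribution order: missing fields, out-of-frame,
CDR3 not starting with C, CDR3 not ending with F or YV, CDR3 longer than
30, ambiguous V, ambiguous J, blacklisted J (TCRBJ02-05, TCRBJ02-07).  The
ending rule is ambiguous in prose ("F or YV" endings vs. single residues
F/Y/V); both readings are implemented, defaulting to the {F, YV}-endings
reading, toggleable via `ending_mode="f_y_v"`.  Gene names are canonical in
the Adaptive style with auto-generated IMGT aliases and allele-suffix
stripping.  Cohort counting is at the protein-triple level: each
nucleotide-distinct record contributes 1 and template abundances are
ignored.  The gene registry lists all 13 TRBJ genes (the J one-hot is
13-dimensional) even though two are blacklisted at filtering, so encoded
dimensions match the locus.

## Study sizes and reproducibility

The statistical studies run at deliberately desk-scale sizes: 10⁵ draws
for selection-stack checks, 5,000 training / 500 + 200 held-out sequences
for the VAE studies, 100-sample importance-sampling estimates for
screening.  `scripts/acceptance.py --seed N --out results.json` re-runs
every study from scratch with seeds derived from N and writes the measured
quantities.  All samplers are driven by NumPy `SeedSequence` streams, so
every artifact is bit-reproducible given its seed.

## Known limitations

- The NumPy training loop is single-threaded BLAS-bound; cohort-scale runs
  (10⁶ sequences, hundreds of epochs) are feasible but slow compared to
  GPU-backed implementations.
- The count_match decoder wiring (germline context concatenated to z;
  two-pass generation) is one reasonable realisation of germline
  conditioning; alternatives (e.g. differentiable match counting against
  the decoded V/J distribution) exist and may behave differently.
- Q is keyed by (V, J, length) only; amino-acid-composition selection is
  out of scope.
- The latent-space analysis is limited to linear PCA of encoder means.
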
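# Methods

## Model

`rloopgram` treats each single-molecule R-loop footprint as a word of a
right-linear stochastic grammar with three nonterminals and ten
terminals. The nonterminal `S` generates the DNA-duplex region upstream
of the R-loop, `R` the RNA:DNA-hybrid interior, `Q` the downstream
duplex:

    S -> xS | x alpha R     x in {sigma, sigma-hat, gamma, delta}
    R -> yR | y omega Q     y in {tau, tau-hat, rho, beta}
    Q -> xQ | x             x in {sigma, sigma-hat, gamma, delta}

Hatted symbols mark configurations unlikely to change state (a stable
DNA duplex `sigma-hat`, a stable hybrid `tau-hat`), `gamma`/`rho` mark
k-mers the training data say nothing about, `delta`/`beta` k-mers with
conflicting start/end evidence. `alpha` and `omega` are branch-migration
blocks of length 0..k−1 that absorb the imprecision of experimentally
assigned footprint boundaries; every word carries exactly one of each,
even at length 0. The grammar is unambiguous — each terminal determines
its rule — so a word's derivation is unique, maximum-likelihood fitting
is relative-frequency counting over rule applications, and a word's
probability is the product over its derivation. No EM, smoothing or
flooring is applied by default; a Laplace pseudocount is exposed for
degenerate corpora but defaults to 0, so rules unobserved in training
keep probability zero.

## Coordinates and preprocessing

Internally all intervals are 1-based inclusive `[i, j]` on the
non-template strand read 5'→3'; BED input/output converts at the
boundary, and template-strand FASTA is reverse-complemented on read.
Footprints are preprocessed by (1) promoting each interval of a
multi-R-loop read to an independent record, and (2) rounding each
length to the nearest multiple of k (ties rounded up; a length that
would round to 0 is promoted to k; the new endpoint is clipped to the
gene region, stepping down to the largest valid multiple if needed).
The rounding direction is a convention — the data constrain it only up
to ±k/2 — chosen to minimally perturb the measured footprint. Records
reaching outside the gene region are clipped, not dropped, to preserve
sample size; every clip or rejection is logged. Footprints that leave
less than one full k-block between themselves and a gene-region
boundary admit no derivation (each rule family emits at least one
terminal) and are skipped at word-encoding time with a warning.

## Dictionary construction

For each footprint, sliding windows of width k harvest k-mers from four
regions: r1 = [i−k−p, i−1] and r2 = [i, i+k+p−1] around initiation,
r3 = [j−k−p+1, j] and r4 = [j+1, j+k+p] around termination. The padding
p (default 13, i.e. k+p ≈ 1.5 turns of A-form helix at k=4) absorbs
boundary uncertainty; windows extending past the gene region are
discarded. Each distinct k-mer s gets, per region, the weight
w_i(s) = n_i(s) / (N·m_s), with n_i its occurrence count in region i
across all N training footprints and m_s its overlapping occurrence
count within the gene region of that plasmid (that plasmid only — when
two plasmids are merged, weights are computed per plasmid before the
merge). Weights are exact rationals (`fractions.Fraction`): rank groups
(ties) and the cross-region maxima that drive symbol assignment are
decided by exact comparison, never by floating-point rounding.

Ranked weights are rescaled by the top weight, each rank group
contributes one entropy H = −w′·log10(w′) (one H per distinct weight,
not per k-mer), and the cutoff is the first rank attaining the global
maximum of the running average h_n. The base-10 logarithm is fixed by
the published worked example of this table, which the test suite
reproduces to five decimals. K-mers at ranks up to the cutoff (tied
groups kept whole) form the highly weighted list of the region.

Symbols: for k-mer s let w*_i(s) be its weight where highly weighted
and 0 elsewhere, and w*(s) the maximum over regions. If w*(s)=0 the
k-mer is indeterminate (gamma outside / rho inside). If the maximum is
attained both in a start region {r1, r2} and an end region {r3, r4},
the k-mer is ambiguous (delta/beta). Otherwise a start-region maximum
gives (sigma, tau-hat) and an end-region maximum (sigma-hat, tau). Two
per-plasmid dictionaries merge entry-wise: agreement copies; a
determinate symbol beats gamma/rho; remaining conflicts either collapse
to delta/beta (deterministic mode) or take one parent's symbol
uniformly at random per entry (stochastic mode, seeded).

## Prediction

A candidate R-loop is any interval [i, j] in the gene region [b, e]
with length a multiple of k, i−b ≥ k and e−j ≥ k (the S and Q families
each emit at least one terminal, so a derivable word needs one full
block on each side; alpha/omega absorb the remainders, so i itself is
unrestricted). Each candidate's word probability is normalized over the
candidate set and the per-nucleotide probability q̄_t is the total mass
of candidates covering t; consequently Σ_t q̄_t equals the expected
R-loop length under the word distribution.

Scoring all candidates naively is O(L²/k · L/k); the implementation
instead precomputes per-position log rule probabilities and cumulative
sums over three fixed block grids (upstream blocks anchored at b,
downstream anchored at e, interior blocks per phase class of i mod k),
making scoring O(L²/k). Zero-probability rules produce −inf log terms,
which plain prefix sums cannot subtract; the cumulative arrays
therefore carry a parallel count of −inf entries and any segment
containing one scores −inf. The brute-force per-word scorer is retained
and the test suite asserts agreement below 1e−10 on ~500 nt plasmids.
If every candidate scores zero the distribution falls back to uniform
with a loud warning rather than propagating NaNs.

Ensembles: each of n_models (default 30) rounds draws a 10% subsample
without replacement per plasmid, builds per-plasmid dictionaries,
merges them, encodes the subsample as words, fits rule probabilities
and predicts a track; the reported track is the per-position mean with
SEM = sd/√n_models. All randomness descends from one
`numpy.random.SeedSequence` spawn tree, so runs are bit-reproducible
under a fixed seed.

## Evaluation

The empirical track is holdout coverage divided by holdout size.
Predictions are scored by RMSD and Pearson r over all gene-region
positions (not only covered ones). Hyperparameters are selected by
3-fold cross-validation over the grid k ∈ {3,4,5} × p ∈ {7,13}: folds
partition each dataset into thirds, each fold's ensemble trains on the
other two, and the winning pair minimizes mean RMSD with mean Pearson
as tie-break. The same fold assignment and the same per-fold ensemble
seeds are used for every grid point (common random numbers), so grid
comparisons are paired rather than confounded by subsample draws.
Footprint lengths are re-rounded to each candidate k inside the loop.
The rule-probability report summarizes ensembles per topology with
median/quartiles/1.5·IQR whiskers and pairwise two-sample t-tests with
Bonferroni adjustment.

## Synthetic data

The generator emulates the features of SMRF-seq footprint data that the
grammar learns from: footprints cluster in two positional modes on a
~1.6 kb gene region inside a 2 kb plasmid; initiation sites are
enriched for a small planted set of start-favoring k-mers (standing in
for the G-rich initiation signal of real substrates) and terminations
for a disjoint end-favoring set; lengths are geometric in units of k
with mean ~300 nt; topology is emulated purely as a leftward shift of
the initiation clusters with increasing negative supercoiling, which is
how topology manifests in the footprint data itself. Planted loci sit
on the k-grid anchored at the gene start so start→end spans are
automatically multiples of k; 8 copies of the planted set per cluster
give clear enrichment (planting many more copies would inflate m_s and
push the planted weights toward the sliding-window background level).
The default planted start set {GCGA, AGGT} and end set {CTTC, TCAC}
have pairwise non-overlapping (k−1)-mer content: an identifiability
requirement, since planted 4-mers sharing 3-mers hand the same signal
to a 3-mer dictionary and no cross-validation could then distinguish
tuple sizes. Observed boundaries wander around the true initiation /
termination points by up to ±3 blocks (±12 nt at k=4), emulating the
documented ~15 nt imprecision of footprint boundary assignment — the
very imprecision the sliding-window padding and the alpha/omega blocks
exist to absorb; jitter is quantized to whole blocks so generated
intervals stay k-aligned. Default dataset size is 600 footprints,
matching the scale of the larger real per-condition datasets.

What the generator does not emulate: bisulfite-conversion noise,
base-composition skew of real CpG-island substrates (a GC-skew knob
exists but defaults to 0), plasmid-backbone sequence outside the gene
region beyond uniform background, and any thermodynamic/supercoiling
energetics. Passing parameter-recovery tests therefore demonstrate that
the inference machinery recovers planted statistical structure, not
that real R-loop biology is captured.

A caveat on tuple-size identifiability: even with non-redundant planted
sets and boundary jitter, a 3-mer dictionary trained on the same single
plasmid captures most of the positional signal that drives track
accuracy — any k-mer that happens to sit in a footprint cluster is
enriched in the harvest regions, planted or not — so cross-validation's
preference between k = 3 and the generating k = 4 is weak on synthetic
single-plasmid data. The classification of the planted k-mers
themselves (start set to sigma/tau-hat, end set to sigma-hat/tau) is by
contrast recovered almost always.

## Problem sizes used in tests

Unit and property tests run on 150–600 footprints over 0.3–1.6 kb gene
regions; the exact-equivalence oracle for candidate scoring uses ~500 nt
plasmids where full enumeration is cheap; the cross-validation recovery
experiment uses 600 footprints on the default 1.6 kb region with
5-model ensembles per fold; ensemble-reproducibility checks use the full
30-model protocol. These sizes were chosen so the entire suite exercises
every stage at the default study conditions or modest fractions of them.

## Known limitations

* The grammar models exactly one R-loop per molecule; multi-loop reads
  are split into independent records (9–10% of real reads).
* Candidate enumeration treats the whole gene region as one word, so
  predictions near the region boundaries are constrained by the one-block
  margins.
* With pseudocount 0, a rule absent from a small training subsample
  zeroes every candidate that needs it; the uniform fallback guards the
  degenerate all-zero case only.
* RMSD between a normalized word distribution's track and empirical
  coverage depends on amplitude calibration (the predicted track
  integrates to the expected R-loop length), so model selection by RMSD
  is noisy at small training sizes.
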
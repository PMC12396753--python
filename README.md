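# rloopgram

A probabilistic formal grammar of co-transcriptional R-loop formation.

R-loops are three-stranded nucleic-acid structures — an RNA:DNA hybrid
plus a displaced single DNA strand — that form behind the RNA polymerase
during transcription. Single-molecule R-loop footprinting (SMRF-seq)
yields one interval per detected R-loop per molecule at nucleotide
resolution on a plasmid gene region. `rloopgram` turns such footprint
collections into a trained stochastic grammar and predicts the
probability that each nucleotide of the gene region lies inside an
R-loop, under different starting DNA topologies (linear, supercoiled,
hyper-negatively supercoiled).

## The model

Every footprint `[i, j]` on the non-template strand is tiled into parsing
blocks: k-mers, plus a variable-length `α` block (0..k−1 nt) just before
initiation and an `ω` block just after termination, absorbing the
experimental imprecision of footprint boundaries. A dictionary maps each
k-mer to a terminal symbol by context —

* outside the R-loop: `σ` (unstable DNA duplex), `σ̂` (stable), `γ`
  (indeterminate), `δ` (ambiguous);
* inside: `τ̂` (stable RNA:DNA hybrid), `τ` (unstable), `ρ`
  (indeterminate), `β` (ambiguous)

— so each footprint becomes a word of the right-linear grammar

```
S → σS | σ̂S | γS | δS | σαR | σ̂αR | γαR | δαR
R → τR | τ̂R | ρR | βR | τωQ | τ̂ωQ | ρωQ | βωQ
Q → σQ | σ̂Q | γQ | δQ | σ | σ̂ | γ | δ
```

The dictionary is learned from data: k-mers are harvested with sliding
windows of width k (padded by p extra shifts) from four regions around
each footprint — r1/r2 flanking initiation, r3/r4 flanking termination —
and weighted by `w_i(s) = n_i(s) / (N·m_s)` (region count over training
size times gene-region multiplicity). Ranked weights are cut off at the
global maximum of the running average entropy of the rescaled weights
(`H = −w′·log₁₀ w′`), and the surviving "highly weighted" k-mers are
assigned symbols by where their maximal weight lies (start regions →
σ/τ̂, end regions → σ̂/τ, ties → δ/β, absent → γ/ρ).

Each word has a unique derivation, so rule probabilities are fitted by
relative-frequency counting. The probability of a word is the product of
its rule probabilities (e.g. `ℙ(σατ̂ωσ) = ℙ(S→σαR)·ℙ(R→τ̂ωQ)·ℙ(Q→σ)`),
and the per-nucleotide landscape is

```
q̄_t = Σ_w q_t(w) ℙ̄(w)
```

summed over all candidate R-loop words on the plasmid, with `ℙ̄`
normalized over candidates. Predictions average an ensemble of 30 models,
each trained on a distinct 10% subsample of the training data, with the
standard error of the mean as an uncertainty band. Defaults follow the
protocol the method was developed with: `k=4`, `p=13`, one-third holdout,
30 × 10% subsampled models.

## Worked example

```python
import rloopgram as rg

spec = rg.spec_for_topology("supercoiled", seed=1)   # synthetic dataset
plasmid, footprints = rg.generate_sample(spec)
train, holdout = rg.split_train_holdout(footprints, holdout_frac=1/3, seed=2)

tracks = rg.ensemble_predict(
    {plasmid.name: train}, {plasmid.name: plasmid},
    k=4, p=13, n_models=30, subsample_frac=0.10, seed=3,
)
track = tracks[plasmid.name]
report = rg.compare_tracks(track, rg.empirical_track(holdout, plasmid))
print(f"peak {track.mean.max():.3f}, RMSD {report.rmsd:.4f}, "
      f"Pearson r {report.pearson_r:.4f}")
```

prints

```
peak 0.539, RMSD 0.1554, Pearson r 0.7943
```

i.e. the ensemble-mean landscape peaks at probability 0.54 inside the
planted footprint clusters, and correlates at r ≈ 0.79 with the holdout
coverage — footprints the model never saw. The `examples/` directory
walks through each capability (simulation, dictionary building, word
encoding, prediction, topology comparison, grid selection); run them as
`python examples/04_predict_landscape.py`.

Real data enter through standard formats: plasmid FASTA (template or
non-template strand) and footprint BED, via `rg.read_fasta` /
`rg.read_bed`, or the `rloopgram` command-line interface
(`rloopgram simulate|preprocess|dictionary|train|predict|evaluate|cv`).

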
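# Methods

## Candidate sites

Candidates are position-weight-matrix (PWM) matches. A position frequency
matrix is converted to base-2 log-odds with entry
`log2(((count + c·bg_b) / (colsum + c)) / bg_b)`; the pseudocount `c`
(default 0.8) is split across bases in proportion to the background, which
defaults to genome-wide mononucleotide frequencies. Both strands are
scanned; a reverse-strand match is reported on forward coordinates, and
when both strands pass the threshold at one locus only the higher-scoring
orientation is kept (ties go to `+`). Windows containing non-ACGT bases are
skipped. The scan threshold is either an absolute score, a fraction of the
maximum attainable score (default 0.8), or chosen automatically as the
smallest point on a 100-point grid spanning 50–100% of the maximum score
whose genome-wide hit count falls in a requested range — the operational
form of keeping a few hundred thousand candidates per TF on a mammalian
genome. Candidates are labeled *bound* when a ChIP-seq peak fully contains
the motif interval; `min_overlap` relaxes containment to a coverage
fraction if desired.

## Methylation model

Each candidate gets `2·n_flank + 1` windows: the motif interval itself plus
`n_flank` windows of `window_size` bp tiled without gaps on each side.
Defaults are `window_size = 30`, `n_flank = 10` (21 windows); 30 bp
balances estimation accuracy against spatial resolution, and a 20-bp option
is exposed. Windows clipped at a chromosome end keep their index (as `None`
placeholders when fully clipped) so window-specific parameters stay
aligned.

Within a window, every in-context cytosine covered by at least one read
contributes its methylated and total read counts; `cg_j` counts such
covered positions. The counts are modeled as binomial with a beta prior on
the window methylation level: window-specific `Beta(α_j, β_j)` at bound
sites (capturing the dip), one shared `Beta(α', β')` for background, making
the marginals beta-binomial. Training QC masks windows with fewer than
`min_reads = 5` total reads out of fitting and drops candidates overlapping
CpG islands (island CpGs are constitutively unmethylated regardless of
binding, so they would corrupt the background contrast). QC applies to
training only; prediction scores any candidate.

Estimation is by the method of moments on per-site window proportions
`p̂ = x/n`: with mean `m1` and sample variance `v` (n−1 denominator),
`κ = m1(1−m1)/v − 1`, `α = m1·κ`, `β = (1−m1)·κ`. Degenerate slices are
clamped: `v = 0` pins `κ` at 10⁴ (mean preserved); `v ≥ m1(1−m1)` (more
dispersion than any beta supports) pins `κ` at 0.01; `m1` is clipped to
`[1e-6, 1−1e-6]`. This estimator weights sites equally regardless of
coverage; a coverage-weighted beta-binomial MOM would shrink the small-n
noise but loses the closed form, and with the default coverage (~20 reads)
the difference in fitted window means is negligible. A window with fewer
than two usable bound observations inherits the background parameters with
a logged warning. The background pools all windows of all unbound training
candidates, reflecting the assumption that background methylation is
homogeneous across the layout.

The methylation score is the log-likelihood ratio
`λ = Σ_{j: cg_j>0} [log BB(x_j; n_j, α_j, β_j) − log BB(x_j; n_j, α', β')]`,
computed stably through log-gamma; uncovered windows contribute nothing, so
a site with no methylation data scores exactly 0 (no evidence either way).
CH and 5hmC contexts reuse the identical machinery, fitted independently,
each contributing its own λ feature.

## Features and classifier

Per site: motif log-odds score; λ per available context; mean conservation
over the motif (absent positions count 0, keeping candidate sets aligned);
distance from the motif midpoint to the nearest TSS; midpoint distance to
the nearest other candidate on the same chromosome; binary overlap (≥1 bp,
half-open) with TSS, TES, exon, intron, CpG island, repeat. Distances with
an empty reference set are NaN, which the forest handles natively rather
than by imputation. The ordered feature schema is stored with the model and
enforced at prediction time; optional contexts absent from a dataset are
excluded from the schema, never zero-filled.

The classifier is a random forest (500 trees by default, √p features per
split, unstratified bootstrap; a `--balanced` flag enables class-balanced
subsample weighting). The binding probability is the fraction of trees
voting bound; feature importance is Gini (mean impurity decrease,
normalized to sum 1). The tree count can be selected as the smallest value
on a grid (100, 200, 500, 1000) where the out-of-bag error changes by less
than 0.005 to the next grid point, falling back to the grid maximum with a
warning. Given the data and a seed, training and prediction are fully
deterministic, and a saved model (joblib, versioned payload with schema and
methylation models) reproduces its predictions exactly — this is what makes
cross-sample prediction (train on cell type A, predict on B) a pure
save/load workflow.

## Evaluation

ROC curves group tied scores into single threshold steps and integrate by
the trapezoid rule (equivalent to the Mann–Whitney statistic); average
precision uses the step-function definition without interpolation.
`repeated_split_evaluation` repeats random 50/50 candidate splits through
the full train→predict path and summarizes the AUC distribution.

## Synthetic data

The generator realizes exactly the generative model the fitting stage
assumes, so parameter-recovery tests are well-posed. Defaults (the standard
strong-signal conditions): 500 planted motif instances of a 14-bp consensus
(per-base mutation rate 0.05, random strand) on two 200-kb chromosomes at
700-bp minimum spacing; 30% of sites covered by peaks (motif ± 150 bp;
spacing guarantees a peak never contains a neighboring site, so containment
labeling recovers the truth exactly); CpGs placed uniformly at 0.04/bp with
Poisson(20) coverage; window methylation levels drawn from betas with
concentration κ = 20, means following a linear dip from 0.8 at the flank
ends to 0.2 at the motif for bound sites and 0.85 everywhere else; CpG
islands as separate 500-bp intervals of 0.2/bp CpG density placed clear of
planted sites; TSS/TES/exon/intron/repeat annotations and per-motif
conservation values random and signal-free. The PFM shipped with a bundle
is tallied from the actually planted instances. A null bundle replaces the
dip with the background mean, leaving methylation uninformative.

What the generator does *not* emulate: CpG clustering and sequence
composition, read-level artifacts (bisulfite conversion failure, mapping
bias), correlated methylation between neighboring CpGs beyond the shared
window level, cell-type heterogeneity, and any true signal in the
annotation features. Passing tests therefore demonstrate that the estimator
and classifier recover the model's own structure and discriminate under it
— not that real-genome performance will match.

## Numerical choices and problem sizes

Beta-binomial log-pmfs go through `gammaln`/`betaln`; `n = 0` yields
log-probability 0. The scan scores every window vectorized per column and
is tested against an exhaustive rescoring oracle. Test and acceptance runs
use toy genomes of 40 kb–800 kb with 60–1000 planted sites, chosen so the
statistical checks (dip recovery within 0.05, held-out AUC on strong vs.
null signal) are tight at desk scale; all randomness flows from explicit
seeds via `numpy.random.default_rng`.

## Known limitations

- The MOM estimator ignores coverage heterogeneity (see above); extremely
  uneven coverage would warrant the weighted variant.
- Containment labeling treats a partially overlapped motif as unbound;
  peak-boundary sites are therefore conservatively labeled.
- Thresholding by hit count assumes the score distribution is well covered
  by the 50–100% grid; degenerate PWMs may saturate it (a warning is
  raised).
- No probability calibration is applied to the vote fractions.
- Single-threaded by design for reproducibility; the forest could be
  parallelized at the cost of cross-platform determinism guarantees.
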
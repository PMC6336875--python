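# Methods

## Scoring model

Permissibility is an enrichment contrast between two FACS pools. For
replicate *j* of one inserted domain, with `r(i, j)` productive reads at
insertion slot *i* and `t(j) = Σ_i r(i, j)` the pool total,

    F(i, j) = r_SE(i, j)/t_SE(j) − r_NSE(i, j)/t_NSE(j)          ∈ [−1, 1]

is defined only where both pools have at least one read; other slots are NA
and stay NA through the ladder. `t` is deliberately the total of *productive*
reads (forward orientation, frame 0): that choice makes F a difference of
proper probability vectors, so when no slot is NA the profile sums to zero
exactly — a property the tests assert to 1e-12. The replicate mean
`G(i)` averages over non-NA replicates by default (a slot missing from one
replicate is not dragged toward zero); a strict divide-by-n mode is available
via `mean_profile(..., strict=True)`. Z-scoring uses the sample SD (ddof=1)
over non-NA slots; binarization calls a slot permissive when its value
exceeds 0 — the natural cut for an SE-vs-NSE contrast, since no published
threshold exists. Near-zero trimming drops slots whose value lies in
(−1e-4, +1e-4) in more than a configurable fraction of datasets (NA counts as
in-band); the presets are 6/16 for correlation analyses, 1/2 for property
correlations, and per-profile for model training.

Coordinates: nucleotide positions are 0-based and half-open; `aa_pos =
nt_pos / 3` is the insertion slot, with value *k* meaning "inserted after
residue *k*" (0 = before residue 1). A 435-residue gene has 434 scoreable
slots because the insertion plus its 5-bp duplication must fit upstream of
the stop codon. Ground truth, count tables and feature tables all share this
axis.

## Insertion calling

A domain insertion leaves the variant sequence `cds[:p+5] + cassette +
cds[p:]`: the duplicated 5-mer `cds[p:p+5]` flanks the cassette on both
sides and is assigned to the reference. A junction read is split into a
reference anchor and a cassette anchor, each ≥ `min_anchor` (default 15 nt),
via a hash index of reference k-mers. Maximal anchor extension alone is
ambiguous — flanking bases can coincide with cassette bases — so the split
point is pinned by requiring the cassette segment to align to the cassette's
own terminus (its start for reference→cassette reads, its end for
cassette→reference reads), scanning candidates inside the maximal extension.
Upstream-junction hits give `nt_pos = breakpoint − 5`, downstream hits
`nt_pos = breakpoint`. Reads whose seed k-mer maps to two or more reference
loci are dropped as ambiguous; orientation comes from which cassette strand
matches, and a segment matching both strands is treated as unresolvable.
Matching is exact by default; `max_mismatch > 0` tolerates substitutions
during extension and in the cassette anchor for noisy reads.

Mate pairs that call the same (position, orientation) collapse to one call
(`--pair-policy dedupe`; `drop` discards such pairs instead, covering the
stricter reading of duplicate-call removal), and conflicting mates are
always discarded. Tallying counts only productive calls by default and
reports `t` as their sum.

## Synthetic study design

The generator's defaults define the study conditions:

- **Gene**: 435 random sense codons (ATG start, TAA stop), mirroring the
  scoreable span of the channel scaffold.
- **Site classes** (counts on 434 slots): 140 permissive (p_SE = 0.8 for
  every domain), 185 scaffold (0.05), 40 differential (0.7 for one of the
  first two domains, 0.1 for the other, alternating; 0.4 for any further
  domain), 70 intermediate (0.45). p_SE is the probability that a cell
  carrying a productive insertion at that slot sorts into the SE pool.
  The intermediate default sits away from the pool-weighted mean trafficking
  probability (≈ 0.39) so that borderline sites do not flip bits under
  binomial noise at the default library size.
- **Library**: 10⁶ transposition events over all (position, orientation)
  pairs, positions weighted `w(p) = 1 − b·exp(−p/λ)` with b = 0.8,
  λ = 150 nt — a 5'-depressed coverage profile of the kind transposases
  produce. Orientation is uniform; exactly 1/6 of variants are productive in
  expectation.
- **Sorting/sequencing**: library counts act as cell counts; each productive
  cell is Bernoulli-sorted by its p_SE, and each pool is sequenced to a
  fixed depth of 2×10⁵ reads drawn multinomially over its cells, in
  triplicate.
- **Reads**: one error-free 100-nt pair per library count unit, R1 across
  the upstream junction, R2 reverse-complemented across the downstream one;
  read ids embed the truth for oracle tests. Errors, when enabled, are
  substitution-only.
- **Features**: 5 static + 21 conservation + 20 dynamic properties. Static
  and conservation features are unit Gaussian noise; dynamic features carry
  a mean shift of `effect_size · 2(p̄_SE − 0.5)` SD, i.e. flexibility tracks
  trafficking propensity continuously. Only the dynamic category is
  informative by construction.
- **Flow events**: the dye channel is a two-component log-normal mixture
  (hyperpolarized ≈ LN(log 120, 0.45), depolarized ≈ LN(log 1200, 0.45));
  the hyperpolarized weight is `activity · (1 + light_shift) · g(K⁺)` with
  `g(k) = 1/(1 + k/15 mM)` decreasing in external K⁺. Photobleaching
  multiplies all raw intensities by `exp(−bleach_rate · t_acq)`. Scatter and
  marker channels are fixed log-normals; event tables are plain TSV in
  arbitrary units, with no cytometer file dialect emulated.

What the generator does **not** emulate: PCR/amplification bias, indel
errors, position-dependent sequencing quality, antibiotic-selection
bottlenecks, phenotypes of out-of-frame insertions, spectral spillover, or
day effects between flow replicates. Passing tests therefore demonstrate
correctness of the analysis on an idealized sampling model, not robustness
to those real-data artifacts.

## Differential analysis choices

The Hamming criterion at a single site reduces to XOR on jointly non-NA
bits; NA in either profile excludes the site from both numerator and
denominator. Correlation matrices replace NA with 0 before correlating
(pairwise-complete mode available) so undersampled slots add noise rather
than deleting rows; clustering is average linkage on 1 − r (no linkage is
canonical for this analysis, and average linkage is robust to the tight
duplicate clusters these matrices contain). The moving average uses a
centered window of 15 slots, drops values below 8 contributors (ends and NA
runs), and thresholds at 1 sample SD of the *smoothed* series, one-sided by
default to match positive-excursion region shading; both the SD source and
sidedness are flags. Rank-sum comparisons use the exact Mann–Whitney null
for tie-free samples of ≤ 8 per group and the tie-corrected normal
approximation (no continuity correction) otherwise.

## Models

Trees are CART with Gini impurity, depth ≤ 4 and ≥ 5 samples per leaf,
via scikit-learn; determinism comes from a fixed `random_state` rather than
an explicit split tie-break rule, so feature-column order can alter
individual tie-broken splits without materially changing accuracy (the
suite bounds the effect). Cross-validation is stratified 10-fold with a
mandatory seed; out-of-fold probabilities are pooled into one ROC (trapezoid
AUC) plus precision/recall/accuracy-vs-cutoff curves, and importances are
normalized total impurity decreases. "Cross-validated 10 times" is read as
10-fold CV. With 20 equally informative dynamic features, a model reduced to
the top 4 importance-ranked features slightly *outperforms* the full model
(variance reduction); the suite asserts that the reduced model retains the
signal rather than that the full model dominates.

## Flow statistics

"Most hyperpolarized" means lowest DiBAC fluorescence (the anionic dye
partitions into depolarized membranes). The function score gates variants at
the wild-type median after arcsinh transform (cofactor 150, a common
cytometry default; the transform is specified but no cofactor is published).
The light/dark dissimilarity builds its gate at the 15 % quantile of the
dark sample, cross-tabulates in/out × dark/light, and uses the Pearson
chi-squared statistic without continuity correction. The photobleaching
normalization is not published; the default here is Χ²/N per K⁺ challenge
(scale removal, so proportionally larger acquisitions do not inflate the
statistic), with optional division by a matched wild-type value — both are
reported by `normalize_and_average`. Dunnett's many-to-one test uses the
equicorrelated multivariate-t distribution (scipy), with a pooled-variance
Bonferroni fallback that is conservative by construction.

## Problem sizes and determinism

Every simulation is bitwise-reproducible given its config and seed
(numpy `default_rng` with explicit seed sequences). Test and acceptance
problem sizes — 10⁴ read pairs for the caller oracle, 2×10⁵ reads/pool ×
3 replicates × 2 domains for scoring and differential recovery, 50 tree
fits and 100 label permutations for the model properties, 2000 null draws
of 2000 events for chi-squared calibration — were chosen so the full suite
exercises every stage at meaningful scale while remaining quick to run on a
single CPU.
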
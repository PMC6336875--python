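# dipscan

Differential domain-insertion profiling (dDIP-seq) analysis: from junction
reads of a transposon-generated domain-insertion library to per-site
permissibility scores, differential-permissibility statistics, decision-tree
permissibility models, and flow-cytometry function / light-modulation
statistics.

## The problem

Domain insertion profiling asks, for every position *i* of a host protein
(here an inward-rectifier K⁺ channel scaffold), whether an in-frame inserted
domain is tolerated — whether the fusion still folds and traffics to the cell
surface. A MuA transposase places a cassette at quasi-random positions
(leaving a 5-bp target-site duplication; only 1 of 6 insertion frames is
productive), FACS separates surface-expressed (SE) from non-surface-expressed
(NSE) cells, and sequencing of both pools reads out each insertion site's
fate. Comparing permissibility maps obtained with *different* inserted
domains ("differential permissibility") highlights conformationally flexible,
allosterically capable regions.

For replicate *j*, position-wise permissibility is the difference of pool
read fractions

    F(i, j) = r_SE(i, j) / t_SE(j) − r_NSE(i, j) / t_NSE(j),

defined only where both pools have reads at *i* (NA otherwise), with *t* the
pool's total productive read count. Replicates average into
G(i) = mean_j F(i, j), which is z-scored, trimmed of near-zero positions
(|G| < 1e-4 in too many datasets) and binarized (1 = permissive) for:

- Pearson dataset/position correlation matrices (NA → 0) with
  average-linkage clustering;
- differential-site calls — bit disagreement (Hamming criterion) between two
  domains' binary profiles, Euclidean distance on z-profiles, and a window-15
  moving average of the z-score difference whose > 1 SD excursions mark
  differentially permissible regions;
- depth-4 CART models predicting binary permissibility from residue-level
  protein properties (static / conservation / dynamic categories), with
  stratified 10-fold cross-validation, ROC/PR curves and feature withholding;
- flow-cytometry statistics: the lower-50 %-of-wild-type gate for percent
  hyperpolarized cells (channel function), one-sided Welch t tests, and the
  light/dark chi-squared dissimilarity on a 15 %-most-hyperpolarized gate,
  normalized per event count and compared against wild type with Dunnett's
  many-to-one test.

Because the original study's raw sequencing data live in an archive, the
package ships a first-class synthetic-data module that generates every input
with known ground truth — reference gene, insertion library with 5'-depressed
MuA bias, sorted-pool counts, junction FASTQ reads, property tables, and
DiBAC-style flow events — so every stage is testable end to end.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
import dipscan as d

ref = d.make_reference(435, seed=1)
domains = d.default_domains()                   # PDZ- and Cib81-sized stand-ins
config = d.SimulationConfig(seed=1, domains=domains)
truth = d.simulate_truth(ref, domains, seed=1)
library = d.simulate_library(ref, config)

means = {}
for dom in ("PDZ", "Cib81"):
    profiles = []
    for rep in (1, 2, 3):
        se, nse = d.simulate_sort_counts(library, truth, dom, config, rep)
        profiles.append(d.enrichment(se, nse))
    means[dom] = d.mean_profile(profiles)

g = means["PDZ"].values
p_true = np.array([s.p_se["PDZ"] for s in truth])
ok = ~np.isnan(g)
print(f"PDZ: {ok.sum()}/{len(truth)} positions scored, "
      f"Spearman(G, p_se) = {spearmanr(g[ok], p_true[ok]).statistic:.3f}")

calls = d.hamming_differential(d.binarize(means["PDZ"]),
                               d.binarize(means["Cib81"]))
print(f"differential sites: {calls.n_diff}/{calls.n_compared} ({calls.percent})")

labels = d.truth_labels(truth)
feats = d.simulate_features(truth, effect_size=1.0, seed=1)
report = d.cross_validate(feats, labels, k=10, seed=0)
print(f"10-fold CV AUC = {report.auc:.3f}, top feature = {report.top_features[0][0]}")
```

prints

```
PDZ: 434/434 positions scored, Spearman(G, p_se) = 0.929
differential sites: 40/434 (9%)
10-fold CV AUC = 0.834, top feature = mode_19
```

The mean profile tracks the configured trafficking probabilities (ρ = 0.93 at
the default depth of 2×10⁵ reads per pool), the Hamming criterion recovers
exactly the 40 ground-truth differential sites, and the tree model ranks a
dynamic feature (a normal-mode stand-in) first — the behaviour expected when
only dynamic properties carry signal.

The same stages are scriptable from a shell:

```sh
dipscan simulate --outdir study --seed 1
dipscan call --reference study/reference.fa --cassette study/cassette_PDZ.fa \
    --r1 study/reads_R1.fastq --r2 study/reads_R2.fastq \
    --out-calls calls.tsv --out-counts counts.tsv
dipscan score --se study/counts_PDZ_r1_SE.tsv --nse study/counts_PDZ_r1_NSE.tsv \
    --stage binarize --out pdz_bin.tsv
dipscan diff --a pdz_bin.tsv --b cib_bin.tsv --metric hamming
```

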
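# tempopool

Temporal pool-seq population genomics: what changed in a natural population
between two samplings decades apart, and was it drift or selection?

`tempopool` re-implements, as a tested and reusable pipeline, the analysis
stack needed to compare an old panel of individually sequenced isofemale
strains against modern pooled seasonal samples of the same *Drosophila*
population (~500 generations apart):

* **Pool-seq sampling theory** — how many distinct chromosomes underlie
  `n_r` reads from a pool of `n_e` equally contributing diploids?
  `P(j | n_r, n_c) = n_c!/(n_c−j)! · S(n_r, j) / n_c^{n_r}` with `S` the
  Stirling numbers of the second kind and `n_c = 2 n_e`; plus Kish effective
  sample sizes `(Σw)²/Σw²` for weighted samples.
* **Inversion frequencies** from marker SNPs fixed between arrangements, with
  seasonal/spatial difference tests against a dual-binomial resampling null
  (`chr_inv ~ Binom(n_e, f)`, then `reads ~ Binom(cov_j, chr_inv/n_e)`).
* **Local effective population size** by fitting the dispersion of observed
  allele-frequency change to Wright–Fisher simulations
  (`f_{i+1} = Binom(2N, f_i)/2N`) over a grid of `N`, replaying both the
  individual- and read-sampling layers of the data.
* **Exact-match rejection ABC** for the selection coefficient and initial
  frequency of a focal allele: draw `s ~ U(0, 0.3)`, `f0 ~ U(0, 0.2)`,
  simulate genic selection (`f* = f(1+s)/(1+fs)`), and accept only draws
  whose simulated sampled counts match the observed counts exactly in every
  sampling year. MAP at 0.1-percentage-point bins, central 95% CIs.
* **PBS selection scan** over diversity-scaled windows (200 non-singleton
  track SNPs each): `PBS = (T_of + T_os − T_fs)/2` with `T = −log(1 − F_ST)`
  (Hudson-type `F_ST` with effective allele counts), inversion-reweighted
  focal frequencies, per-recombination-bin empirical p-values `(k+1)/(M+1)`,
  Bonferroni flags, outlier-region delimitation, enrichment-removal
  accounting, and pseudo-pool cross-confirmation of SNP-level outliers.
* **Permutation category enrichment** of window outliers (regions merged
  across gaps of ≤4 windows, placements permuted within arms, each region
  counted once per category, analysis-wide threshold from per-permutation
  minimum p).
* **Clinal-SNP shift testing** (one SNP per 10 kb, one-sided binomial test of
  northern-allele increases), inversion-matched ancestry reweighting, and
  coverage-ratio CNV genotyping `f = (r_pool − r_del)/(r_int − r_del)`.
* **IBD QC** of the strain panel (500-kb windows, 100-kb steps, <0.0005
  differences/site; recurrent regions extend but never seed tracts; pairs
  with tracts >5 Mb flagged and one member masked).
* A **synthetic-data generator** that emulates every input with fully known
  ground truth, so each stage is testable without any external data.

## Worked example

Estimate the pooled frequency of an intact (two-paralog) allele at a deletion
locus from depth-of-coverage ratios, then infer the selection strength needed
to explain its rise across six sampling years:

```python
import pandas as pd
from tempopool.cline import CNVCoverageProfile, cnv_frequency_pool
from tempopool.wf import ExactMatchABC

f = cnv_frequency_pool(CNVCoverageProfile(r_pool=0.646, r_intact=1.2,
                                          r_deleted=0.0676))
print(f"pooled intact-allele frequency: {f:.4f}")

counts = pd.DataFrame({"year": [1975, 1977, 1979, 1980, 1981, 1983],
                       "n": [30] * 6, "k": [0, 3, 12, 17, 21, 26]})
res = ExactMatchABC(counts, gens_per_year=15, n_e=9500).fit(n_accept=5000,
                                                            seed=1)
print(res.summary())
```

prints

```
pooled intact-allele frequency: 0.5108
Exact-match rejection ABC (Wright-Fisher, genic selection)
==========================================================
acceptances        : 5000 (target 5000)
simulations run    : 4800000
selection s  MAP   : 4.55%  (95% CI 3.39-6.37%)
initial freq MAP   : 3.25%  (95% CI 1.03-8.49%)
```

The first number inverts the linear coverage mixture
`r_pool = f·r_intact + (1−f)·r_deleted`: a pooled focal/genome-wide depth
ratio of 0.646, between the calibration ratios of intact (1.2) and deleted
(0.0676) haplotypes, implies the intact allele is at 51.08% frequency. The
ABC summary says that, for these (synthetic) yearly counts of 30 sampled
chromosomes, only simulations with a selective advantage around 4–5% per
generation and a starting frequency of a few percent reproduce the counts
exactly — drift alone does not.

An end-to-end synthetic run (simulate → inversions → Ne fit → PBS scan →
enrichment → clinal test → CNV/ABC) with all report tables:

```bash
tempopool run --seed 1 --out demo_run
```

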
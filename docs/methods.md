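# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `tempopool`. It describes what the code computes and under
which assumptions; every empirical number referenced here is produced by the
test suite or the acceptance script at run time.

## The two-epoch sampling model

The package treats a temporal study as two observations of one
Wright–Fisher population:

* **Epoch 1** — a panel of isofemale strains, each founded from one wild
  female and maintained in the laboratory since. Each strain exposes either
  one chromosome copy (inbred tract, haploid call) or two (residually
  heterozygous tract, diploid call). New laboratory mutations are not
  modelled: at laboratory population sizes the chance that the same new
  mutation is sampled in more than one strain is negligible, so strain
  panels are treated as frozen draws from the source population.
* **Epoch 2** — pooled sequencing of wild-caught flies, in several pools per
  season (fall and spring) across nearby trap locations. A pool with
  effective size `n_e` (equally contributing diploids) observed at coverage
  `cov` yields counts through two binomial layers: chromosomes into the pool,
  `ψ ~ Binom(2 n_e, f)`, then reads from those chromosomes,
  `φ ~ Binom(cov, ψ / 2 n_e)`. Seasonal frequencies combine pools weighted
  by `n_e`.

Between the epochs the allele frequency evolves by per-generation binomial
reproduction, `f_{i+1} = Binom(2N, f*_i)/2N`, where
`f*_i = f_i (1+s)/(1 + f_i s)` applies genic selection (relative fitness
`1 + s` for the focal allele; `s = 0` reduces to pure drift). The calendar
maps to generations at 15 per year, so 31 years between samplings is 465
generations. A diploid-additive selection mode is not separately implemented;
genic selection is the haploid-equivalent of additive selection at the
allele level and is the model used throughout.

## Effective numbers of sampled alleles (pool.py)

Reads are not independent draws from the population because few distinct
chromosomes may underlie them. The number of distinct lineages `j` among
`n_r` reads from `n_c` chromosomes follows the occupancy law
`P(j) = n_c!/(n_c−j)! · S(n_r, j)/n_c^{n_r}` (Stirling numbers of the second
kind); `E[j]` is the effective chromosomal sample size at a site. Diploid
pools use `n_c = 2 n_e`.

Numerics: `S(n_r, j)` overflows doubles long before realistic coverages
(171! is already past the double range), so the row `S(n_r, ·)` is built by
the exact big-integer recurrence up to `n_r = 200` and in log space
(logaddexp recurrence, then normalized exponentials) above. Normalization
holds to 1e-12 in both branches; the two routes and a Monte-Carlo occupancy
oracle agree in the tests.

Weighted samples use the Kish effective size `(Σw)²/Σw²`: it equals the
number of observations iff weights are equal, and is the sample size passed
to the F_ST estimator after inversion reweighting.

The pseudo-pool construction turns the panel into an in-silico pool to place
both data types on one footing: every strain's reads are Bernoulli-thinned to
the shallowest strain's total (binomial per-site coverage, hypergeometric
allocation of allele reads), then summed.

## Inversion frequencies and resampling tests (inversions.py)

Pool inversion frequencies are the unweighted mean of inverted-allele
frequencies across marker SNPs (fixed differences between arrangements) with
coverage ≥10 reads; markers below the cutoff are dropped, and a pool with no
passing marker is missing, not zero. Strains are karyotyped by majority rule
over marker calls (mostly-heterozygous → inversion heterozygote,
mostly-homozygous-standard → standard; ties are excluded with a warning), and
the panel frequency is heterozygotes/(2 × strains). Carriers are simulated
as heterozygotes only, matching what isofemale panels show; a homozygote
mode exists as a generator flag.

The seasonal difference test replays sampling under a null in which both
seasons share the midpoint of the two seasonal point estimates: per pool,
`chr_inv ~ Binom(n_units, f_mid)`, then per passing marker
`reads ~ Binom(cov_j, chr_inv/n_units)`; seasonal estimates are recomputed
per replicate and the two-sided p-value is the fraction of replicates with
|simulated difference| ≥ |observed|. `n_units` defaults to `n_e` — the
literal notation of the published resampling scheme — with a `2 n_e` switch
(`n_units_diploid=True`) because the diploid reading is equally defensible;
the default is the literal one. The location test uses the largest pairwise
difference among per-location estimates as its statistic and an `n_e`-weighted
common frequency as the null (the midpoint rule is inherently two-group).

Calibration: under a single-frequency null generator the seasonal p-values
are uniform (KS < 0.05 over 1,000 datasets × 1,000 replicates in the
acceptance suite).

## Local N_e grid fit (wf.py)

`EffectiveSizeGridModel` matches the dispersion of observed frequency change
between epochs against simulations on a grid of `N`. For each grid value,
start frequencies are resampled from the observed epoch-1 spectrum (so the
simulated SFS matches the data at the first time point), propagated the
stated number of generations, and pushed through the same pool-sampling
scheme as the data; when `old_sample_size` is given the epoch-1 binomial
sampling noise is replayed too. This symmetry matters: without it the fit
absorbs the old-sample noise into drift and is biased low by roughly 25% at
panel-scale sample sizes.

The summary statistic is the mean absolute frequency change by default, with
the standard deviation as an alternative (`statistic="sd"`); which of the two
the original analysis matched is ambiguous from the published wording, so
both are provided and neither is asserted as canonical. The fit returns the
full profile; the profile is monotone decreasing in `N` on well-behaved
data, so the argmin of |simulated − observed| is well defined. Parameter
recovery: a planted `N = 10,000` at 465 generations and 5,000 SNPs is
recovered within a factor of 1.25 on a 5%-spaced grid (acceptance suite).

## Exact-match ABC (wf.py)

`ExactMatchABC` targets the posterior of `(s, f0)` given yearly counts
`(n_y, k_y)` of a focal allele, under priors `s ~ U(0, 0.3)` and
`f0 ~ U(0, 0.2)`, a fixed population size (default `N = 9,500`, the local
estimate; the size used originally is not stated), 15 generations per year,
and sampling years placed at their calendar generations with the first at
generation 0. A draw is accepted only if `Binom(n_y, f_{g(y)})` reproduces
`k_y` exactly for every sampling year. MAP estimates are univariate modes in
0.001-wide bins; intervals are central 2.5/97.5% quantiles.

Two samplers draw from this posterior:

* `method="literal"` — simulate the counts and reject on any mismatch.
* `method="thinned"` (default) — at each sampling year, keep a surviving
  trajectory with probability `pmf(k_y; n_y, f) / pmf(k_y; n_y, k_y/n_y)`.
  The denominator is the maximum of the binomial pmf over the success
  probability, so this is rejection sampling with a valid envelope: the
  accepted `(s, f0)` have density proportional to
  `prior × E[∏_y pmf(k_y; n_y, f_y)]`, exactly the exact-match posterior,
  while the acceptance rate improves by the constant `1/∏_y max pmf`
  (roughly four orders of magnitude for six years of 30 chromosomes). The
  two samplers agree by a two-sample KS test in the suite.

Degenerate inputs: a year with `n = 0` matches everything (useful for
verifying that unconditional acceptance returns the prior); an observation
that is essentially unreachable under the prior aborts with a diagnostic
once a simulation budget is exhausted rather than looping forever.

A note on coverage: the credible intervals are Bayesian. Their frequentist
coverage at a fixed truth near the edge of the plausible-data range (for
example `f0 = 0.05` with 30-chromosome yearly samples) sits near, not above,
90% for the joint event that both intervals cover — e.g.
`P(k_0 ≥ 5 | n=30, f0=0.05) ≈ 2%` already exhausts one tail. The coverage
test in the acceptance suite runs 10 generator replicates at 1,200
acceptances each; larger designs hover around the 90% line for this reason,
not because of a sampler defect.

## The PBS scan (scan.py)

Differentiation specific to the old lineage is measured as
`PBS = (T_of + T_os − T_fs)/2`, `T = −log(1 − F_ST)`, with o = old panel,
f = fall, s = spring. Placing the two seasonal samples on the non-focal
branches keeps seasonally oscillating SNPs from inflating the focal branch.

* **F_ST** is Hudson-type with sample-size-corrected heterozygosity,
  `num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`,
  `den = p1(1−p2) + p2(1−p1)`, where the `n` are effective allele counts
  (Kish for the reweighted panel, summed expected lineages for pools).
  Negative values clamp to 0 and values at 1 clamp to `1 − 1e−6` before the
  log transform. SNPs monomorphic in both samples of a pair are excluded.
* **Window PBS** uses the ratio of summed numerators to summed denominators
  across a window's SNPs (the standard low-bias window estimator), then the
  T-transform; max-SNP PBS is the largest per-SNP PBS inside.
* **Windows** are diversity-scaled: consecutive blocks of 200 non-singleton
  SNPs from a reference diversity track, tiling each arm without overlap
  (each window ends at its last track SNP; a short trailing block is
  dropped). Coordinates are 1-based inclusive; BED exports convert.
* **Inversion reweighting**: each panel chromosome copy is weighted
  `f_target/f_panel` (inverted) or `(1−f_target)/(1−f_panel)` (standard),
  multiplied across co-located inversions, so the old sample matches the
  pooled inversion frequencies; per-SNP effective allele counts are the Kish
  size of the contributing weights. The generator phases carrier haplotypes,
  so tagging SNPs move exactly to the target frequency; a panel fixed for an
  arrangement cannot be reweighted and raises an error.
* **Empirical p-values** per recombination bin — (0.5,1], (1,1.5], (1.5,2],
  (2,3], (3,∞) cM/Mb; windows below 0.5 cM/Mb are excluded — use
  `p = (k+1)/(M+1)` with `k` the simulated values strictly greater; at
  `M = 2.5` million this reproduces a 4e-7 floor. The packaged null is a
  Wright–Fisher stand-in (drift + the sampling layers, no linkage or
  demography) intended for testing; a production scan should supply
  externally simulated nulls per bin, for which `NullDistribution` is the
  container. Bonferroni significance is `0.05/(number of windows)`.
* **Outlier regions** seed at windows with `p < 0.05` (the published rule
  says only "a low P value"; the threshold is configurable) and extend until
  ten consecutive windows with `p > 0.1`, with edges resting on qualifying
  windows; overlapping regions merge, and re-calling called output is a
  no-op.
* **Enrichment removal** excises regions until the p∈[0, 0.05) bin holds no
  more windows than p∈[0.05, 0.1], either deterministically (lowest-p region
  first) or by random seed choice averaged over repetitions; with a
  pseudo-pool confirmation table, a removed region only counts if its seed
  window is a top-5% outlier there. In the planted-truth experiment (1,200
  windows, 20 planted six-window sweeps) the deterministic count lands
  within ±5 of 20 on average; bin-count noise makes a few extra single-window
  removals unavoidable, which is why the assertion is on the replicate mean.
* **SNP-outlier confirmation** reports windows whose max-SNP PBS is in the
  top 1% of the primary scan and top 2.5% of the pseudo-pool scan while the
  window PBS stays in the bottom 95%; all quantile thresholds are inclusive
  at the boundary.

## Category enrichment (enrichment.py)

Outliers are the top 1% of window PBS. Outlier windows separated by at most
four non-outlier windows merge into one region; regions are then placed
uniformly at random over window starts within their own arm, preserving
lengths (inter-region spacing is not preserved — the published description
does not specify it, and independent placement is the simpler null). A
region counts at most once per category in both observed and permuted data,
so paralog clusters cannot double-count. Raw p is the fraction of
permutations with at least the observed count (reported no smaller than
1/n_perm); the analysis-wide threshold is the 5th percentile of each
permutation's own minimum raw p across categories. Desk-scale default is
10,000 permutations (configurable; the original analysis used 10⁶).

## Clinal SNPs, ancestry, CNV (cline.py)

Clinal SNPs with clinal p strictly below 0.001 are thinned to one per 10 kb
by a greedy left-to-right scan per arm (a most-significant-first mode exists
behind `order="significance"`). The shift test reports the mean change of
the northern allele, the count of increases (zero shifts excluded from the
tally — a strict ">0 increased" reading), and the one-sided binomial tail
at a 50% null. Being an exact discrete test its null p-values are
conservative rather than exactly uniform; the suite checks size control.

Ancestry reweighting applies the same copy weights as the scan at the strain
level (a carrier's weight is the mean of its inverted and standard copy
weights) and returns the weighted mean ancestry; the relative decline
between epochs is `(old − new)/old`.

CNV genotyping classifies strains by their focal/genome-wide coverage ratio
at the log-scale midpoint `sqrt(r_intact · r_deleted)` of the calibration
ratios (≈0.285 for 1.2 and 0.0676 — the two modes differ ~20-fold, so the
boundary placement is uncritical); an optional log10 band flags ambiguous
ratios as uncalled. The pooled intact-allele frequency inverts the linear
mixture `r_pool = f·r_intact + (1−f)·r_deleted`, clamped to [0, 1]; the
inversion is exact (round-trip identity to 1e-12). Per-collection-year count
tables feed the ABC directly.

## IBD QC (ibd.py)

Pairs of genome call tracks are compared in 500-kb windows sliding by
100 kb; a window qualifies when its per-site difference rate over jointly
callable sites (missing calls excluded from the denominator — heterozygosity
masks create missingness) is below 0.0005 and at least 100 sites are
callable. Qualifying windows chain into tracts; tracts lying entirely inside
user-supplied recurrent-IBD intervals never seed (they are dropped unless a
non-recurrent window participates), but a tract seeded outside may extend
through them. A pair with any tract over 5 Mb is flagged related and one
member is masked — the lower-coverage genome when coverages are supplied,
otherwise the second member. The scan is symmetric up to which member is
masked, and adding differences can only shrink IBD.

## Synthetic data (synthetic.py)

`SimWorld` declares the full latent state: arms, SNP count, ancestral
frequencies (default: log-uniform on [0.02, 0.98], a heavy-at-rare stand-in
for a neutral SFS), selected loci, inversions with per-epoch frequencies and
marker positions, a CNV locus with per-year intact frequencies, clinal
annotations, and the pool layout. Defaults mirror the study conditions:
465 generations between epochs (31 years × 15), 64 strains with 32.6%
residual heterozygosity in geometric tracts of mean 500 kb (heterozygosity
blocks, as an HMM would emit, rather than site-wise noise), six fall pools
(41 flies, `n_e` 41 for the five single-location pools and 10 for the
mixed-family pool) and twelve spring pools (34 flies, `n_e` 31), fall/spring
mean coverages 64×/16×, and a clinal northern-allele shift of 2.44% applied
on top of drift to a ~3% clinal subset. Pools are drawn by the dual binomial
scheme, with all markers of one inversion sharing the pool's drawn count of
inverted chromosomes so marker frequencies are correlated within a pool as
in real data.

What the generator does **not** emulate: linkage disequilibrium between
ordinary SNPs (sites are exchangeable given their frequencies; only
inversion markers are correlated), read-level artefacts (mapping error,
base-quality), demography beyond a single panmictic deme, and spatial
structure among trap locations. Tests passing on this generator therefore
validate the estimators' sampling theory and bookkeeping, not robustness to
linkage or demographic misspecification — which is precisely why the null
distribution for the scan is pluggable.

Determinism: a `SimWorld` seed fixes every array bit-for-bit; the pipeline
derives one recorded sub-seed per stage from the global seed by hashing, so
stages can be rerun independently and identically.

## Problem sizes

Default test and acceptance runs use: 2,000–5,000 SNPs per dataset, grids of
~40 `N` values at 5% spacing, 1,000 null datasets × 1,000 replicates for
resampling calibration, 1,200-window planted-sweep scans, 10 ABC coverage
replicates at 1,200 acceptances, and 10⁴ permutations for enrichment. These
sizes are the package's desk-scale choices; every routine accepts larger
values unchanged.
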
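# Methods

## Model

`rohmap` scores a run of homozygosity (ROH) by the population frequency of
the haplotype spanning it.  Let `G_1 … G_n` be the SNPs of the region and
`g_i` the homozygous allele at `G_i`.  Writing `P(g_{i-1}, g_i)` for the
two-locus haplotype frequency of adjacent markers and `P(g_i)` for the
allele frequency, the region haplotype frequency is the first-order Markov
chain

    HF = P(g_1) · ∏_{i=2..n} P(g_{i-1}, g_i) / P(g_{i-1})

and the probability of carrying the region homozygous by chance is
`HBC_s = HF²`.  The model assumptions are:

* **First-order dependence.**  LD beyond adjacent markers enters only
  through the chain.  For long *common* haplotypes (population copying
  structure) the chain underestimates the true frequency, increasingly so
  with region length.  Both case regions and the Monte-Carlo null carry
  this bias, which is why significance is assessed empirically rather than
  nominally.
* **No genotyping-error model.**  Heterozygous exceptions inside an ROH are
  budgeted by the run caller, not modelled probabilistically.
* **Case and controls from one population.**  All frequencies come from an
  unaffected control panel; population mismatch shifts the null.

### Estimation details

* Two-locus frequencies are estimated by EM from unphased control
  genotypes.  Only double heterozygotes are phase-ambiguous; the update
  splits them by `p_AB·p_ab / (p_AB·p_ab + p_Ab·p_aB)`.  Initialization is
  at linkage equilibrium, convergence at max absolute frequency change
  `1e-8`, cap 1000 iterations, no random restarts (the two-locus likelihood
  is well behaved).  Haplotypes incompatible with every observed genotype
  are exact structural zeros.
* A required transition with frequency zero is replaced by the
  rare-haplotype surrogate `K` with `(1 − K)^{2v} = 0.95`, where `v` is the
  number of pairwise-complete control individuals for that pair; the pair's
  other three frequencies are rescaled by `(1 − K)` so they still sum to
  one.  The criterion reads the control sample as `2v` haplotypes; a
  `v`-haplotype reading is available (`haploid_factor=1`).
* The chain is evaluated in log space; underflow of `HF` itself is normal
  for long regions and all comparisons use `−log₁₀`.  The denominator of
  each factor is the left marginal of that pair's (K-adjusted) table, which
  makes `log HF` exactly additive when a region is split at an interior
  marker.  Heterozygous exceptions and missing calls inside a region are
  marginalized by composing the adjacent transition matrices across the
  gap; if a composed transition is zero it is floored at `K` for the
  smallest `v` in the gap.

### Run calling

Maximal homozygous runs with a budget of heterozygous exceptions
(default 0) and missing calls (default 2), minimum 25 SNPs (at least 2 is
required by the chain).  Windows grow left and right to a fixed point, so
extending any reported region violates a budget or a chromosome end.  No
HMM: the discriminating statistic is HF, not the run caller.

### Sharing statistics

For a consensus interval carried homozygous, with identical alleles, by
`N` of `T` patients, `HBC_m` is the Binomial(`T`, `p`) upper tail at `N`
with `p` the consensus-interval `HF²` (all carriers share the consensus
alleles, so their interval `HF²` coincide).  `N = T = 1` reduces to
`HBC_s`.  Regions are compared on `−log₁₀ HBC_m`; for carrier counts the
multi-patient mode considers `min(2, N) ≤ carriers ≤ N`.  Single-carrier
regions are excluded when `N ≥ 2` because their `−log HBC_m` scale is not
comparable with genuine consensus regions (a long chance ROH in one
individual can dominate every sharing signal; see "Design choices").

Affected sib pairs: within-family homogeneity is assumed, each family
contributes the smaller `HF²` of its two genotyped affected siblings, and
the final P-value is multiplied by `(1/4)^N` — the chance that `N` sib
pairs each share both alleles identical by descent.  Only two-sib families
are supported.

### Empirical significance

* **Single patient** — one statistic per control: the genome-wide smallest
  `HF²` over that control's ROH (sentinel 1.0 when a control has none).
  Each control is scored **leave-one-out**, against a table re-estimated
  without that control: a control's own two haplotypes otherwise inflate
  the estimated frequency of exactly the haplotypes it carries, weakening
  the null and making case P-values anti-conservative (we observed this
  directly before adopting leave-one-out).  A case individual appearing in
  the control panel is likewise dropped from estimation and from its own
  null.
* **N of T** — per round, `T` controls are sampled without replacement and
  the best (smallest) `HBC_m` region with at most `N` carriers is
  recorded; the recorded interval is masked in subsequent rounds.  The
  published description of this exclusion is ambiguous (excluded from later
  rounds, or merely from being recorded twice); we mask in later rounds and
  expose `--no-exclusion`.  The multi-patient null keeps the full-sample
  table (per-round leave-`T`-out re-estimation is not attempted); ranking
  experiments are unaffected, but nominal multi-mode P-values inherit a
  small liberal bias from this.
* **Empirical P** — `(1 + #{null ≥ stat}) / (M + 1)` on the `−log₁₀`
  scale; the add-one pseudocount keeps P strictly positive for finite
  nulls.

All randomness flows from a single integer seed through a counter-based
generator (Philox); every null records its seed and parameters.

## Synthetic populations

Three generator modes, all with exact ground truth:

* **markov** (default) — haplotypes from a first-order Markov chain with
  per-marker allele frequencies `Beta(0.5, 0.5)` clipped to `[0.05, 0.95]`
  and adjacent-marker correlation 0.8–0.9 clipped to 99% of the feasible
  range implied by the allele frequencies.  This matches the model class of
  the statistic, so true pairwise and region frequencies are closed-form.
  Defaults give a control heterozygosity of ~0.26, typical of SNP arrays.
* **pool** — whole haplotypes drawn per chromosome from a finite weighted
  pool: genuinely rare long haplotypes, used to exercise the K
  substitution.
* **mosaic** — haplotypes copy from a pool of 100 founder haplotypes with
  switch probability 0.005 per marker (Li–Stephens style).  This creates
  haplotype-block sharing — short haplotypes common, long ones rare — which
  is the mechanism that makes the *age* of a founder segment matter.  True
  frequencies come from a forward recursion over pool states.  At the
  default 10 kb marker spacing the mean copy tract is ~2 Mb, and a
  100-control panel shows ~3 ROH ≥ 25 SNPs per genome (a somewhat
  consanguineous population, comparable to the host populations this method
  targets).

What the generators do **not** model: demographic history (bottlenecks,
admixture), genotyping error, marker ascertainment against a reference
panel, variable recombination rate (1 cM/Mb is used throughout), sex
differences.  Passing tests on these populations show the statistic and
its calibration behave as designed under controlled LD; they do not certify
performance on any particular real population.

## Founder-allele simulator

A mutation is placed at a focal locus; each generation a meiosis draws
crossovers as a Poisson process on genetic distance (Haldane, no
interference), and transmission of the focal allele is conditioned on —
the surviving segment shrinks by an Exponential(1/Morgan) arm on each side
per meiosis, truncated at chromosome ends (expected surviving length
≈ 200/g cM after g generations).  An affected individual is the
intersection of two independent transmission paths, homozygous for the
founder haplotype over that intersection, with background genotypes drawn
from the synthetic population; empty intersections are resampled (logged),
matching the conditioning on an affected who exists.

The cousin IBD-sharing simulation follows labelled segments of an
ancestral couple's four haplotype copies down independent lineages over the
22 autosomes (bundled sex-averaged lengths totalling ~3541 cM; the
bundled table is configurable) and declares sharing when segments with the
same ancestral label overlap.  An independent closed-form cross-check,
`E[#segments] = a(Ld + c)/2^(d-1)` for `d` meioses, `a` ancestors, map
length `L` Morgans and `c` chromosomes, brackets the Monte-Carlo output in
the tests.  Under this standard model the sharing probability for two 10th
cousins is ≈ 0.07% and for three 6th cousins ≈ 0.14% (20,000 replicates);
note that a trio of 6th cousins shares *more* often than a pair of 10th
cousins — the coverage advantage (2⁻⁵ per lineage, cubed, versus 2⁻⁹
squared) outweighs the stricter three-way label matching.  Published
figures exist that differ from these; `scripts/acceptance.py` reports what
this model computes, and the sensitivity to the assumed map length is
linear in `L` per the formula above.

## Experiment design (problem sizes)

The validation experiments (`rohmap.experiments`) run on a desk-scale
genome: 2 chromosomes × 2500 markers at 10 kb spacing (50 Mb, 0.5 Morgan),
100 controls, mosaic mode.  Sizes were chosen so each experiment completes
in minutes while leaving the qualitative contrasts intact:

* **Planted recovery vs founder age** — 200 replicates per age; the
  planted region must rank first by empirical P (ties broken by `HF²`).
  Recovery is ≈ 0.98 at g = 10 and degrades through g = 30 to g = 50, as
  shorter founder segments approach the scale of chance haplotype sharing.
* **Sharing sensitivity** — 300 replicates (200 at T = 50), g = 30:
  recovery at 4-of-10 exceeds 2-of-10, while 4-of-50 tracks 4-of-10
  closely — the number of carriers matters, the cohort size barely does.
* **Calibration** — 500 global-null cases spread over 5 independent study
  panels (100 controls each).  Cases scored against a single finite null
  share its realization and are therefore dependent; independent panels
  make the pooled P-values nearly independent, which the one-sided
  Kolmogorov–Smirnov uniformity check assumes.

## Known limitations

* The chain underestimates frequencies of long common haplotypes; nominal
  `HBC` values are only comparable through the empirical null.
* The multi-patient null does not leave the sampled controls out of the
  frequency table (cost); its nominal P-values are slightly liberal.
* Sib-pair support is restricted to two genotyped affected siblings per
  family, and the pseudo-sib-pair null pairs unrelated controls, which is
  conservative for the family-consensus step.
* Strand flips in input data are never auto-resolved; mismatched markers
  are dropped with a logged warning.
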
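# Methods

This note records the models implemented in karyolute, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what the synthetic-data generators do and do not emulate.

## Chromosome representation

The genome is a vector of 23 chromosome-type copy numbers: the 22 autosome
pairs plus one pooled sex-chromosome slot, so a normal diploid cell has
N = 46 and a tetraploid one N = 92 (configurable to 24 types where X and Y
must be distinguished). A *copy-number profile* is the multiset of those
copy numbers, summarised as counts per class (monosomy, disomy, ...); for
display, classes of five and above are pooled as "high polysomy", but exact
classes are kept internally so N is always exact. Profile equality — the
basis of the expected-prevalence statistic — compares exact class counts
and ignores which chromosome carries which copy number.

ISCN parsing is deliberately numerical-only: the leading modal count fixes
a baseline ploidy (the nearest multiple of 23 — the policy is exposed
because hyperdiploid-but-sub-triploid karyotypes are ambiguous), the sex
field sets the sex slot, and +/− tokens adjust types. Structural tokens
never change whole-chromosome counts; dmin/hsr imply MYCN amplification
(subtype 2B); inc/mar/r set exclusion flags consumed by the cohort filter.

## Allele-mixture (AC) model

For a segment whose aberrant clone occupies DNA fraction f with allele
copies (n_A, n_B), against a balanced background of ploidy b,

    mBAF(f) = (f·n_A + (1−f)·b/2) / (f·(n_A + n_B) + (1−f)·b),

strictly increasing in f whenever n_A > n_B, equal to 0.5 at f = 0. The
inversion is closed-form (linear in f) and is applied to a segment's
median, minimum and maximum mBAF to give the AC point estimate and
interval. Estimates are clipped to [0, 1].

Parameters and defaults:

* `mbaf_imbalance` = 0.55 — classification threshold for allelic imbalance;
* `mbaf_call` = 0.56 — the stricter quantification threshold; implies
  detection limits f = 3/14 ≈ 21.4% (hemizygous loss) and f = 3/11 ≈ 27.3%
  (single-copy gain) on a diploid background;
* `log2_gain` = 0.073 and `log2_loss` = −0.080 — the three copy-number
  classes (gain / copy-number-neutral imbalance / loss) are only disjoint
  with the loss cutoff below the gain cutoff, so the negative sign is the
  default; the positive literal is available via configuration, in which
  case gains keep precedence in the overlap;
* genotype models for inversion default by call type: loss (1,0), gain
  (2,1), CNN-LOH (2,0); the background ploidy is configurable per case
  (near-tetraploid cases can be inverted against b = 4). Genotypes with
  more than 5 total copies (amplifications) are refused as not
  quantifiable.

Segment fusion merges adjacent same-chromosome segments separated by
< 1 Mb with mBAF difference < 0.1, left-to-right with re-testing after each
merge. The fused mBAF is the marker-count-weighted mean (length-weighted
when marker counts are absent) — a weighted mean rather than a median
because marker-level values are not available in segment tables — and the
min/max take the union extrema, so AC intervals can only widen.

A case's diversity is the *prevalence span*: max − min of AC point
estimates, overall and within the numerical/structural classes (each class
uses its own extrema). Majority-clone consistency operationalises "same
DNA-content level" as interval overlap: the majority level is the
[AC_min, AC_max] band overlapping the most calls, and a call belongs to the
majority clone when its band overlaps that level.

## Segregation-error simulators

All four mechanisms evolve virtual cells from a balanced start to a target
chromosome number; 10,000 virtual tumours per case by default.

* **Loss from tetraploidy** — chromatids are removed one at a time, each
  drawn uniformly over all remaining chromatids (i.e. with probability
  proportional to current copy number; uniform-over-types is available as a
  switch). This makes the process exactly equivalent to drawing a uniform
  random subset of the 92 chromatids, so the viable-cell profile
  distribution is multivariate-hypergeometric-like (∝ Π C(4, lost_j)
  conditioned on per-type loss ≤ 3) — a property the tests exploit as an
  exact oracle.
* **Sequential non-disjunction** — each step picks a type uniformly and
  follows the daughter whose total moves toward the target (trisomic going
  up, monosomic going down), so stepping is monotone. Both diploid and
  tetraploid starts are supported; the tetraploid start necessarily steps
  downward.
* **Tripolar, randomised** — after replication each chromosome's 2c
  chromatids are assigned multinomially to three poles; the followed
  daughter is drawn from its exact marginal (independent Binomial(2c, 1/3)
  per type), equivalent to simulating the division and picking a pole
  uniformly. Divisions are re-run (rejection) until the daughter hits the
  target; sequential tripolar divisions are not chained.
* **Tripolar, amphitelic + cytokinetic failure** — every sister-chromatid
  pair splits cleanly across a uniformly chosen pair of the three poles;
  cytokinesis fails between two fixed poles, merging them into a "gains"
  daughter (copies c + Binomial(c, 1/3)) while the third pole forms the
  "losses" daughter (the complement). The side matching the target
  direction is followed, with rejection on the total.

Cells that acquire a nullisomy are eliminated by replacement with random
sampling from the remaining population (for the monotone mechanisms,
end-state nullisomy is equivalent to ever-nullisomy; for the rejection
samplers, non-viable daughters are rejected — the same conditional
distribution). Under monosomy selection, finished tumours carrying any
monosomy are replaced by resampling from the monosomy-free tumours. Note
that replacement duplicates survivors, which inflates the Monte-Carlo
variance of prevalence estimates by roughly the inverse survival fraction;
anyone building confidence intervals on expected prevalence should use the
effective (unique-survivor) sample size.

Cohort evaluation runs every case to its own N, averages expected
prevalence over cases (cases unreachable under a mechanism score 0 — the
mechanism assigns them zero probability — and are flagged), pools the
simulated copy-number classes into an expected distribution, and compares
it to the cohort's observed pooled distribution by Pearson chi-square with
df = classes − 1, pooling classes whose expected count falls below 5 into
their upper neighbour.

### Identifiability of the mechanisms

Three exact distributional facts shape what model comparison can and
cannot decide, all derivable because each single-division mechanism yields
conditioned independent binomials (∝ a product of binomial coefficients)
and sequential non-disjunction a conditioned multinomial:

1. the amphitelic losses-daughter from a tetraploid start is
   **distribution-identical** to loss from tetraploidy (both ∝ Π C(4, l_j)
   given the total) — those two cannot be told apart on the losses side, so
   recovery exercises run the amphitelic model from its identifiable
   diploid gains side;
2. for targets below ~63 chromosomes the diploid amphitelic gains
   distribution pointwise dominates sequential non-disjunction on the
   latter's own draws, so mean expected prevalence cannot recover seq-ND in
   the low-hyperdiploid band; seq-ND is identifiable for N ≳ 65, where its
   multinomial tail (pentasomies and above) escapes the amphitelic support;
3. randomised tripolar beats loss-from-tetraploidy on its own draws at
   every target in [55, 72], but thinly at the low end, so demonstrating
   its recovery needs targets ≥ 60 and a cohort of ~150 cases.

The model-recovery test draws each synthetic cohort from its mechanism's
identifiable band accordingly (loss: N ∈ [55, 85]; seq-ND: [65, 85];
tripolar randomised: [60, 72]; amphitelic: [55, 67]), with cohort sizes
fixed by an exact power analysis of the paired prevalence margins. This
echoes, in sharper form, the empirical observation that the mechanisms are
indistinguishable for tumours with few numerical changes.

## Dynamic population model

A synchronized, constant-size population: each generation every cell
either undergoes whole-genome duplication (probability t, doubling every
copy number) or divides with independent per-chromosome single-copy loss
(probability p per chromosome), the events being mutually exclusive within
one mitosis. Offspring with any chromosome at ≤ 1 copy or a total above
max_N = 92 are removed, and the population is restored to n_cells by
uniform resampling among viable survivors — selection therefore acts
within the generation. *Net growth* is the viable fraction of newly formed
cells. Defaults: p = 0.04 per chromosome per mitosis, t = 0.06, 10,000
cells, 500 generations — the rates measured in a chromosomally unstable
neuroblastoma cell line.

Two consequences of the viability rule are worth stating because they
differ from a bookkeeping that retains non-dividing cells: every recorded
cell has all copies ≥ 2, so N ≥ 46 always and the no-duplication control
population is pinned exactly at diploidy (rather than accumulating a
visible monosomic fraction), and the hypodiploid band is empty in both
populations. The attractor phenomenology is unaffected: an early
hypotetraploid takeover (modal N ≥ 80 by generation 10), drift down
through triploidy, and re-duplication cycles that keep the long-run mean in
the peri-triploid band, with net growth well above the control's.

## FISH statistics

Per sample and probe, the modal number is the most frequent signal count
(ties broken toward the expected ploidy, then the lower class, always
flagged — ties are vanishingly rare in ≥ 200-cell tables, which is the
analysis-grade minimum and warns below). The non-modal fraction is the
percentage of nuclei outside the modal class. The control-derived
significance threshold is mean + 3 sample standard deviations (n − 1
denominator — the only convention reproducing the published 0.77% from the
fibroblast control values) of the control's per-probe non-modal fractions.
Per-line summaries aggregate probes unweighted, which reproduces the
published per-line means. Group comparisons use the two-tailed t-test for
fraction-valued groups, the two-tailed Fisher exact test for 2×2 count
tables, and fall back to an exact permutation test when both groups have
zero variance.

## Synthetic data

The generators are seed-deterministic and always return ground truth
alongside the data.

* **BAF segments** — each aberration yields one segment whose expected
  mBAF comes from the full mixture (carrier clone, non-carrier clones and
  normal contamination all contribute alleles); per-marker mBAF noise is
  Gaussian with sd 0.05, mirrored and clipped into [0.5, 1]; the
  segment-level mBAF gets noise sd 0.05/√markers (≈ 0.005 at the typical
  100 markers, matching a high-quality array's tight diploid baseline) and
  the min/max come from the simulated marker spread. Marker counts are
  uniform on [50, 500]. Log2 ratios are log2(total copies / background)
  plus noise. Not emulated: marker-level BAF series (no segmentation can
  be run on the output), GC waves, and homozygous-SNP removal.
* **FISH counts** — clone fractions are treated as cell fractions; each
  cell's probe count is its clone's copy number at that chromosome,
  mis-scored by ±1 with probability ε (≤ 0.1, emulating near-perfect
  hybridisation efficiency). Not emulated: signal splitting/overlap or
  nuclear truncation artefacts.
* **Karyotype cohorts** — each case is one viable virtual tumour evolved
  under a chosen mechanism to a target drawn from a given range; targets
  the mechanism cannot practically reach (rejection budget exhausted) are
  redrawn. The truth table records the generating mechanism, which is what
  the model-recovery tests score against.

Passing recovery tests on these generators shows the estimators invert the
generators' own assumptions correctly at realistic noise; they do not show
robustness to artefacts the generators omit (segmentation errors,
constitutional CNVs, mosaic normal tissue).

## Problem sizes and tolerances

Simulation-backed tests run 2,000–60,000 virtual tumours per case
(tolerances set at 3–4 Monte-Carlo standard errors of the *effective*
sample size), the dynamic model at its full default size, and the
model-recovery exercise at 120–150 cases per cohort with 1,500 virtual
tumours per case — sizes chosen so that every stochastic assertion sits
several standard errors from its boundary. The mBAF inversion identities
are exact and tested at 1e-9. Exact combinatorial oracles (subset counting
for the loss model, step enumeration for ≤ 3 losses) live in the test
suite, independent of the library code.

## Known limitations

Only one error mechanism per tumour is modelled (no mixed sequences);
chromosome-specific fitness effects and selection coefficients are absent;
the population model has no spatial structure or growth-rate variation;
the ISCN parser covers numerical karyotypes plus flag tokens, not the full
grammar; AC estimation assumes one aberrant genotype per segment against a
balanced background, so overlapping subclonal genotypes on the same
segment are not decomposed.
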
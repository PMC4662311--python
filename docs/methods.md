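# Methods

`scatcap` implements the analysis chain used in noninvasive genetic
capture–recapture studies of territorial carnivores: scats collected
along search transects are genotyped at microsatellite loci from
replicate PCRs, grouped into individuals, and the resulting individual
set feeds population-genetic summaries, relatedness and inbreeding
estimation, effective-number-of-breeders estimators, and a spatially
explicit capture–recapture (SECR) abundance model. This note records
the models, the defaults and why, and the choices made where the design
was genuinely open.

## Consensus genotyping

Fecal DNA is dilute and degraded; single PCRs suffer allelic dropout
(one allele of a heterozygote amplifies, mimicking a homozygote) and
occasional false alleles. The guard is replication:

* a **heterozygous** genotype is accepted only when the identical
  unordered allele pair appears in at least `min_obs` (default 3)
  successful PCRs;
* a **homozygous** genotype is accepted only when *every* successful
  PCR shows that single allele and at least `min_obs` did.

Failed reactions count neither for nor against a call — "all PCRs"
cannot reasonably include reactions that produced nothing, and the
`min_obs` floor preserves the replication standard for homozygotes.
A possible weaker reading — letting a heterozygote's full pair in two
PCRs combine with a single-allele PCR — is *not* used: each supporting
PCR must show the complete pair. Scats amplifying at fewer than
`min_amplified` (4) loci are screened out, and only scats with accepted
consensus genotypes at `min_consensus` (6) or more loci are retained
for identity analysis. All three thresholds are configuration keys.

Consensus calling is permutation-invariant in replicate order and
idempotent. Adding a confirming replicate can never demote an accepted
heterozygote; adding a conflicting successful PCR *can* demote an
accepted homozygote — that asymmetry is inherent to the "all PCRs"
homozygote rule.

## Species assignment

Species identity comes from the length of a diagnostic mtDNA
control-region fragment; bobcat and coyote products differ by 16 bp.
The classifier assigns the species whose reference length lies within
`tolerance_bp` (default 3) of the observed length, requires the
tolerance to be under half the inter-species gap, and returns UNKNOWN
for missing, out-of-window or ambiguous fragments.

## Probability of identity and individual identification

Whether a marker panel can separate individuals is quantified by the
probability of identity. Per locus with allele frequencies $p_i$:

$$\mathrm{PID} = 2\left(\sum p_i^2\right)^2 - \sum p_i^4$$

$$\mathrm{PID}_{sib} = 0.25 + 0.5\sum p_i^2 +
  0.5\left(\sum p_i^2\right)^2 - 0.25\sum p_i^4$$

Loci multiply. $\mathrm{PID}_{sib}$ (the chance two *full siblings*
share a multilocus genotype) is the conservative benchmark; the package
reports whether it clears a configurable threshold (default $10^{-6}$).
Both formulas are exact under Hardy–Weinberg and are tested against
full genotype-pair enumeration oracles to $10^{-12}$.

Two retained scat profiles are declared the same individual when they
match at `min_match` (5) or more co-typed loci with at most
`max_mismatch` (0) disagreements; genotypes compare as unordered
pairs. The strict zero-mismatch default is conservative; a tolerant
mode (`max_mismatch=1`) exists because field matching tools allow it
and because a single allelic-dropout slip should be inspectable rather
than silently splitting an animal. Matching decisions are closed
transitively (union–find), so clustering is independent of input
order; clusters containing an internally DIFFERENT pair (possible via
chaining) are flagged, not split. The composite genotype per cluster
is the per-locus majority call across member scats, with exact ties
set to missing. Allele frequencies for PID and everything downstream
are computed from composite *individual* genotypes, never per scat,
so resampled animals are not overweighted.

## Population-genetic summaries

Per locus over typed individuals: observed heterozygosity $H_O$,
expected heterozygosity $H_E = 1 - \sum p_i^2$, Nei's unbiased
$uH_E = H_E \cdot 2n/(2n-1)$, and allele count $A$. Allelic richness
is the raw mean allele count — no rarefaction — matching the
"total number of alleles" definition used by survey tools at a single
sampling level. $F_{IS} = (H_E - H_O)/H_E$ per polymorphic locus,
averaged unweighted; negative values indicate heterozygote excess.
Across-locus means are unweighted, with among-locus standard errors.

Hardy–Weinberg deviation is tested per locus by the chi-square over
genotype categories (df $=k(k-1)/2$) — the survey-tool default — with
a seeded Monte Carlo exact alternative that permutes alleles among
genotypes (the asymptotic and exact p agree closely only for large
samples; the exact test is preferred below ~100 individuals).

## Effective number of breeders

**Heterozygote excess.** A cohort produced by few breeders shows an
excess of heterozygotes relative to Hardy–Weinberg. With per-locus
$D_l = (H_{O,l} - H_{E,l})/H_{E,l}$ averaged over loci weighted by the
number of independent alleles ($k_l - 1$; an unweighted mean is also
available),

$$\hat N_b = \frac{1}{2\bar D} + \frac{1}{2(\bar D + 1)}.$$

$\bar D \le 0$ carries no signal and maps to infinity. The confidence
interval comes from a delete-one-locus jackknife on $\bar D$, pushed
through the (monotone decreasing) formula.

**Molecular coancestry.** Raw allele sharing between two genotypes,
$f_{xy} = \tfrac14[\mathbb 1(a{=}c)+\mathbb 1(a{=}d)+\mathbb 1(b{=}c)+\mathbb 1(b{=}d)]$,
corrected for chance sharing, $(f_{xy} - s)/(1-s)$ with
$s = \sum p_i^2$, estimates the pair's kinship; a cohort bred by $N_b$
equally contributing parents has mean kinship $1/(2N_b)$, so
$\hat N_b = 1/(2\hat f_1)$, with a jackknife-over-loci CI. An
important caveat, verified by simulation during development: when $s$
is computed from the cohort's *own* allele frequencies, the pairwise
estimates sum to approximately zero by construction — the sample
frequencies absorb the family structure — and the estimator degenerates
toward infinity. The function therefore accepts reference
(parental-population) allele frequencies and should be given them
whenever available; cohort frequencies (with the small-sample
correction of expected homozygosity) remain the fallback for parity
with common survey tools, with the caveat attached. Exact numerical
parity with any specific tool's internal finite-sample corrections is
not claimed.

## Pairwise relatedness and inbreeding

A non-inbred dyad is summarized by $k = (k_0, k_1, k_2)$, the
probabilities of sharing 0/1/2 alleles identical by descent;
relatedness is $r = k_1/2 + k_2$. Anchors: U $=(1,0,0)$,
HS $=(\tfrac12,\tfrac12,0)$, FS $=(\tfrac14,\tfrac12,\tfrac14)$,
PO $=(0,1,0)$. The per-locus likelihood of an observed genotype pair
is $k_0 P_0 + k_1 P_1 + k_2 P_2$ using the standard non-inbred
unordered-pair tables (verified against exact enumeration); loci
multiply and missing loci are skipped. The ML $\hat k$ is located on a
0.01-step simplex grid and refined by constrained local search, with
ties broken toward smaller $r$; the full simplex is searched (no
$k_1^2 \ge 4k_0k_2$ constraint), matching the default behaviour of the
common ML relatedness tool. Categorical classification evaluates the
four anchors and breaks ties toward the less related category; a locus
sharing no allele makes PO impossible. A genotyping-error parameter is
deliberately not modelled (fixed at zero): the ML relatedness r's of
this package are conditional on the consensus genotypes being correct,
which the replication rules are designed to ensure.

ML estimates of $r$ are boundary-biased upward for unrelated dyads
(truth sits on a vertex of the simplex); the bias shrinks with marker
information. The recovery studies in the test suite therefore use two
panels: the island-scale fixture (12 loci, 3–5 alleles) for categorical
classification, and a 12-locus, 8-allele panel — the polymorphism these
microsatellites show in continental source populations — for the
continuous-$r$ recovery, where mean $\hat r$ for unrelated dyads is
~0.05 (it is ~0.09 at island-scale diversity).

Individual inbreeding $F$ is estimated by maximizing
$\prod_l P(g_l \mid F)$ with $P(aa|F) = p_a^2 + F p_a(1-p_a)$ and
$P(ab|F) = 2 p_a p_b (1-F)$ over $F \in [0,1]$. The per-locus
likelihood is linear in $F$, so a dense 1000-point grid locates the
product maximum to $10^{-3}$, which is far below the estimator's
sampling noise at realistic locus counts. Confidence intervals are
percentile bootstrap over loci (default 100 replicates, seeded). This
single-individual ML replaces the triadic (three-reference) estimator
used by some tools; parity with that estimator is not claimed, and the
packaged published triadic values are used only as worked-example
inputs for the summary operations.

## Spatially explicit capture–recapture

Transects are cut into `section_length` (200 m) sections measured
along the path; each section's midpoint is a binary proximity detector.
A final remainder merges into the previous section unless it is longer
than half a section (the boundary case merges). Identified scats snap
to the nearest detector (ties to the lowest id; scats beyond a 500 m
snap radius are dropped with a warning), and repeated detections of an
individual at one detector × occasion collapse to a single 1.

Detection is half-normal, $g(d) = g_0 \exp(-d^2/2\sigma^2)$, and
activity centers follow a homogeneous Poisson process of density $D$
over a habitat mask (cells of side `mask_resolution`, default 250 m,
whose centers fall in the habitat polygon; without a polygon, a
rectangular buffer — at least $4\sigma$ — around the detectors). The
log-likelihood is the standard Poisson form

$$\log L = -D\sum_x p_\cdot(x)\,a
  + \sum_i \log\Big(D\sum_x \Pr(\omega_i\mid x)\,a\Big),$$

maximized over $(\log D,\ \mathrm{logit}\,g_0,\ \log\sigma)$ by
L-BFGS-B with a Nelder–Mead restart on failure. Standard errors come
from the inverse central-difference Hessian on the link scale; 95% CIs
are back-transformed Wald intervals, and $\hat N = \hat D A$ over the
mask with a delta-method SE. The estimator satisfies $\hat N \ge n$
analytically (the profile MLE of $D$ is $n / \sum_x a\,p_\cdot(x)$).
Starting values: $\sigma_0$ = half the mean distance between a
detected animal's detectors, $g_0 = 0.1$, $D_0 = n/A$. Mask-halving
changes the log-likelihood by well under 0.01 at survey-scale $\sigma$,
and enlarging the buffer beyond $4\sigma$ leaves $\hat D$ and
$\hat\sigma$ unchanged to within 2% (both are tested). Occasion
structure defaults to the maximum occasion index in the detections
(two search passes in the fixture); when scats are undated, the
mapping of collections to occasions is the caller's responsibility.
Only the binary (Bernoulli per detector × occasion) observation model
is implemented; a Poisson count-detector mode is a known omission.

## Synthetic surveys and what passing recovery tests shows

The generator simulates every layer the pipeline consumes, from one
integer seed, with truth tables for recovery testing: a pedigreed
population (founders in Hardy–Weinberg at configured frequencies;
Mendelian inheritance; pedigree $F$ and the kinship matrix by the
tabular recursion, so truth is exact under any mating rule including
selfing), uniform activity centers on the habitat polygon (matching
the SECR model fitted downstream), half-normal Bernoulli detection at
the transect detectors with one scat deposited per detection, a
species mixture (coyote and unreadable scats exercise the mtDNA
classifier), and replicate PCRs with allelic dropout, false alleles
(replacement, keeping records diploid) and reaction failure.

The default configuration mirrors a small insular felid survey: 12
loci with 3–5 equifrequent alleles (allele counts averaging 4, so the
observed allelic richness of a 9-animal sample lands near 3.7), 9
individuals on a 3 × 10 km island, three 10 km transects at 200 m
sections, $g_0 = 0.16$, $\sigma = 700$ m, two occasions — yielding
roughly 40 bobcat scats per survey — plus 46 coyote and 26 unreadable
scats. PCR quality is a two-class mixture: half the scats are
environmentally degraded (95% reaction failure) and half are good (15%
failure, 10% dropout, 2% false alleles, 4 replicates). The mixture is
what lets per-locus amplification sit below 50% while roughly half the
bobcat scats still clear the 6-locus retention filter — a single
failure rate cannot do both, because real genotyping success is
strongly correlated within a scat.

What the generator does *not* emulate: home-range structure beyond a
stationary center, density inhomogeneity, within-scat contamination,
allele-size ladders with stutter, locus-specific amplification
quality, or temporal population change. Passing recovery tests
therefore demonstrates the estimators are correct under their own
model assumptions at realistic sample sizes — not that those
assumptions hold for any particular field dataset.

## Numerical choices

* Unordered allele pairs are stored sorted; all equality is
  order-free. Missing is `(0, 0)` on disk, `None` in memory.
* Likelihoods clamp at $10^{-300}$ before logs; SECR per-occasion
  probabilities are clipped to $[10^{-15}, 1-10^{-12}]$.
* Simplex and $F$ grids (0.01 and 0.001 steps) are resolution floors;
  local refinement must never return a worse likelihood than the grid
  (property-tested).
* Jackknife/bootstrap CIs are percentile or normal-theory as stated
  above; all resampling is seeded.
* Degenerate inputs fail loudly: half-missing genotypes, duplicate
  replicate keys, occasion 0, detections >10 km outside the habitat
  bounding box (a CRS mix-up signature), monomorphic-only tables.

## Problem sizes used in the test suite

Recovery studies run at the scale of the system being emulated: 100
simulated surveys for SECR (9 animals, ~150 detectors, 500 m mask),
1000 dyads per relationship category, 1000 selfed individuals for
inbreeding, 40 replicate cohorts for the coancestry estimator. The
whole suite completes in well under a minute.
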
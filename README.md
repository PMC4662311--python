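# scatcap

Noninvasive genetic capture–recapture for scat surveys: consensus
microsatellite genotyping from replicate PCRs, individual
identification via probability of identity, population-genetic and
relatedness/inbreeding estimation, effective-number-of-breeders
estimators, and spatially explicit capture–recapture (SECR) abundance
estimation — plus a synthetic scat-survey generator so the entire
pipeline runs and is testable without field data.

The package is aimed at wildlife geneticists and quantitative
ecologists analyzing surveys like the one that motivated it: a small,
insular, reintroduced bobcat (*Lynx rufus*) population censused by
walking transects, collecting scats, and genotyping fecal DNA.

## What it computes

**Consensus genotyping.** Fecal DNA suffers allelic dropout and false
alleles, so a heterozygous genotype is accepted only when the same
unordered allele pair is seen in ≥3 independent PCRs, and a homozygote
only when every successful PCR shows that single allele (≥3 of them).
Scats must amplify at ≥4 loci to stay in, and need accepted genotypes
at ≥6 loci to be used for identification.

**Identity.** Per locus, PID $=2(\sum p_i^2)^2-\sum p_i^4$ and
PID$_{sib}=0.25+0.5\sum p_i^2+0.5(\sum p_i^2)^2-0.25\sum p_i^4$; loci
multiply. Profiles matching at ≥5 co-typed loci are the same animal;
matches are closed transitively and composite genotypes built per
individual.

**Population genetics.** $H_O$, $H_E=1-\sum p_i^2$, Nei's unbiased
$uH_E$, allelic richness (raw allele count), $F_{IS}=(H_E-H_O)/H_E$,
chi-square and Monte Carlo exact Hardy–Weinberg tests.

**Effective breeders.** Heterozygote excess:
$\hat N_b = 1/(2\bar D)+1/(2(\bar D+1))$ with
$D_l=(H_{O,l}-H_{E,l})/H_{E,l}$ weighted by $k_l-1$; and molecular
coancestry: $\hat N_b = 1/(2\hat f_1)$ from bias-corrected pairwise
allele sharing (give it reference allele frequencies — see
`docs/methods.md`).

**Relatedness and inbreeding.** Maximum-likelihood $k=(k_0,k_1,k_2)$
on the IBD simplex per dyad ($r=k_1/2+k_2$), categorical
classification against U/HS/FS/PO anchors, and ML individual $F$ with
a bootstrap-over-loci CI.

**SECR.** Transects cut into 200 m sections whose midpoints are binary
proximity detectors; half-normal detection
$g(d)=g_0 e^{-d^2/2\sigma^2}$; homogeneous-Poisson activity centers
integrated over a habitat mask; $\hat D,\hat g_0,\hat\sigma$ by
maximum likelihood on link scales and $\hat N=\hat D A$ with
delta-method SE.

## Worked example

Run the full pipeline on the built-in synthetic survey (a 3 × 10 km
island, 9 bobcats, three 10 km transects searched twice, replicate
PCRs at 12 microsatellite loci with realistic dropout/failure rates):

```sh
scatcap run --seed 1 --out-dir out/
```

prints

```
scat-survey pipeline summary
==============================
scats with replicate PCRs : 37
scats retained (>= loci)  : 14
individuals identified    : 9
mean scats per individual : 1.56
cumulative PIDsib         : 7.31e-05
Ho=0.8312  uHe=0.7378  AR=3.917  FIS=-0.2338
mean r=0.1465 (SD 0.2997), pairs>=0.5: 6
SECR: N=16.7 (SE 7.208), sigma=560.0 m, g0=0.047
Nb (heterozygote_excess) = 2.49
Nb (coancestry) = 35.33
```

Reading it: 37 bobcat scats were simulated and genotyped, 14 survived
the 6-locus consensus filter, and clustering them recovered exactly
the 9 simulated individuals (the truth tables are written alongside).
The cumulative sibling probability of identity (7×10⁻⁵) says the
retained loci cannot plausibly merge two siblings into one animal.
The SECR fit estimates ~17 animals against a simulated truth of 9 —
a reminder that with n = 9 detected individuals the abundance SE
(7.2) is honest and wide. Negative $F_{IS}$ (heterozygote excess) is
expected in a cohort descended from few founders, and the
heterozygote-excess $N_b$ correspondingly lands well below the census
size. `out/report.json` holds every number with full precision plus
the settings and seed.

Each stage is also a standalone subcommand (`scatcap simulate`,
`consensus`, `identify`, `popgen`, `relatedness`, `secr`) reading and
writing plain CSV/GeoJSON, so real survey data can enter at any stage.

## Input dialects

* **Genotype CSV** — `sample_id`, then two columns per locus
  (`LOC_1`, `LOC_2`), alleles as integer fragment sizes, missing
  `0,0` (half-missing pairs are rejected).
* **Replicate CSV** — `scat_id,pcr_id,locus_id,allele_a,allele_b`,
  `0,0` = failed reaction; a single observed band is `a,a`.
* **Detections CSV** — `scat_id,x,y,occasion` in projected planar
  meters, occasions 1-based.
* **Transects / habitat** — GeoJSON LineStrings / Polygons (projected
  coordinates; convert shapefiles externally, e.g. with `ogr2ogr`), or
  a `transect_id,x,y` CSV for transects.

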
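"""Allele frequencies, diversity statistics, HWE tests, FIS and
effective-number-of-breeders estimators.

Conventions follow the common survey tools: expected heterozygosity
He = 1 - sum p_i^2; Nei's unbiased uHe = He * 2n/(2n-1) for n typed
individuals; allelic richness is the raw allele count (no rarefaction);
FIS = (He - Ho)/He, negative under heterozygote excess.

Two single-sample estimators of the effective number of breeders (Nb):

* heterozygote excess — a cohort produced by few breeders shows
  Ho > He; with D = (Ho - He)/He averaged over loci,
  Nb = 1/(2D) + 1/(2(D+1)), infinite for D <= 0.
* molecular coancestry — mean allele-sharing between cohort members,
  corrected for chance sharing, estimates mean kinship f1; Nb = 1/(2 f1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .dtypes import GenotypeTable, Genotype, ValidationError, is_het

AlleleFrequencies = dict[str, dict[int, float]]


def allele_frequencies(table: GenotypeTable) -> AlleleFrequencies:
    """Per-locus relative allele frequencies over non-missing genotypes."""
    freqs: AlleleFrequencies = {}
    for locus in table.loci:
        counts: dict[int, int] = {}
        for g in table.typed_genotypes(locus):
            for a in g:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        if total:
            freqs[locus] = {a: counts[a] / total for a in sorted(counts)}
    return freqs


# ---------------------------------------------------------------- diversity

@dataclass
class PopgenSummary:
    per_locus: pd.DataFrame  # locus, n, A, Ho, He, uHe, FIS, hwe_chi2, hwe_df, hwe_p
    mean_Ho: float
    se_Ho: float
    mean_He: float
    mean_uHe: float
    se_uHe: float
    AR: float
    mean_FIS: float
    se_FIS: float


def _locus_stats(table: GenotypeTable, locus: str) -> Optional[dict]:
    gens = table.typed_genotypes(locus)
    n = len(gens)
    if n == 0:
        return None
    counts: dict[int, int] = {}
    for g in gens:
        for a in g:
            counts[a] = counts.get(a, 0) + 1
    p = np.array([c / (2 * n) for c in counts.values()])
    ho = sum(1 for g in gens if is_het(g)) / n
    he = 1.0 - float(np.sum(p**2))
    uhe = he * 2 * n / (2 * n - 1) if n > 0 else math.nan
    return {"locus": locus, "n": n, "A": len(counts), "Ho": ho, "He": he, "uHe": uhe}


def heterozygosity_stats(table: GenotypeTable, hwe: str | None = "chi2",
                         hwe_reps: int = 10_000, seed: int = 0) -> PopgenSummary:
    """Per-locus and mean diversity statistics, FIS and (optionally) HWE tests.

    Loci with zero typed individuals are excluded.  Means are
    unweighted over loci (FIS over polymorphic loci only); SEs are the
    among-locus standard errors.
    """
    rows = []
    for locus in table.loci:
        st = _locus_stats(table, locus)
        if st is None:
            continue
        st["FIS"] = (st["He"] - st["Ho"]) / st["He"] if st["He"] > 0 else math.nan
        if hwe is not None and st["A"] >= 2:
            chi2, df, p = hwe_test(table, locus, method=hwe, reps=hwe_reps, seed=seed)
            st.update(hwe_chi2=chi2, hwe_df=df, hwe_p=p)
        else:
            st.update(hwe_chi2=math.nan, hwe_df=0, hwe_p=math.nan)
        rows.append(st)
    if not rows:
        raise ValidationError("no locus with typed individuals")
    per_locus = pd.DataFrame(rows)

    def mean_se(col, mask=None):
        v = per_locus[col].to_numpy(float)
        if mask is not None:
            v = v[mask]
        v = v[np.isfinite(v)]
        if len(v) == 0:
            return math.nan, math.nan
        se = float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else math.nan
        return float(np.mean(v)), se

    mean_Ho, se_Ho = mean_se("Ho")
    mean_He, _ = mean_se("He")
    mean_uHe, se_uHe = mean_se("uHe")
    poly = per_locus["A"].to_numpy() > 1
    mean_FIS, se_FIS = mean_se("FIS", poly)
    return PopgenSummary(
        per_locus=per_locus,
        mean_Ho=mean_Ho,
        se_Ho=se_Ho,
        mean_He=mean_He,
        mean_uHe=mean_uHe,
        se_uHe=se_uHe,
        AR=float(per_locus["A"].mean()),
        mean_FIS=mean_FIS,
        se_FIS=se_FIS,
    )


def fis(table: GenotypeTable) -> tuple[dict[str, float], float]:
    """Per-locus FIS = (He - Ho)/He and the unweighted mean over polymorphic loci."""
    per_locus = {}
    for locus in table.loci:
        st = _locus_stats(table, locus)
        if st is None or st["He"] <= 0:
            continue
        per_locus[locus] = (st["He"] - st["Ho"]) / st["He"]
    if not per_locus:
        raise ValidationError("no polymorphic locus for FIS")
    return per_locus, float(np.mean(list(per_locus.values())))


# ---------------------------------------------------------------- HWE

def _hwe_chi2(gens: list[Genotype]) -> tuple[float, int]:
    n = len(gens)
    counts: dict[int, int] = {}
    for g in gens:
        for a in g:
            counts[a] = counts.get(a, 0) + 1
    alleles = sorted(counts)
    k = len(alleles)
    p = {a: counts[a] / (2 * n) for a in alleles}
    obs: dict[Genotype, int] = {}
    for g in gens:
        obs[g] = obs.get(g, 0) + 1
    chi2 = 0.0
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            e = n * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
            o = obs.get((a, b), 0)
            if e > 0:
                chi2 += (o - e) ** 2 / e
    return chi2, k * (k - 1) // 2


def hwe_test(
    table: GenotypeTable,
    locus: str,
    method: str = "chi2",
    reps: int = 10_000,
    seed: int = 0,
) -> tuple[float, int, float]:
    """Test deviation from Hardy-Weinberg proportions at one locus.

    Returns ``(chi2, df, p)``.  ``method='chi2'`` uses the asymptotic
    chi-square over genotype categories (df = k(k-1)/2); ``'exact'``
    uses a seeded Monte Carlo permutation of alleles among genotypes
    with the same statistic.  Monomorphic loci return NaN statistics.
    """
    gens = table.typed_genotypes(locus)
    n = len(gens)
    alleles = sorted({a for g in gens for a in g})
    if len(alleles) < 2:
        return math.nan, 0, math.nan
    chi2, df = _hwe_chi2(gens)
    if method == "chi2":
        return chi2, df, float(stats.chi2.sf(chi2, df))
    if method != "exact":
        raise ValueError(f"unknown HWE method {method!r}")
    rng = np.random.default_rng(seed)
    pool = np.array([a for g in gens for a in g])
    hits = 0
    for _ in range(reps):
        rng.shuffle(pool)
        perm = [(min(pool[2 * i], pool[2 * i + 1]), max(pool[2 * i], pool[2 * i + 1]))
                for i in range(n)]
        c, _ = _hwe_chi2(perm)
        if c >= chi2 - 1e-12:
            hits += 1
    return chi2, df, (hits + 1) / (reps + 1)


# ------------------------------------------------- Nb: heterozygote excess

def nb_from_D(D: float) -> float:
    """Effective breeders from the mean heterozygote-excess D.

    Nb = 1/(2D) + 1/(2(D+1)); D <= 0 carries no signal and maps to
    infinity.
    """
    if D <= 0:
        return math.inf
    return 1.0 / (2.0 * D) + 1.0 / (2.0 * (D + 1.0))


@dataclass
class NbEstimate:
    nb: float
    statistic: float  # D-bar or corrected mean coancestry f1
    ci: tuple[float, float]
    per_locus: dict[str, float]
    method: str


def _d_per_locus(table: GenotypeTable) -> tuple[dict[str, float], dict[str, float]]:
    """Heterozygote-excess D_l = (Ho - He)/He and weights k_l - 1 per locus."""
    d, w = {}, {}
    for locus in table.loci:
        st = _locus_stats(table, locus)
        if st is None or st["A"] < 2 or st["He"] <= 0:
            continue
        d[locus] = (st["Ho"] - st["He"]) / st["He"]
        w[locus] = st["A"] - 1.0
    return d, w


def _weighted_D(d: Mapping[str, float], w: Mapping[str, float]) -> float:
    tw = sum(w.values())
    return sum(d[l] * w[l] for l in d) / tw


def ne_heterozygote_excess(table: GenotypeTable, alpha: float = 0.05) -> NbEstimate:
    """Heterozygote-excess estimate of the effective number of breeders.

    D is averaged over loci weighted by the number of independent
    alleles (k-1); the CI comes from a delete-one-locus jackknife on D,
    mapped through the (monotone decreasing) Nb formula.
    """
    d, w = _d_per_locus(table)
    if not d:
        raise ValidationError("all loci monomorphic; D undefined")
    dbar = _weighted_D(d, w)
    loci = list(d)
    if len(loci) > 1:
        pseudo = []
        for drop in loci:
            dd = {l: v for l, v in d.items() if l != drop}
            ww = {l: v for l, v in w.items() if l != drop}
            pseudo.append(_weighted_D(dd, ww))
        pseudo = np.array(pseudo)
        m = len(loci)
        se = math.sqrt((m - 1) / m * float(np.sum((pseudo - pseudo.mean()) ** 2)))
        z = stats.norm.ppf(1 - alpha / 2)
        d_lo, d_hi = dbar - z * se, dbar + z * se
        ci = (nb_from_D(d_hi), nb_from_D(d_lo))
    else:
        ci = (math.nan, math.nan)
    return NbEstimate(nb=nb_from_D(dbar), statistic=dbar, ci=ci, per_locus=d,
                      method="heterozygote_excess")


# ------------------------------------------------- Nb: molecular coancestry

def molecular_similarity(g1: Genotype, g2: Genotype) -> float:
    """Allele-sharing score: 1/4 of the count of equal cross-pairs."""
    a, b = g1
    c, d = g2
    return ((a == c) + (a == d) + (b == c) + (b == d)) / 4.0


def ne_coancestry(
    table: GenotypeTable,
    freqs: Optional[AlleleFrequencies] = None,
    alpha: float = 0.05,
) -> NbEstimate:
    """Molecular-coancestry estimate of the effective number of breeders.

    Per pair and locus the raw similarity f_xy is corrected for chance
    sharing, (f_xy - s)/(1 - s) with s = sum p_i^2, so its expectation
    is the pair's kinship; a cohort bred by Nb parents has mean kinship
    f1 = 1/(2 Nb), so Nb = 1/(2 f1).  Jackknife over loci for the CI.

    ``freqs`` should be reference (parental-population) allele
    frequencies whenever they are available: frequencies estimated from
    the cohort itself absorb the very family structure being measured
    (the pairwise estimates then sum to roughly zero by construction),
    which drives the estimate toward infinity.  With ``freqs=None`` the
    sample frequencies are used with Nei's small-sample correction of
    the expected homozygosity, matching common survey-tool behaviour,
    and the result should be read with that caveat.
    """
    samples = table.samples
    if len(samples) < 2:
        raise ValidationError("coancestry Nb needs at least 2 individuals")
    sample_based = freqs is None
    if sample_based:
        freqs = allele_frequencies(table)
    per_locus_mean: dict[str, float] = {}
    for locus in table.loci:
        if locus not in freqs or len(freqs[locus]) < 2:
            continue
        s = sum(p**2 for p in freqs[locus].values())
        if sample_based:
            # unbiased expected homozygosity from 2n sampled alleles
            two_n = 2 * table.n_typed(locus)
            if two_n > 1:
                s = (two_n * s - 1.0) / (two_n - 1.0)
        if s >= 1.0 or s <= 0.0:
            continue
        vals = []
        for i in range(len(samples)):
            gi = table.genotype(samples[i], locus)
            if gi is None:
                continue
            for j in range(i + 1, len(samples)):
                gj = table.genotype(samples[j], locus)
                if gj is None:
                    continue
                vals.append((molecular_similarity(gi, gj) - s) / (1.0 - s))
        if vals:
            per_locus_mean[locus] = float(np.mean(vals))
    if not per_locus_mean:
        raise ValidationError("no usable locus for coancestry Nb")
    f1 = float(np.mean(list(per_locus_mean.values())))

    def to_nb(f):
        return 1.0 / (2.0 * f) if f > 0 else math.inf

    loci = list(per_locus_mean)
    if len(loci) > 1:
        vals = np.array([per_locus_mean[l] for l in loci])
        pseudo = np.array([np.mean(np.delete(vals, i)) for i in range(len(loci))])
        m = len(loci)
        se = math.sqrt((m - 1) / m * float(np.sum((pseudo - pseudo.mean()) ** 2)))
        z = stats.norm.ppf(1 - alpha / 2)
        ci = (to_nb(f1 + z * se), to_nb(f1 - z * se))
    else:
        ci = (math.nan, math.nan)
    return NbEstimate(nb=to_nb(f1), statistic=f1, ci=ci, per_locus=per_locus_mean,
                      method="molecular_coancestry")
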
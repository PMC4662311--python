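"""Likelihood-based pairwise relatedness and individual inbreeding.

A non-inbred dyad's genetic relationship is summarised by the k-vector
(k0, k1, k2): the probabilities of sharing 0, 1 or 2 alleles identical
by descent at a locus.  Relatedness is r = k1/2 + k2.  Familiar
relationships sit at fixed points of the simplex:

    unrelated        U  = (1, 0, 0)        r = 0
    half siblings    HS = (1/2, 1/2, 0)    r = 1/4
    full siblings    FS = (1/4, 1/2, 1/4)  r = 1/2
    parent-offspring PO = (0, 1, 0)        r = 1/2

Given population allele frequencies, the likelihood of an observed
genotype pair at one locus is k0*P0 + k1*P1 + k2*P2, where P0/P1/P2 are
the probabilities of the pair conditional on sharing 0/1/2 IBD alleles
(standard non-inbred dyad tables).  Loci multiply.  The ML estimate of
k is found on the simplex; the ML estimate of an individual inbreeding
coefficient F maximises the product of per-locus genotype probabilities
P(aa|F) = p^2 + F p (1-p), P(ab|F) = 2 p_a p_b (1-F) over F in [0,1],
with a percentile bootstrap over loci for confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .dtypes import Genotype, GenotypeTable, ValidationError
from .popgen import AlleleFrequencies, allele_frequencies

KVector = tuple[float, float, float]

ANCHORS: dict[str, KVector] = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}
#: tie-break preference, least related first
ANCHOR_ORDER = ["U", "HS", "FS", "PO"]

_TINY = 1e-300


def r_from_k(k: KVector) -> float:
    return k[1] / 2.0 + k[2]


def _hwe_prob(g: Genotype, p: Mapping[int, float]) -> float:
    a, b = g
    return p[a] ** 2 if a == b else 2.0 * p[a] * p[b]


def pair_ibd_probs(
    g1: Genotype, g2: Genotype, p: Mapping[int, float]
) -> tuple[float, float, float]:
    """(P0, P1, P2): probability of the unordered genotype pair given
    that the dyad shares 0, 1 or 2 alleles IBD at this locus."""
    a, b = g1
    c, d = g2
    P0 = _hwe_prob(g1, p) * _hwe_prob(g2, p)
    P2 = _hwe_prob(g1, p) if g1 == g2 else 0.0
    if a == b and c == d:
        P1 = p[a] ** 3 if a == c else 0.0
    elif a == b:  # AA vs CD (het)
        P1 = p[a] ** 2 * (p[d] if a == c else (p[c] if a == d else 0.0))
    elif c == d:  # AB (het) vs CC
        P1 = p[c] ** 2 * (p[b] if c == a else (p[a] if c == b else 0.0))
    else:  # het vs het
        if g1 == g2:
            P1 = p[a] * p[b] * (p[a] + p[b])
        else:
            shared = set(g1) & set(g2)
            if len(shared) == 1:
                s = shared.pop()
                o1 = b if a == s else a
                o2 = d if c == s else c
                P1 = p[s] * p[o1] * p[o2]
            else:
                P1 = 0.0
    return P0, P1, P2


def _locus_prob_matrix(
    g1: Mapping[str, Optional[Genotype]],
    g2: Mapping[str, Optional[Genotype]],
    freqs: AlleleFrequencies,
) -> np.ndarray:
    """Stack per-locus (P0, P1, P2) for the co-typed polymorphic loci."""
    rows = []
    for locus, p in freqs.items():
        a = g1.get(locus)
        b = g2.get(locus)
        if a is None or b is None or len(p) < 2:
            continue
        rows.append(pair_ibd_probs(a, b, p))
    if not rows:
        raise ValidationError("no co-typed polymorphic locus for the dyad")
    return np.asarray(rows, dtype=float)


def dyad_loglik(
    g1: Mapping[str, Optional[Genotype]],
    g2: Mapping[str, Optional[Genotype]],
    k: KVector,
    freqs: AlleleFrequencies,
) -> float:
    """Log-likelihood of a dyad's genotypes under IBD-sharing vector k."""
    P = _locus_prob_matrix(g1, g2, freqs)
    lik = P @ np.asarray(k, dtype=float)
    return float(np.sum(np.log(np.maximum(lik, _TINY))))


def _simplex_grid(step: float = 0.01) -> np.ndarray:
    n = round(1.0 / step)
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            pts.append((i / n, j / n, (n - i - j) / n))
    return np.asarray(pts)


_GRID = _simplex_grid(0.01)
_GRID_R = _GRID[:, 1] / 2.0 + _GRID[:, 2]


def _grid_argmax(P: np.ndarray) -> tuple[KVector, float]:
    """Best k on the 0.01 simplex grid; ties resolved toward smaller r."""
    lik = np.log(np.maximum(_GRID @ P.T, _TINY)).sum(axis=1)
    best = lik.max()
    cand = np.flatnonzero(lik >= best - 1e-12)
    kidx = cand[np.argmin(_GRID_R[cand])]
    return tuple(_GRID[kidx]), float(lik[kidx])


@dataclass
class RelatednessEstimate:
    k: KVector
    r: float
    loglik: float
    n_loci: int


def estimate_r_ml(
    g1: Mapping[str, Optional[Genotype]],
    g2: Mapping[str, Optional[Genotype]],
    freqs: AlleleFrequencies,
    refine: bool = True,
) -> RelatednessEstimate:
    """Maximum-likelihood k-vector and relatedness for one dyad.

    A 0.01-step simplex grid locates the optimum; a constrained local
    search refines it.  Ties go to the smaller r.
    """
    P = _locus_prob_matrix(g1, g2, freqs)
    k, ll = _grid_argmax(P)
    if refine:
        def neg(kv):
            k0, k1 = kv
            k2 = 1.0 - k0 - k1
            lik = P @ np.array([k0, k1, k2])
            return -float(np.sum(np.log(np.maximum(lik, _TINY))))

        res = minimize(
            neg,
            x0=[k[0], k[1]],
            method="SLSQP",
            bounds=[(0.0, 1.0), (0.0, 1.0)],
            constraints=[{"type": "ineq", "fun": lambda kv: 1.0 - kv[0] - kv[1]}],
            options={"ftol": 1e-12, "maxiter": 200},
        )
        if res.success and -res.fun >= ll:
            k = (float(res.x[0]), float(res.x[1]), float(1.0 - res.x[0] - res.x[1]))
            ll = -float(res.fun)
    return RelatednessEstimate(k=k, r=r_from_k(k), loglik=ll, n_loci=P.shape[0])


def classify_relationship(
    g1: Mapping[str, Optional[Genotype]],
    g2: Mapping[str, Optional[Genotype]],
    freqs: AlleleFrequencies,
) -> tuple[str, dict[str, float]]:
    """Most likely of the four anchor relationships (U, HS, FS, PO).

    Ties are broken toward the less related category.  A locus where
    the pair shares no allele makes PO impossible (log-likelihood -inf).
    """
    P = _locus_prob_matrix(g1, g2, freqs)
    logliks = {}
    for name in ANCHOR_ORDER:
        lik = P @ np.asarray(ANCHORS[name])
        if np.any(lik <= 0.0):
            logliks[name] = -math.inf
        else:
            logliks[name] = float(np.sum(np.log(lik)))
    best = max(ANCHOR_ORDER, key=lambda nm: (logliks[nm], -ANCHOR_ORDER.index(nm)))
    return best, logliks


# ---------------------------------------------------------------- matrix

@dataclass
class RelatednessMatrix:
    individuals: list[str]
    r: np.ndarray  # symmetric, NaN diagonal
    categories: list[list[Optional[str]]]
    n_cotyped: np.ndarray

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.individuals), k=1)
        return self.r[iu]


def relatedness_matrix(
    table: GenotypeTable, freqs: Optional[AlleleFrequencies] = None
) -> RelatednessMatrix:
    """Pairwise ML relatedness and anchor categories for all dyads."""
    if freqs is None:
        freqs = allele_frequencies(table)
    ids = table.samples
    n = len(ids)
    r = np.full((n, n), np.nan)
    cats: list[list[Optional[str]]] = [[None] * n for _ in range(n)]
    cot = np.zeros((n, n), dtype=int)
    gmaps = [{l: table.genotype(s, l) for l in table.loci} for s in ids]
    for i in range(n):
        for j in range(i + 1, n):
            est = estimate_r_ml(gmaps[i], gmaps[j], freqs)
            cat, _ = classify_relationship(gmaps[i], gmaps[j], freqs)
            r[i, j] = r[j, i] = est.r
            cats[i][j] = cats[j][i] = cat
            cot[i, j] = cot[j, i] = est.n_loci
    return RelatednessMatrix(individuals=list(ids), r=r, categories=cats, n_cotyped=cot)


@dataclass
class RelatednessSummary:
    n_pairs: int
    mean: float
    sd: float
    n_low: int       # r < low threshold ("near zero" pairs)
    n_ge_high: int   # r >= high threshold
    n_gt_high: int   # r > high threshold
    low: float
    high: float


def summarize_relatedness(
    values: np.ndarray | Sequence[float] | RelatednessMatrix,
    low: float = 0.25,
    high: float = 0.5,
) -> RelatednessSummary:
    """Mean/SD and threshold counts over the unordered pairs.

    Accepts a :class:`RelatednessMatrix` (upper triangle is used) or a
    flat array of pairwise values.
    """
    if isinstance(values, RelatednessMatrix):
        v = values.upper_triangle()
    else:
        v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValidationError("no pairwise values to summarize")
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return RelatednessSummary(
        n_pairs=len(v),
        mean=float(np.mean(v)),
        sd=sd,
        n_low=int(np.sum(v < low)),
        n_ge_high=int(np.sum(v >= high)),
        n_gt_high=int(np.sum(v > high)),
        low=low,
        high=high,
    )


# ---------------------------------------------------------------- inbreeding

_F_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass
class InbreedingEstimate:
    individual_id: str
    f: float
    ci: tuple[float, float]
    n_loci: int


def _f_loglik_rows(
    genotype: Mapping[str, Optional[Genotype]], freqs: AlleleFrequencies
) -> np.ndarray:
    """Per-locus log P(g|F) evaluated on the F grid; shape (L, len(grid))."""
    rows = []
    for locus, p in freqs.items():
        g = genotype.get(locus)
        if g is None or len(p) < 2:
            continue
        a, b = g
        if a == b:
            pa = p[a]
            lik = pa**2 + _F_GRID * pa * (1.0 - pa)
        else:
            lik = 2.0 * p[a] * p[b] * (1.0 - _F_GRID)
        rows.append(np.log(np.maximum(lik, _TINY)))
    if len(rows) < 3:
        raise ValidationError("need >= 3 typed polymorphic loci to estimate F")
    return np.asarray(rows)


def estimate_F_ml(
    genotype: Mapping[str, Optional[Genotype]],
    freqs: AlleleFrequencies,
    n_boot: int = 100,
    seed: int = 0,
    individual_id: str = "",
) -> InbreedingEstimate:
    """ML inbreeding coefficient with a percentile bootstrap over loci.

    The likelihood is linear in F per locus, so a dense grid on [0, 1]
    locates the product maximum to 1e-3; bootstrap replicates resample
    loci with replacement.
    """
    rows = _f_loglik_rows(genotype, freqs)
    f_hat = float(_F_GRID[int(np.argmax(rows.sum(axis=0)))])
    L = rows.shape[0]
    if n_boot == 0:
        return InbreedingEstimate(
            individual_id=individual_id, f=f_hat, ci=(math.nan, math.nan), n_loci=L
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, L, size=(n_boot, L))
    boot_ll = rows[idx].sum(axis=1)  # (n_boot, grid)
    boot_f = _F_GRID[np.argmax(boot_ll, axis=1)]
    lo, hi = np.percentile(boot_f, [2.5, 97.5])
    return InbreedingEstimate(
        individual_id=individual_id, f=f_hat, ci=(float(lo), float(hi)), n_loci=L
    )


def estimate_F_all(
    table: GenotypeTable,
    freqs: Optional[AlleleFrequencies] = None,
    n_boot: int = 100,
    seed: int = 0,
) -> list[InbreedingEstimate]:
    if freqs is None:
        freqs = allele_frequencies(table)
    out = []
    for i, s in enumerate(table.samples):
        gmap = {l: table.genotype(s, l) for l in table.loci}
        out.append(
            estimate_F_ml(gmap, freqs, n_boot=n_boot, seed=seed + i, individual_id=s)
        )
    return out
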
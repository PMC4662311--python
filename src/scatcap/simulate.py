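"""Synthetic scat-survey generator with truth tables.

Simulates every layer the analysis consumes: a pedigreed population
with Mendelian microsatellite genotypes, activity centers on a habitat
polygon, half-normal spatial detection of scats along transect
detectors, species mixture (bobcat / coyote / unreadable) via mtDNA
fragment lengths, and replicate-PCR genotyping with allelic dropout,
false alleles and reaction failure.  Every stochastic layer is driven
by one integer seed, and truth tables (genotypes, pedigree inbreeding,
relationship categories, activity centers, scat-to-individual map) are
returned for parameter-recovery tests.

The default configuration mirrors a small insular felid survey: 12
polymorphic loci with 3-5 alleles each, 9 individuals, 2 search
occasions over ~29 km of transects on a 3 x 10 km island, half-normal
detection (sigma = 700 m), and a scat-quality mixture tuned so roughly
half the collected bobcat scats survive the consensus filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .dtypes import (
    ConfigError,
    Genotype,
    GenotypeTable,
    ReplicateRecord,
    ReplicateSet,
    SurveyGeometry,
)
from .popgen import AlleleFrequencies
from .secr import DetectorArray, segment_transects

# ---------------------------------------------------------------- config

@dataclass
class PedigreeSpec:
    """Founder count and simple mating rules for generating relatives."""

    n_founders: int = 9
    n_generations: int = 0
    offspring_per_generation: int = 0
    selfing_rate: float = 0.0  # probability an offspring is produced by selfing

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ConfigError("need at least one founder")
        if not 0 <= self.selfing_rate <= 1:
            raise ConfigError("selfing_rate must lie in [0, 1]")


@dataclass
class SimulationConfig:
    n_loci: int = 12
    alleles_per_locus: int | Sequence[int] = (4, 3, 5, 4, 3, 5, 4, 4, 3, 5, 4, 4)
    founder_allele_freqs: Optional[AlleleFrequencies] = None  # equal freqs if None
    pedigree: PedigreeSpec = field(default_factory=PedigreeSpec)

    # spatial detection
    g0: float = 0.16
    sigma_m: float = 700.0
    n_occasions: int = 2
    section_length_m: float = 200.0

    # replicate-PCR error model
    n_replicates: int = 4
    dropout_rate: float = 0.10
    false_allele_rate: float = 0.02
    pcr_failure_rate: float = 0.15
    # a fraction of scats is environmentally degraded and fails almost always,
    # reproducing per-locus amplification rates well below 50%
    degraded_fraction: float = 0.5
    degraded_failure_rate: float = 0.95

    # species mixture (non-target scats exercise the mtDNA classifier)
    n_coyote_scats: int = 46
    n_unreadable_scats: int = 26
    bobcat_fragment_bp: float = 180.0
    coyote_fragment_bp: float = 196.0
    fragment_sd_bp: float = 0.5

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("g0", "dropout_rate", "false_allele_rate", "pcr_failure_rate",
                     "degraded_fraction", "degraded_failure_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0 < self.g0 < 1:
            raise ConfigError("g0 must lie in (0, 1)")
        if self.sigma_m <= 0:
            raise ConfigError("sigma_m must be positive")
        if isinstance(self.alleles_per_locus, int):
            if self.alleles_per_locus < 1:
                raise ConfigError("alleles_per_locus must be >= 1")
        elif len(self.alleles_per_locus) != self.n_loci:
            raise ConfigError("alleles_per_locus list must have n_loci entries")
        if self.founder_allele_freqs is not None:
            for locus, p in self.founder_allele_freqs.items():
                if len(p) == 0:
                    raise ConfigError(f"locus {locus} has no alleles")
                if abs(sum(p.values()) - 1.0) > 1e-9:
                    raise ConfigError(f"frequencies at {locus} do not sum to 1")

    @property
    def loci(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_loci)]

    def freqs(self) -> AlleleFrequencies:
        """Founder allele frequencies (equal per locus unless given)."""
        if self.founder_allele_freqs is not None:
            return self.founder_allele_freqs
        ks = (
            [self.alleles_per_locus] * self.n_loci
            if isinstance(self.alleles_per_locus, int)
            else list(self.alleles_per_locus)
        )
        out: AlleleFrequencies = {}
        for i, (locus, k) in enumerate(zip(self.loci, ks)):
            alleles = [100 + 6 * i + 2 * j for j in range(k)]  # a dinucleotide ladder
            out[locus] = {a: 1.0 / k for a in alleles}
        return out

# ---------------------------------------------------------------- pedigree

@dataclass
class TruthRecord:
    individual_id: str
    genotype: dict[str, Genotype]
    f_pedigree: float
    parents: tuple[Optional[str], Optional[str]]
    activity_center: Optional[tuple[float, float]] = None


@dataclass
class Population:
    records: list[TruthRecord]
    kinship: np.ndarray  # pedigree kinship matrix over all individuals
    config: SimulationConfig

    @property
    def ids(self) -> list[str]:
        return [r.individual_id for r in self.records]

    def record(self, individual_id: str) -> TruthRecord:
        return next(r for r in self.records if r.individual_id == individual_id)

    def genotype_table(self) -> GenotypeTable:
        loci = self.config.loci
        calls = {
            (r.individual_id, l): r.genotype[l] for r in self.records for l in loci
        }
        return GenotypeTable(self.ids, loci, calls)

    def relationship(self, id1: str, id2: str) -> str:
        """Pedigree relationship category: PO, FS, HS or U."""
        r1, r2 = self.record(id1), self.record(id2)
        if id2 in r1.parents or id1 in r2.parents:
            return "PO"
        p1 = set(p for p in r1.parents if p is not None)
        p2 = set(p for p in r2.parents if p is not None)
        if p1 and p1 == p2 and len(p1) == 2:
            return "FS"
        if p1 and p2 and len(p1 & p2) >= 1:
            return "HS" if len(p1 & p2) == 1 else "FS"
        return "U"


def _draw_hwe_genotype(p: Mapping[int, float], rng: np.random.Generator) -> Genotype:
    alleles = np.array(list(p.keys()))
    probs = np.array(list(p.values()))
    a, b = rng.choice(alleles, size=2, p=probs / probs.sum())
    return (int(a), int(b)) if a <= b else (int(b), int(a))


def _mendelian_child(g1: Genotype, g2: Genotype, rng: np.random.Generator) -> Genotype:
    a = g1[rng.integers(2)]
    b = g2[rng.integers(2)]
    return (a, b) if a <= b else (b, a)


def generate_population(
    config: SimulationConfig, seed: Optional[int] = None
) -> Population:
    """Simulate the pedigreed population and its multilocus genotypes.

    Founders are drawn from Hardy-Weinberg proportions at the
    configured allele frequencies; each offspring receives one
    uniformly chosen allele from each parent per locus.  Pedigree
    inbreeding F and the kinship matrix are computed by the tabular
    recursion, so truth values are exact for any mating scheme.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    freqs = config.freqs()
    ped = config.pedigree
    records: list[TruthRecord] = []
    index: dict[str, int] = {}
    parent_idx: list[tuple[Optional[int], Optional[int]]] = []
    kin = np.zeros((0, 0))

    def add(individual_id, genotype, pi1, pi2):
        nonlocal kin
        n = len(records)
        new = np.zeros((n + 1, n + 1))
        new[:n, :n] = kin
        for j in range(n):
            if pi1 is None:
                new[n, j] = new[j, n] = 0.0
            else:
                new[n, j] = new[j, n] = 0.5 * (new[pi1, j] + new[pi2, j])
        f = 0.0 if pi1 is None else new[pi1, pi2]
        new[n, n] = 0.5 * (1.0 + f)
        kin = new
        p1 = records[pi1].individual_id if pi1 is not None else None
        p2 = records[pi2].individual_id if pi2 is not None else None
        records.append(TruthRecord(individual_id, genotype, f, (p1, p2)))
        index[individual_id] = n
        parent_idx.append((pi1, pi2))

    for i in range(ped.n_founders):
        g = {l: _draw_hwe_genotype(freqs[l], rng) for l in config.loci}
        add(f"F{i + 1:03d}", g, None, None)

    current = list(range(ped.n_founders))
    for gen in range(ped.n_generations):
        nxt = []
        for c in range(ped.offspring_per_generation):
            if rng.random() < ped.selfing_rate or len(current) == 1:
                pi1 = pi2 = int(rng.choice(current))
            else:
                pi1, pi2 = (int(v) for v in rng.choice(current, size=2, replace=False))
            g1 = records[pi1].genotype
            g2 = records[pi2].genotype
            g = {l: _mendelian_child(g1[l], g2[l], rng) for l in config.loci}
            add(f"G{gen + 1}I{c + 1:03d}", g, pi1, pi2)
            nxt.append(len(records) - 1)
        current = nxt
    return Population(records=records, kinship=kin, config=config)


def surveyed_cohort(pop: Population) -> list[TruthRecord]:
    """The individuals alive at survey time: the final generation, or
    the founders when no offspring generations were simulated."""
    ped = pop.config.pedigree
    if ped.n_generations == 0:
        return pop.records
    n_off = ped.offspring_per_generation
    return pop.records[-n_off:]

# ---------------------------------------------------------------- geometry

def default_geometry() -> SurveyGeometry:
    """Fixture survey frame: a 3 x 10 km island rectangle with three
    10 km longitudinal transects ~750 m apart."""
    habitat = Polygon([(0, 0), (3000, 0), (3000, 10000), (0, 10000)])
    transects = [
        LineString([(x, 200), (x, 9800)]) for x in (750.0, 1500.0, 2250.0)
    ]
    detections = pd.DataFrame(columns=["scat_id", "x", "y", "occasion"])
    return SurveyGeometry(transects=transects, habitat=habitat, detections=detections)


def draw_activity_centers(
    n: int, habitat: Polygon, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draws over the habitat polygon (rejection from the bbox)."""
    minx, miny, maxx, maxy = habitat.bounds
    out = []
    while len(out) < n:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if habitat.contains(Point(x, y)):
            out.append((x, y))
    return np.asarray(out)


def simulate_survey(
    centers: np.ndarray,
    individual_ids: Sequence[str],
    detectors: DetectorArray,
    g0: float,
    sigma_m: float,
    n_occasions: int,
    rng: np.random.Generator,
    scat_prefix: str = "S",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Half-normal Bernoulli detection of each individual at each
    detector and occasion; every detection deposits one scat at the
    detector's location.  Returns the detections table and the true
    scat-to-individual map."""
    if sigma_m <= 0:
        raise ConfigError("sigma_m must be positive")
    if not 0 <= g0 < 1:
        raise ConfigError("g0 must lie in [0, 1)")
    dx = centers[:, 0][:, None] - detectors.coords[:, 0][None, :]
    dy = centers[:, 1][:, None] - detectors.coords[:, 1][None, :]
    p = g0 * np.exp(-(dx**2 + dy**2) / (2.0 * sigma_m**2))  # (n, J)
    rows = []
    truth: dict[str, str] = {}
    counter = 1
    for k in range(1, n_occasions + 1):
        hits = rng.random(p.shape) < p
        for i, j in zip(*np.nonzero(hits)):
            sid = f"{scat_prefix}{counter:04d}"
            counter += 1
            rows.append((sid, detectors.coords[j, 0], detectors.coords[j, 1], k))
            truth[sid] = individual_ids[i]
    det = pd.DataFrame(rows, columns=["scat_id", "x", "y", "occasion"])
    return det, truth

# ---------------------------------------------------------------- PCR

def simulate_pcr_replicates(
    scat_genotypes: Mapping[str, Mapping[str, Genotype]],
    config: SimulationConfig,
    rng: np.random.Generator,
    failure_rates: Optional[Mapping[str, float]] = None,
) -> ReplicateSet:
    """Replicate-PCR observations of each scat's true genotype.

    Per PCR x locus: the reaction fails with the scat's failure rate;
    otherwise each allele of a heterozygote independently drops out
    with ``dropout_rate`` (both dropping means a failed reaction), and
    each surviving allele copy is replaced by a random *other* allele
    of that locus with ``false_allele_rate`` (so records stay diploid).
    """
    freqs = config.freqs()
    universe = {l: sorted(freqs[l]) for l in freqs}
    records = []
    for sid in scat_genotypes:
        fail = (
            failure_rates[sid] if failure_rates is not None else config.pcr_failure_rate
        )
        for locus, g in scat_genotypes[sid].items():
            for rep in range(1, config.n_replicates + 1):
                pcr_id = f"PCR{rep}"
                if rng.random() < fail:
                    records.append(ReplicateRecord(sid, pcr_id, locus, None))
                    continue
                alleles = list(g)
                if g[0] != g[1]:  # heterozygote: allelic dropout
                    kept = [a for a in alleles if rng.random() >= config.dropout_rate]
                    if not kept:
                        records.append(ReplicateRecord(sid, pcr_id, locus, None))
                        continue
                    alleles = kept if len(kept) == 2 else [kept[0], kept[0]]
                out = []
                for a in alleles:
                    if rng.random() < config.false_allele_rate:
                        others = [x for x in universe[locus] if x != a]
                        a = int(rng.choice(others)) if others else a
                    out.append(a)
                call = (min(out), max(out))
                records.append(ReplicateRecord(sid, pcr_id, locus, call))
    return ReplicateSet(records)

# ---------------------------------------------------------------- dyads

def simulate_dyad(
    category: str, freqs: AlleleFrequencies, rng: np.random.Generator
) -> tuple[dict[str, Genotype], dict[str, Genotype]]:
    """One dyad with the requested pedigree relationship (U/HS/FS/PO)."""
    g1, g2 = {}, {}
    parents = {l: [_draw_hwe_genotype(freqs[l], rng) for _ in range(4)] for l in freqs}
    for l, (pa, pb, pc, pd_) in parents.items():
        if category == "U":
            g1[l] = _mendelian_child(pa, pb, rng)
            g2[l] = _mendelian_child(pc, pd_, rng)
        elif category == "PO":
            g1[l] = _mendelian_child(pa, pb, rng)
            g2[l] = _mendelian_child(g1[l], pc, rng)
        elif category == "FS":
            g1[l] = _mendelian_child(pa, pb, rng)
            g2[l] = _mendelian_child(pa, pb, rng)
        elif category == "HS":
            g1[l] = _mendelian_child(pa, pb, rng)
            g2[l] = _mendelian_child(pa, pc, rng)
        else:
            raise ConfigError(f"unknown dyad category {category!r}")
    return g1, g2


def simulate_selfed(
    freqs: AlleleFrequencies, n: int, rng: np.random.Generator
) -> list[dict[str, Genotype]]:
    """Offspring of one generation of selfing (pedigree F = 1/2)."""
    out = []
    for _ in range(n):
        parent = {l: _draw_hwe_genotype(freqs[l], rng) for l in freqs}
        out.append({l: _mendelian_child(g, g, rng) for l, g in parent.items()})
    return out

# ---------------------------------------------------------------- dataset

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    population: Population
    geometry: SurveyGeometry
    detectors: DetectorArray
    species: pd.DataFrame  # scat_id, fragment_length_bp
    replicates: ReplicateSet
    scat_to_individual: dict[str, str]  # truth, bobcat scats only
    activity_centers: dict[str, tuple[float, float]]


def simulate_dataset(
    config: Optional[SimulationConfig] = None, seed: Optional[int] = None
) -> SimulatedDataset:
    """Full synthetic survey: population, scats, species mixture and PCRs."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pop = generate_population(config, seed=int(rng.integers(2**31)))
    cohort = surveyed_cohort(pop)
    geom = default_geometry()
    detectors = segment_transects(geom.transects, config.section_length_m)
    centers = draw_activity_centers(len(cohort), geom.habitat, rng)
    for rec, c in zip(cohort, centers):
        rec.activity_center = (float(c[0]), float(c[1]))
    det, truth = simulate_survey(
        centers,
        [r.individual_id for r in cohort],
        detectors,
        config.g0,
        config.sigma_m,
        config.n_occasions,
        rng,
    )

    # species mixture: non-target scats scattered along the transects
    extra_rows = []
    frag_rows = []
    for sid in det["scat_id"]:
        frag_rows.append(
            (sid, config.bobcat_fragment_bp + rng.normal(0, config.fragment_sd_bp))
        )
    n_extra = config.n_coyote_scats + config.n_unreadable_scats
    for i in range(n_extra):
        line = geom.transects[int(rng.integers(len(geom.transects)))]
        pt = line.interpolate(rng.uniform(0, line.length))
        sid = f"X{i + 1:04d}"
        occ = int(rng.integers(1, config.n_occasions + 1))
        extra_rows.append((sid, pt.x, pt.y, occ))
        if i < config.n_coyote_scats:
            frag_rows.append(
                (sid, config.coyote_fragment_bp + rng.normal(0, config.fragment_sd_bp))
            )
        else:
            frag_rows.append((sid, math.nan))
    detections = pd.concat(
        [det, pd.DataFrame(extra_rows, columns=det.columns)], ignore_index=True
    )
    geom = SurveyGeometry(geom.transects, geom.habitat, detections)
    species = pd.DataFrame(frag_rows, columns=["scat_id", "fragment_length_bp"])

    # degraded-scat mixture controls per-scat PCR failure
    genotypes = {
        sid: pop.record(ind).genotype for sid, ind in truth.items()
    }
    failure_rates = {
        sid: (
            config.degraded_failure_rate
            if rng.random() < config.degraded_fraction
            else config.pcr_failure_rate
        )
        for sid in genotypes
    }
    reps = simulate_pcr_replicates(genotypes, config, rng, failure_rates)
    centers_map = {
        r.individual_id: r.activity_center for r in cohort
    }
    return SimulatedDataset(
        config=config,
        population=pop,
        geometry=geom,
        detectors=detectors,
        species=species,
        replicates=reps,
        scat_to_individual=truth,
        activity_centers=centers_map,
    )
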
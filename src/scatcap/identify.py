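"""Probability of identity, profile matching, and scat-to-individual clustering.

Whether a multilocus genotype panel can distinguish individuals is
quantified by the probability of identity: the chance two individuals
drawn from the population share an identical multilocus genotype.  For
unrelated individuals at one locus,

    PID = 2 (sum p_i^2)^2 - sum p_i^4,

and for full siblings (the conservative benchmark, since relatives share
genotypes far more often),

    PIDsib = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4.

Loci combine by multiplication (independence).  Scats whose consensus
profiles match at enough co-typed loci are grouped into individuals by
transitive closure, and a composite genotype is built per individual.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .consensus import ScatProfile
from .dtypes import Genotype, GenotypeTable


# ---------------------------------------------------------------- PID

@dataclass
class PIDResult:
    per_locus: dict[str, float]
    cumulative: float
    below_threshold: Optional[bool] = None


def _pid_unrelated_locus(p: np.ndarray) -> float:
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 2.0 * s2**2 - s4


def _pid_sib_locus(p: np.ndarray) -> float:
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4


def _pid(freqs: Mapping[str, Mapping[int, float]], locus_fn) -> tuple[dict[str, float], float]:
    per_locus = {}
    cumulative = 1.0
    for locus, pdict in freqs.items():
        p = np.asarray(list(pdict.values()), dtype=float)
        val = locus_fn(p)
        per_locus[locus] = val
        cumulative *= val
    return per_locus, cumulative


def pid_unrelated(freqs: Mapping[str, Mapping[int, float]]) -> PIDResult:
    """Probability two unrelated individuals share the full multilocus genotype."""
    per_locus, cumulative = _pid(freqs, _pid_unrelated_locus)
    return PIDResult(per_locus, cumulative)


def pid_sib(
    freqs: Mapping[str, Mapping[int, float]], threshold: float = 1e-6
) -> PIDResult:
    """Probability two full siblings share the full multilocus genotype.

    Also reports whether the cumulative value clears ``threshold`` —
    the criterion for treating identical profiles as one individual.
    """
    per_locus, cumulative = _pid(freqs, _pid_sib_locus)
    return PIDResult(per_locus, cumulative, below_threshold=cumulative < threshold)


# ---------------------------------------------------------------- matching

class MatchDecision(str, Enum):
    SAME = "SAME"
    DIFFERENT = "DIFFERENT"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class MatchResult:
    decision: MatchDecision
    n_compared: int
    n_match: int
    n_mismatch: int


def match_profiles(
    a: ScatProfile | Mapping[str, Genotype],
    b: ScatProfile | Mapping[str, Genotype],
    min_match: int = 5,
    max_mismatch: int = 0,
) -> MatchResult:
    """Compare two profiles at their co-typed loci.

    SAME requires at least ``min_match`` equal loci and at most
    ``max_mismatch`` unequal ones; genotypes compare as unordered
    pairs.  With no co-typed locus the comparison is INDETERMINATE.
    """
    ga = {l: a.genotype(l) for l in a.calls} if isinstance(a, ScatProfile) else dict(a)
    gb = {l: b.genotype(l) for l in b.calls} if isinstance(b, ScatProfile) else dict(b)
    shared = [l for l in ga if ga[l] is not None and gb.get(l) is not None]
    n_match = sum(1 for l in shared if ga[l] == gb[l])
    n_mismatch = len(shared) - n_match
    if not shared:
        return MatchResult(MatchDecision.INDETERMINATE, 0, 0, 0)
    same = n_match >= min_match and n_mismatch <= max_mismatch
    decision = MatchDecision.SAME if same else MatchDecision.DIFFERENT
    return MatchResult(decision, len(shared), n_match, n_mismatch)


def table_to_profiles(table: GenotypeTable, min_consensus: int = 6) -> list[ScatProfile]:
    """Wrap a per-scat genotype table as retained-or-not scat profiles.

    Used when matching starts from an already-called genotype table
    rather than from replicate PCRs; every call gets unit support.
    """
    from .consensus import CallStatus, LocusCall, Species

    out = []
    for s in table.samples:
        prof = ScatProfile(scat_id=s, species=Species.BOBCAT)
        for l in table.loci:
            g = table.genotype(s, l)
            if g is None:
                continue
            status = CallStatus.ACCEPTED_HOM if g[0] == g[1] else CallStatus.ACCEPTED_HET
            prof.calls[l] = LocusCall(s, l, status, g, 1, 1)
        prof.n_amplified_loci = len(prof.calls)
        prof.n_consensus_loci = len(prof.calls)
        prof.passed_screen = True
        prof.retained = prof.n_consensus_loci >= min_consensus
        out.append(prof)
    return out


# ---------------------------------------------------------------- clustering

@dataclass
class IndividualRecord:
    individual_id: str
    scat_ids: list[str]
    composite: dict[str, Optional[Genotype]]
    n_loci_typed: int
    support: dict[str, int]
    inconsistent: bool = False  # cluster contains a DIFFERENT pair (chaining)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _composite_genotype(
    members: Sequence[ScatProfile], loci: Sequence[str]
) -> tuple[dict[str, Optional[Genotype]], dict[str, int]]:
    composite: dict[str, Optional[Genotype]] = {}
    support: dict[str, int] = {}
    for l in loci:
        counts: dict[Genotype, int] = {}
        for p in members:
            g = p.genotype(l)
            if g is not None:
                counts[g] = counts.get(g, 0) + 1
        if not counts:
            continue
        best = max(counts.values())
        winners = sorted(g for g, c in counts.items() if c == best)
        # majority vote; an exact tie between distinct genotypes -> MISSING
        composite[l] = winners[0] if len(winners) == 1 else None
        support[l] = best if len(winners) == 1 else 0
    return composite, support


def cluster_scats(
    profiles: Sequence[ScatProfile],
    min_match: int = 5,
    max_mismatch: int = 0,
) -> list[IndividualRecord]:
    """Group retained scat profiles into individuals.

    SAME decisions are closed transitively (union-find), so the result
    does not depend on input order.  Clusters that also contain a
    DIFFERENT pair (possible through chaining) are flagged rather than
    split.
    """
    profs = sorted((p for p in profiles if p.retained), key=lambda p: p.scat_id)
    n = len(profs)
    uf = _UnionFind(n)
    decisions: dict[tuple[int, int], MatchDecision] = {}
    for i in range(n):
        for j in range(i + 1, n):
            res = match_profiles(profs[i], profs[j], min_match, max_mismatch)
            decisions[(i, j)] = res.decision
            if res.decision == MatchDecision.SAME:
                uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)
    loci = sorted({l for p in profs for l in p.calls})
    out = []
    for k, root in enumerate(sorted(clusters), start=1):
        idx = clusters[root]
        members = [profs[i] for i in idx]
        composite, support = _composite_genotype(members, loci)
        inconsistent = any(
            decisions[(min(i, j), max(i, j))] == MatchDecision.DIFFERENT
            for ii, i in enumerate(idx)
            for j in idx[ii + 1 :]
        )
        out.append(
            IndividualRecord(
                individual_id=f"IND{k:02d}",
                scat_ids=[p.scat_id for p in members],
                composite=composite,
                n_loci_typed=sum(1 for g in composite.values() if g is not None),
                support=support,
                inconsistent=inconsistent,
            )
        )
    return out


def individuals_to_genotype_table(individuals: Sequence[IndividualRecord]) -> GenotypeTable:
    """Composite genotypes as a table, one row per identified individual.

    Allele frequencies for PID and downstream statistics are computed
    from this table, not from per-scat profiles, so re-sampled animals
    are not over-weighted.
    """
    loci = sorted({l for ind in individuals for l in ind.composite})
    calls = {
        (ind.individual_id, l): g
        for ind in individuals
        for l, g in ind.composite.items()
        if g is not None
    }
    return GenotypeTable([ind.individual_id for ind in individuals], loci, calls)
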
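"""Species assignment and consensus genotype calling from replicate PCRs.

Fecal DNA is degraded and dilute, so single PCRs suffer allelic dropout
(one allele of a heterozygote fails to amplify) and false alleles.  The
guard is replication: a heterozygous genotype is accepted only when the
identical unordered allele pair is seen in at least ``min_obs``
successful PCRs, and a homozygote only when *every* successful PCR shows
that single allele and at least ``min_obs`` of them did.  Failed
reactions count neither for nor against a call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .dtypes import (
    ConfigError,
    Genotype,
    GenotypeTable,
    ReplicateRecord,
    ReplicateSet,
    is_het,
)


class Species(str, Enum):
    BOBCAT = "BOBCAT"
    COYOTE = "COYOTE"
    UNKNOWN = "UNKNOWN"


class CallStatus(str, Enum):
    ACCEPTED_HET = "ACCEPTED_HET"
    ACCEPTED_HOM = "ACCEPTED_HOM"
    NO_CALL = "NO_CALL"
    ALL_FAILED = "ALL_FAILED"


def classify_species(
    fragment_length_bp: Optional[float],
    reference_lengths: Mapping[str, float],
    tolerance_bp: float = 3.0,
) -> Species:
    """Assign species from the mtDNA control-region fragment length.

    The diagnostic fragment differs in size between bobcat and coyote
    (a 16 bp gap), so a length within ``tolerance_bp`` of exactly one
    reference length identifies the species; anything else (no
    fragment, out of window, or ambiguous) is UNKNOWN.
    """
    refs = {Species(k.upper()): float(v) for k, v in reference_lengths.items()}
    if Species.BOBCAT not in refs or Species.COYOTE not in refs:
        raise ConfigError("reference lengths required for both BOBCAT and COYOTE")
    gap = abs(refs[Species.BOBCAT] - refs[Species.COYOTE])
    if tolerance_bp >= gap / 2:
        raise ConfigError(
            f"tolerance {tolerance_bp} bp overlaps the {gap} bp inter-species gap"
        )
    if fragment_length_bp is None:
        return Species.UNKNOWN
    hits = [sp for sp, ref in refs.items() if abs(fragment_length_bp - ref) <= tolerance_bp]
    return hits[0] if len(hits) == 1 else Species.UNKNOWN


@dataclass(frozen=True)
class LocusCall:
    """Consensus decision for one scat x locus."""

    scat_id: str
    locus_id: str
    status: CallStatus
    genotype: Optional[Genotype]
    n_successful_pcrs: int
    n_supporting_pcrs: int


def call_locus_consensus(
    replicates: Sequence[ReplicateRecord], min_obs: int = 3
) -> LocusCall:
    """Call the consensus genotype for one scat x locus from its replicates.

    Replicate order never affects the result.  With no successful
    reaction the status is ALL_FAILED; with successful reactions that
    satisfy neither acceptance rule, NO_CALL.
    """
    if not replicates:
        return LocusCall("", "", CallStatus.ALL_FAILED, None, 0, 0)
    scat_id = replicates[0].scat_id
    locus_id = replicates[0].locus_id
    successes = [r.call for r in replicates if r.call is not None]
    if not successes:
        return LocusCall(scat_id, locus_id, CallStatus.ALL_FAILED, None, 0, 0)

    # heterozygote rule: identical unordered pair in >= min_obs successes
    het_counts: dict[Genotype, int] = {}
    for g in successes:
        if is_het(g):
            het_counts[g] = het_counts.get(g, 0) + 1
    het_hits = sorted(
        (g for g, c in het_counts.items() if c >= min_obs),
        key=lambda g: -het_counts[g],
    )
    if het_hits:
        g = het_hits[0]
        return LocusCall(
            scat_id, locus_id, CallStatus.ACCEPTED_HET, g, len(successes), het_counts[g]
        )

    # homozygote rule: every successful PCR shows only allele a, >= min_obs of them
    alleles = {a for g in successes for a in g}
    if len(alleles) == 1 and len(successes) >= min_obs:
        a = alleles.pop()
        return LocusCall(
            scat_id, locus_id, CallStatus.ACCEPTED_HOM, (a, a), len(successes), len(successes)
        )
    return LocusCall(scat_id, locus_id, CallStatus.NO_CALL, None, len(successes), 0)


@dataclass
class ScatProfile:
    """Per-scat consensus profile with retention bookkeeping.

    A scat is *retained* for downstream identity analysis only when it
    is a bobcat and produced accepted consensus genotypes at
    ``min_consensus`` or more loci.  Scats amplifying at fewer than
    ``min_amplified`` loci are screened out earlier.
    """

    scat_id: str
    species: Species
    calls: dict[str, LocusCall] = field(default_factory=dict)
    n_amplified_loci: int = 0
    n_consensus_loci: int = 0
    passed_screen: bool = False
    retained: bool = False

    def genotype(self, locus_id: str) -> Optional[Genotype]:
        call = self.calls.get(locus_id)
        return call.genotype if call is not None else None

    @property
    def consensus_loci(self) -> list[str]:
        return [l for l, c in self.calls.items() if c.genotype is not None]


def build_scat_profile(
    replicates: ReplicateSet,
    scat_id: str,
    species: Species,
    min_obs: int = 3,
    min_amplified: int = 4,
    min_consensus: int = 6,
) -> ScatProfile:
    """Consensus-call every locus of one scat and apply the retention rules."""
    profile = ScatProfile(scat_id=scat_id, species=species)
    by_locus: dict[str, list[ReplicateRecord]] = {}
    for r in replicates.for_scat(scat_id):
        by_locus.setdefault(r.locus_id, []).append(r)
    for locus_id in sorted(by_locus):
        profile.calls[locus_id] = call_locus_consensus(by_locus[locus_id], min_obs=min_obs)
    profile.n_amplified_loci = sum(
        1 for c in profile.calls.values() if c.n_successful_pcrs > 0
    )
    profile.n_consensus_loci = sum(1 for c in profile.calls.values() if c.genotype is not None)
    profile.passed_screen = profile.n_amplified_loci >= min_amplified
    profile.retained = (
        species == Species.BOBCAT
        and profile.passed_screen
        and profile.n_consensus_loci >= min_consensus
    )
    return profile


def build_all_profiles(
    replicates: ReplicateSet,
    species_map: Mapping[str, Species],
    min_obs: int = 3,
    min_amplified: int = 4,
    min_consensus: int = 6,
) -> list[ScatProfile]:
    return [
        build_scat_profile(
            replicates,
            scat_id,
            species_map.get(scat_id, Species.UNKNOWN),
            min_obs=min_obs,
            min_amplified=min_amplified,
            min_consensus=min_consensus,
        )
        for scat_id in replicates.scat_ids
    ]


def amplification_rates(replicates: ReplicateSet) -> dict[str, float]:
    """Per-locus fraction of PCR reactions that produced a readable call."""
    totals: dict[str, int] = {}
    wins: dict[str, int] = {}
    for r in replicates.records:
        totals[r.locus_id] = totals.get(r.locus_id, 0) + 1
        if r.call is not None:
            wins[r.locus_id] = wins.get(r.locus_id, 0) + 1
    return {l: wins.get(l, 0) / totals[l] for l in totals}


def genotyping_rates(profiles: Sequence[ScatProfile]) -> dict[str, float]:
    """Per-locus fraction of scats with an accepted consensus genotype."""
    if not profiles:
        return {}
    loci = sorted({l for p in profiles for l in p.calls})
    out = {}
    for l in loci:
        n = sum(1 for p in profiles if l in p.calls)
        ok = sum(1 for p in profiles if p.genotype(l) is not None)
        out[l] = ok / n if n else 0.0
    return out


def profiles_to_genotype_table(profiles: Sequence[ScatProfile]) -> GenotypeTable:
    """Genotype table of retained scats (one row per scat)."""
    kept = [p for p in profiles if p.retained]
    loci = sorted({l for p in kept for l in p.calls})
    calls = {
        (p.scat_id, l): p.genotype(l) for p in kept for l in loci if p.genotype(l) is not None
    }
    return GenotypeTable([p.scat_id for p in kept], loci, calls)
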
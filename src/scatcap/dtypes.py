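"""Core data model for noninvasive scat-survey genetics.

Genotypes are unordered pairs of integer microsatellite fragment sizes
(base pairs).  A missing genotype is the pair ``(0, 0)`` on disk and
``None`` in memory.  All containers validate on construction and compare
genotypes as unordered pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPolygon, Polygon


class FormatError(ValueError):
    """Raised when an on-disk file violates the documented dialect."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


class ValidationError(ValueError):
    """Raised when input data violate a domain invariant."""


Genotype = tuple[int, int]


def make_genotype(a: int, b: int) -> Genotype:
    """Return the unordered (sorted) allele pair."""
    a, b = int(a), int(b)
    if a <= 0 or b <= 0:
        raise ValidationError(f"alleles must be positive integers, got ({a}, {b})")
    return (a, b) if a <= b else (b, a)


def is_het(g: Genotype) -> bool:
    return g[0] != g[1]


class GenotypeTable:
    """Multilocus genotypes for a set of samples.

    The locus set is shared by all samples; a sample may be untyped
    (``None``) at any locus.  Equality is order-insensitive in both
    alleles and row order.
    """

    def __init__(
        self,
        samples: Sequence[str],
        loci: Sequence[str],
        calls: Mapping[tuple[str, str], Optional[Genotype]],
    ):
        self.samples = list(dict.fromkeys(str(s) for s in samples))
        self.loci = list(dict.fromkeys(str(l) for l in loci))
        self._calls: dict[tuple[str, str], Optional[Genotype]] = {}
        for s in self.samples:
            for l in self.loci:
                g = calls.get((s, l))
                if g is not None:
                    g = make_genotype(*g)
                self._calls[(s, l)] = g

    def genotype(self, sample: str, locus: str) -> Optional[Genotype]:
        return self._calls[(sample, locus)]

    def set_genotype(self, sample: str, locus: str, g: Optional[Genotype]) -> None:
        if sample not in self.samples or locus not in self.loci:
            raise KeyError((sample, locus))
        self._calls[(sample, locus)] = None if g is None else make_genotype(*g)

    def n_typed(self, locus: str) -> int:
        return sum(1 for s in self.samples if self._calls[(s, locus)] is not None)

    def typed_genotypes(self, locus: str) -> list[Genotype]:
        return [g for s in self.samples if (g := self._calls[(s, locus)]) is not None]

    def loci_typed(self, sample: str) -> list[str]:
        return [l for l in self.loci if self._calls[(sample, l)] is not None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            for l in self.loci:
                g = self._calls[(s, l)]
                a, b = (0, 0) if g is None else g
                rows.append((s, l, a, b))
        return pd.DataFrame(rows, columns=["sample_id", "locus_id", "allele_a", "allele_b"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            sorted(self.samples) == sorted(other.samples)
            and sorted(self.loci) == sorted(other.loci)
            and all(
                self._calls[(s, l)] == other._calls[(s, l)]
                for s in self.samples
                for l in self.loci
            )
        )

    def __repr__(self) -> str:
        return f"GenotypeTable({len(self.samples)} samples x {len(self.loci)} loci)"


#: sentinel call for a failed PCR x locus reaction
FAILED = None


@dataclass(frozen=True)
class ReplicateRecord:
    """One PCR replicate's reading of one locus of one scat.

    ``call`` is the unordered allele pair seen in that reaction.  A
    single observed band is recorded as the pair ``(a, a)`` — from one
    reaction a true homozygote and a dropped-out heterozygote are
    indistinguishable.  ``None`` means the reaction failed.
    """

    scat_id: str
    pcr_id: str
    locus_id: str
    call: Optional[Genotype]


class ReplicateSet:
    """Replicate-PCR allele calls: the raw evidence for consensus genotyping."""

    def __init__(self, records: Iterable[ReplicateRecord]):
        self.records = list(records)
        seen = set()
        for r in self.records:
            key = (r.scat_id, r.pcr_id, r.locus_id)
            if key in seen:
                raise ValidationError(f"duplicate replicate record {key}")
            seen.add(key)

    @property
    def scat_ids(self) -> list[str]:
        return list(dict.fromkeys(r.scat_id for r in self.records))

    @property
    def locus_ids(self) -> list[str]:
        return list(dict.fromkeys(r.locus_id for r in self.records))

    def for_scat(self, scat_id: str) -> list[ReplicateRecord]:
        return [r for r in self.records if r.scat_id == scat_id]

    def for_scat_locus(self, scat_id: str, locus_id: str) -> list[ReplicateRecord]:
        return [r for r in self.records if r.scat_id == scat_id and r.locus_id == locus_id]

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReplicateSet):
            return NotImplemented
        key = lambda r: (r.scat_id, r.pcr_id, r.locus_id)
        return sorted(self.records, key=key) == sorted(other.records, key=key)


@dataclass
class SurveyGeometry:
    """Transect polylines, habitat polygon and scat detections.

    Coordinates are planar meters (an already-projected CRS, e.g. UTM);
    no coordinate transformation is ever applied.  Occasions are
    1-based integers.
    """

    transects: list[LineString]
    habitat: Optional[Polygon | MultiPolygon]
    detections: pd.DataFrame  # scat_id, x, y, occasion

    def __post_init__(self) -> None:
        req = {"scat_id", "x", "y", "occasion"}
        if not req.issubset(self.detections.columns):
            raise ValidationError(f"detections need columns {sorted(req)}")
        det = self.detections
        if len(det):
            xy = det[["x", "y"]].to_numpy(float)
            if not np.all(np.isfinite(xy)):
                raise ValidationError("non-finite detection coordinates")
            occ = det["occasion"].to_numpy()
            if not np.all(occ == occ.astype(int)) or occ.min() < 1:
                raise ValidationError("occasions must be positive integers (1-based)")
            if self.habitat is not None:
                minx, miny, maxx, maxy = self.habitat.bounds
                pad = 10_000.0  # >10 km outside the habitat bbox suggests a CRS mix-up
                bad = (
                    (xy[:, 0] < minx - pad)
                    | (xy[:, 0] > maxx + pad)
                    | (xy[:, 1] < miny - pad)
                    | (xy[:, 1] > maxy + pad)
                )
                if bad.any():
                    raise ValidationError(
                        f"{int(bad.sum())} detection(s) lie >10 km outside the habitat "
                        "bounding box; check that all inputs share one projected CRS"
                    )
        for t in self.transects:
            if not math.isfinite(t.length):
                raise ValidationError("non-finite transect geometry")

    @property
    def n_occasions(self) -> int:
        if len(self.detections) == 0:
            return 0
        return int(self.detections["occasion"].max())
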
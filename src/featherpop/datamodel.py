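"""Core domain types for non-invasive microsatellite population genetics.

Allele labels are PCR fragment sizes in base pairs (integers), the unit in
which microsatellite genotypes are scored.  A genotype is an unordered pair
of allele labels per locus, or missing at that locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Tuple

MISSING: Optional[Tuple[int, int]] = None

VALID_BASES = set("ACGTN-")


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus; ``panel`` is the multiplex PCR reaction (A-D)."""

    name: str
    panel: str = "A"

    def __post_init__(self) -> None:
        if self.panel not in ("A", "B", "C", "D"):
            raise ValueError(f"panel must be one of A-D, got {self.panel!r}")


class Genotype:
    """Multilocus genotype: per-locus unordered allele pair or missing.

    Stored as a dict mapping locus name -> sorted (a, b) tuple, or None for a
    missing locus.  ``Genotype({'L1': (120, 124)})`` equals
    ``Genotype({'L1': (124, 120)})``.
    """

    __slots__ = ("calls",)

    def __init__(self, calls: Dict[str, Optional[Tuple[int, int]]]):
        normalized: Dict[str, Optional[Tuple[int, int]]] = {}
        for locus, pair in calls.items():
            if pair is None:
                normalized[locus] = None
            else:
                a, b = pair
                normalized[locus] = (a, b) if a <= b else (b, a)
        self.calls = normalized

    def __getitem__(self, locus: str) -> Optional[Tuple[int, int]]:
        return self.calls[locus]

    def get(self, locus: str) -> Optional[Tuple[int, int]]:
        return self.calls.get(locus)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genotype) and self.calls == other.calls

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.calls.items(), key=lambda kv: kv[0])))

    def __repr__(self) -> str:
        return f"Genotype({self.calls!r})"

    @property
    def loci(self) -> List[str]:
        return list(self.calls)

    def typed_loci(self) -> List[str]:
        return [l for l, p in self.calls.items() if p is not None]

    def missing_fraction(self) -> float:
        if not self.calls:
            return 0.0
        n_missing = sum(1 for p in self.calls.values() if p is None)
        return n_missing / len(self.calls)

    def is_het(self, locus: str) -> bool:
        pair = self.calls[locus]
        return pair is not None and pair[0] != pair[1]


@dataclass
class SampleRecord:
    """One feather's raw multilocus genotype plus field metadata."""

    sample_id: str
    genotype: Genotype
    site_id: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    year: Optional[int] = None
    sex_fragment_bp: Optional[int] = None
    mtdna_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if self.mtdna_seq is not None:
            seq = self.mtdna_seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"invalid bases in mtDNA sequence: {sorted(bad)}")
            self.mtdna_seq = seq


@dataclass
class Individual:
    """A genotyped individual: the unit of all population-level analyses."""

    individual_id: str
    consensus: Genotype
    members: List[str] = field(default_factory=list)
    sex: Sex = Sex.UNKNOWN
    region: str = ""
    haplotype_id: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    mtdna_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.members:
            self.members = [self.individual_id]


@dataclass
class PopulationDataset:
    """Loci plus individuals partitioned into geographic regions."""

    loci: List[Locus]
    individuals: List[Individual]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        declared = set(names)
        for ind in self.individuals:
            extra = set(ind.consensus.calls) - declared
            if extra:
                raise ValueError(
                    f"individual {ind.individual_id} has undeclared loci {sorted(extra)}"
                )

    @property
    def locus_names(self) -> List[str]:
        return [l.name for l in self.loci]

    @property
    def regions(self) -> List[str]:
        seen: List[str] = []
        for ind in self.individuals:
            if ind.region not in seen:
                seen.append(ind.region)
        return seen

    def by_region(self) -> Dict[str, List[Individual]]:
        out: Dict[str, List[Individual]] = {}
        for ind in self.individuals:
            out.setdefault(ind.region, []).append(ind)
        return out

    def subset(self, individual_ids) -> "PopulationDataset":
        keep = set(individual_ids)
        return PopulationDataset(
            loci=list(self.loci),
            individuals=[i for i in self.individuals if i.individual_id in keep],
        )
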
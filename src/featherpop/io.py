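"""Readers and writers: Genepop, FASTA, replicate-level CSV, site clustering.

Genepop is the canonical interchange format for consensus genotypes; since it
has no notion of replicate samples, a long-form CSV
(sample_id, locus, allele1, allele2) carries replicate-level data.
"""

from __future__ import annotations

import csv
import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import Genotype, Individual, Locus, PopulationDataset

EARTH_RADIUS_KM = 6371.0088


class GenepopParseError(ValueError):
    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def _decode_allele_pair(code: str, width: int, line_no: int) -> Optional[Tuple[int, int]]:
    if len(code) != 2 * width:
        raise GenepopParseError(f"allele code {code!r} is not {2 * width} digits", line_no)
    a, b = int(code[:width]), int(code[width:])
    if a == 0 or b == 0:
        # 000/000000 (and any half-missing call) maps to a missing locus
        return None
    return (a, b)


def read_genepop(path) -> PopulationDataset:
    """Read a Genepop file (2- or 3-digit allele codes, POP-delimited).

    Population blocks map to regions named pop1, pop2, ... in file order.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file", 1)

    locus_names: List[str] = []
    i = 1  # line 0 is the title
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped.upper() == "POP":
            break
        if not stripped:
            i += 1
            continue
        # locus list: one per line, or comma-separated on one line
        for name in stripped.split(","):
            name = name.strip()
            if name:
                locus_names.append(name)
        i += 1
    if not locus_names:
        raise GenepopParseError("no locus names before first POP", i + 1)
    if len(set(locus_names)) != len(locus_names):
        raise GenepopParseError("duplicate locus names in header", i + 1)

    individuals: List[Individual] = []
    pop_idx = 0
    width: Optional[int] = None
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped.upper() == "POP":
            pop_idx += 1
            i += 1
            continue
        if not stripped:
            i += 1
            continue
        if pop_idx == 0:
            raise GenepopParseError("genotype line before first POP", i + 1)
        if "," not in stripped:
            raise GenepopParseError("genotype line missing ',' separator", i + 1)
        ind_id, geno_part = stripped.split(",", 1)
        codes = geno_part.split()
        if len(codes) != len(locus_names):
            raise GenepopParseError(
                f"expected {len(locus_names)} allele codes, got {len(codes)}", i + 1
            )
        if width is None and codes:
            if len(codes[0]) == 4:
                width = 2
            elif len(codes[0]) == 6:
                width = 3
            else:
                raise GenepopParseError(f"allele code {codes[0]!r} not 4 or 6 digits", i + 1)
        calls = {
            name: _decode_allele_pair(code, width, i + 1)
            for name, code in zip(locus_names, codes)
        }
        individuals.append(
            Individual(
                individual_id=ind_id.strip(),
                consensus=Genotype(calls),
                region=f"pop{pop_idx}",
            )
        )
        i += 1

    return PopulationDataset(
        loci=[Locus(n) for n in locus_names], individuals=individuals
    )


def write_genepop(dataset: PopulationDataset, path, title: str = "featherpop export",
                  width: int = 3) -> None:
    """Write a Genepop file; refuses allele labels wider than the code width."""
    limit = 10 ** width - 1
    for ind in dataset.individuals:
        for locus, pair in ind.consensus.calls.items():
            if pair is not None and max(pair) > limit:
                raise ValueError(
                    f"allele label {max(pair)} at {locus} exceeds {width}-digit codes"
                )
    lines = [title]
    lines.extend(dataset.locus_names)
    for region, inds in dataset.by_region().items():
        lines.append("POP")
        for ind in inds:
            codes = []
            for name in dataset.locus_names:
                pair = ind.consensus.get(name)
                if pair is None:
                    codes.append("0" * (2 * width))
                else:
                    codes.append(f"{pair[0]:0{width}d}{pair[1]:0{width}d}")
            lines.append(f"{ind.individual_id} , " + " ".join(codes))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read FASTA as (id, uppercased sequence) pairs; duplicate ids error."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids: {dupes}")
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_replicates_csv(path) -> Tuple[List[str], Dict[str, Genotype]]:
    """Read long-form replicate genotypes (sample_id, locus, allele1, allele2).

    Blank/zero alleles mean a missing locus.  Returns (locus order, genotypes
    keyed by sample_id); every sample's genotype covers the full locus set.
    """
    rows: List[Tuple[str, str, Optional[Tuple[int, int]]]] = []
    loci: List[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            a1, a2 = row.get("allele1", ""), row.get("allele2", "")
            if a1 in ("", "0") or a2 in ("", "0"):
                pair = None
            else:
                pair = (int(a1), int(a2))
            locus = row["locus"]
            if locus not in loci:
                loci.append(locus)
            rows.append((row["sample_id"], locus, pair))
    genotypes: Dict[str, Dict[str, Optional[Tuple[int, int]]]] = {}
    for sample_id, locus, pair in rows:
        genotypes.setdefault(sample_id, {})[locus] = pair
    out = {}
    for sample_id, calls in genotypes.items():
        full = {l: calls.get(l) for l in loci}
        out[sample_id] = Genotype(full)
    return loci, out


def write_replicates_csv(loci: Sequence[str], genotypes: Dict[str, Genotype], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "locus", "allele1", "allele2"])
        for sample_id, geno in genotypes.items():
            for locus in loci:
                pair = geno.get(locus)
                if pair is None:
                    writer.writerow([sample_id, locus, "", ""])
                else:
                    writer.writerow([sample_id, locus, pair[0], pair[1]])


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in km between WGS84 decimal-degree points."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def group_sites(samples, threshold_km: float = 16.0) -> Dict[str, str]:
    """Single-linkage clustering of sampling sites under great-circle distance.

    Sites (or samples) closer than ``threshold_km`` are merged into one
    location.  Returns a mapping sample_id -> cluster id; the cluster id is
    the site_id of the southwesternmost member (ties broken by id), making
    cluster naming deterministic.  Samples without coordinates are left
    unclustered (mapped to their own site_id).
    """
    if threshold_km <= 0:
        raise ValueError("threshold_km must be positive")
    located = [s for s in samples if s.latitude is not None and s.longitude is not None]
    unlocated = [s for s in samples if s not in located]

    # union-find over unique sites
    sites: Dict[str, Tuple[float, float]] = {}
    for s in located:
        sites.setdefault(s.site_id, (s.latitude, s.longitude))
    site_ids = sorted(sites)
    parent = {sid: sid for sid in site_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(site_ids):
        for b in site_ids[i + 1:]:
            la, lo = sites[a]
            lb, lob = sites[b]
            if great_circle_km(la, lo, lb, lob) <= threshold_km:
                parent[find(a)] = find(b)

    clusters: Dict[str, List[str]] = {}
    for sid in site_ids:
        clusters.setdefault(find(sid), []).append(sid)

    label: Dict[str, str] = {}
    for members in clusters.values():
        # southwesternmost member: lowest latitude, then lowest longitude, then id
        rep = min(members, key=lambda sid: (sites[sid][0], sites[sid][1], sid))
        for sid in members:
            label[sid] = rep

    out: Dict[str, str] = {}
    for s in located:
        out[s.sample_id] = label[s.site_id]
    for s in unlocated:
        out[s.sample_id] = s.site_id
    return out
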
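"""Read-depth deletion screening and breakpoint-junction analysis.

Provides RPKM normalisation of exon read counts, a cohort-median ratio
screen for heterozygous/homozygous exonic deletions, deletion size
arithmetic from printed genomic coordinates, exact-match resolution of a
Sanger-derived junction read against its proximal and distal reference
flanks (reporting microhomology or inserted bases), and classification of
deletions as candidate Alu-Alu mediated rearrangements (AAMR) when both
breakpoints land in directly oriented Alu elements.

The deletion screen is a deliberately simple cohort-median ratio method:
per exon, a sample's RPKM divided by the median RPKM of the other samples,
with maximal runs of consecutive exons inside the heterozygous window (or
below the homozygous ceiling) emitted as calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExonInterval",
    "RpkmMatrix",
    "DeletionCall",
    "JunctionResolution",
    "RepeatAnnotation",
    "UnresolvableJunctionError",
    "AmbiguousJunctionError",
    "rpkm",
    "read_exons_bed",
    "read_repeats_bed",
    "screen_deletions",
    "deletion_size",
    "resolve_junction",
    "classify_aamr",
]


@dataclass(frozen=True)
class ExonInterval:
    """0-based half-open exon interval with gene/exon labels."""

    chrom: str
    start: int
    end: int
    gene: str = ""
    exon_id: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"exon length must be positive: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> str:
        return self.exon_id or f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class RpkmMatrix:
    """RPKM values, exons (rows, in genomic order) x samples (columns)."""

    exons: list  # of ExonInterval
    values: pd.DataFrame  # index = exon keys, columns = samples

    @property
    def samples(self) -> list:
        return list(self.values.columns)


@dataclass
class DeletionCall:
    sample: str
    chrom: str
    start: int
    end: int
    zygosity: str  # het | hom
    supporting_exons: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class JunctionResolution:
    """Resolved breakpoint junction of a deletion.

    Breakpoint intervals capture the ambiguity introduced by
    microhomology: the true junction can sit anywhere along the shared
    tract, so each breakpoint is an interval of width ``len(microhomology)``
    (zero-width when the junction is exact or carries an insertion).
    """

    proximal_interval: tuple  # (p1, p2) in proximal reference coordinates
    distal_interval: tuple  # (d1, d2) in distal reference coordinates
    microhomology: str = ""
    inserted: str = ""
    exact: bool = False
    chrom: str | None = None

    def __post_init__(self):
        if self.microhomology and self.inserted:
            raise ValueError("junction cannot have both microhomology and insertion")
        m = len(self.microhomology)
        if (self.proximal_interval[1] - self.proximal_interval[0] != m
                or self.distal_interval[1] - self.distal_interval[0] != m):
            raise ValueError("breakpoint interval widths must equal the "
                             "microhomology length")


@dataclass(frozen=True)
class RepeatAnnotation:
    chrom: str
    start: int
    end: int
    family: str  # e.g. AluSx1, AluSq2
    strand: str  # + | -

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("repeat interval must be well-formed")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


class UnresolvableJunctionError(ValueError):
    """Neither flank of the junction read matched its reference."""


class AmbiguousJunctionError(ValueError):
    """A flank places at several equally long reference positions."""

    def __init__(self, side: str, positions):
        self.side = side
        self.positions = list(positions)
        super().__init__(
            f"{side} flank aligns at multiple positions: {self.positions}"
        )


# ---------------------------------------------------------------------------
# read-depth screen
# ---------------------------------------------------------------------------

def read_exons_bed(path) -> list:
    """Exon intervals from BED (chrom, start, end[, name[, gene]])."""
    exons = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            exons.append(ExonInterval(
                chrom=f[0], start=int(f[1]), end=int(f[2]),
                exon_id=f[3] if len(f) > 3 else "",
                gene=f[4] if len(f) > 4 else "",
            ))
    return exons


def read_repeats_bed(path) -> list:
    """Repeat annotations from BED with name and strand columns."""
    repeats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError("repeat BED needs chrom,start,end,name,score,strand")
            repeats.append(RepeatAnnotation(
                chrom=f[0], start=int(f[1]), end=int(f[2]),
                family=f[3], strand=f[5],
            ))
    return repeats


def rpkm(counts: pd.DataFrame, exons: Sequence[ExonInterval],
         total_reads: pd.Series | dict) -> RpkmMatrix:
    """Reads per kilobase per million mapped reads.

    ``RPKM = reads * 1e9 / (exon_length * total_mapped_reads)``.
    ``counts`` is exon keys x samples; exon order follows genomic order.
    """
    exons = sorted(exons, key=lambda e: (e.chrom, e.start, e.end))
    keys = [e.key for e in exons]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate exon keys")
    totals = pd.Series(total_reads, dtype=float)
    if (totals <= 0).any():
        raise ValueError("total mapped reads must be positive for every sample")
    counts = counts.loc[keys, totals.index]
    lengths = pd.Series({e.key: e.length for e in exons}, dtype=float)
    values = counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return RpkmMatrix(exons=exons, values=values)


def screen_deletions(m: RpkmMatrix, sample: str,
                     het_window: tuple = (0.3, 0.7), hom_max: float = 0.1,
                     min_consecutive: int = 1) -> list:
    """Call exonic deletions for one sample against the cohort median.

    Per exon, the depth ratio is the sample's RPKM over the median RPKM of
    the *other* samples.  Maximal runs of consecutive exons (within one
    chromosome) whose ratio falls in ``het_window`` become heterozygous
    calls; runs at or below ``hom_max`` become homozygous calls.  Exons
    whose cohort median is zero are skipped with a warning.
    """
    if len(m.samples) < 8:
        raise ValueError("deletion screen needs >= 8 samples for a stable median")
    if sample not in m.samples:
        raise KeyError(f"unknown sample {sample!r}")

    others = m.values.drop(columns=[sample])
    medians = others.median(axis=1)
    states = []  # aligned with m.exons
    for exon in m.exons:
        med = medians[exon.key]
        if med <= 0:
            warnings.warn(f"exon {exon.key}: cohort median RPKM is 0; skipped")
            states.append(None)
            continue
        ratio = m.values.at[exon.key, sample] / med
        if ratio <= hom_max:
            states.append("hom")
        elif het_window[0] <= ratio <= het_window[1]:
            states.append("het")
        else:
            states.append("normal")

    calls: list[DeletionCall] = []
    run: list[int] = []
    run_state = None

    def flush():
        if run_state in ("het", "hom") and len(run) >= min_consecutive:
            first, last = m.exons[run[0]], m.exons[run[-1]]
            calls.append(DeletionCall(
                sample=sample, chrom=first.chrom,
                start=first.start, end=last.end, zygosity=run_state,
                supporting_exons=[m.exons[i].key for i in run],
            ))

    prev_chrom = None
    for i, (exon, state) in enumerate(zip(m.exons, states)):
        broken = exon.chrom != prev_chrom or state != run_state or state is None
        if broken:
            flush()
            run, run_state = [], state
        if state in ("het", "hom"):
            run.append(i)
        prev_chrom = exon.chrom
    flush()
    return calls


def deletion_size(coord1: int, coord2: int) -> tuple:
    """Deletion size and orientation-normalised (start, end).

    Printed genomic coordinates are inclusive 1-based positions whose
    absolute difference is the reported size.
    """
    if coord1 <= 0 or coord2 <= 0:
        raise ValueError("coordinates must be positive")
    start, end = sorted((coord1, coord2))
    return end - start, start, end


# ---------------------------------------------------------------------------
# junction resolution
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> list:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def resolve_junction(read: str, proximal_ref: str, distal_ref: str,
                     seed_length: int = 12, proximal_offset: int = 0,
                     distal_offset: int = 0, chrom: str | None = None
                     ) -> JunctionResolution:
    """Resolve a deletion junction read against its two reference flanks.

    Finds the longest prefix of the read matching the proximal reference
    exactly and the longest suffix matching the distal reference exactly.
    If the prefix and suffix overlap within the read, the overlap is
    microhomology and each breakpoint is reported as an interval of that
    width (the junction can slide along the homologous tract); a gap
    between them is an untemplated insertion; a seamless meeting is an
    exact (blunt) junction.  Offsets shift reported coordinates into
    genomic space.
    """
    read = read.strip().upper()
    proximal_ref = proximal_ref.strip().upper()
    distal_ref = distal_ref.strip().upper()
    if len(read) < 20:
        raise ValueError("junction read must be at least 20 nt")

    # longest prefix of the read present in the proximal reference
    lo = 0
    for length in range(seed_length, len(read) + 1):
        if read[:length] in proximal_ref:
            lo = length
        else:
            break
    if lo < seed_length:
        raise UnresolvableJunctionError(
            f"no proximal match of at least {seed_length} nt"
        )
    prox_hits = _find_all(proximal_ref, read[:lo])
    if len(prox_hits) > 1:
        raise AmbiguousJunctionError("proximal", prox_hits)

    hi = 0
    for length in range(seed_length, len(read) + 1):
        if read[len(read) - length:] in distal_ref:
            hi = length
        else:
            break
    if hi < seed_length:
        raise UnresolvableJunctionError(
            f"no distal match of at least {seed_length} nt"
        )
    dist_hits = _find_all(distal_ref, read[len(read) - hi:])
    if len(dist_hits) > 1:
        raise AmbiguousJunctionError("distal", dist_hits)

    prefix_end = lo  # read coordinate just past the proximal match
    suffix_start = len(read) - hi
    prox_end = proximal_offset + prox_hits[0] + lo  # ref coord past match
    dist_start = distal_offset + dist_hits[0]

    if prefix_end > suffix_start:  # overlapping matches -> microhomology
        mh = read[suffix_start:prefix_end]
        return JunctionResolution(
            proximal_interval=(prox_end - len(mh), prox_end),
            distal_interval=(dist_start, dist_start + len(mh)),
            microhomology=mh, inserted="", exact=False, chrom=chrom,
        )
    if prefix_end < suffix_start:  # gap -> untemplated insertion
        return JunctionResolution(
            proximal_interval=(prox_end, prox_end),
            distal_interval=(dist_start, dist_start),
            microhomology="", inserted=read[prefix_end:suffix_start],
            exact=False, chrom=chrom,
        )
    return JunctionResolution(
        proximal_interval=(prox_end, prox_end),
        distal_interval=(dist_start, dist_start),
        microhomology="", inserted="", exact=True, chrom=chrom,
    )


# ---------------------------------------------------------------------------
# AAMR classification
# ---------------------------------------------------------------------------

@dataclass
class AamrClassification:
    aamr_candidate: bool
    pair: tuple | None = None  # (proximal family, distal family)
    chimeric: bool = False


def _covering_repeat(repeats, chrom, interval):
    # a zero-width breakpoint sits between bases, so either flanking base
    # lying inside the repeat counts as containment
    p1, p2 = interval
    probe = (p1 + p2) // 2 if p2 > p1 else p1
    for rep in repeats:
        if rep.contains(chrom, probe) or (probe > 0 and rep.contains(chrom, probe - 1)):
            return rep
    return None


def classify_aamr(resolution: JunctionResolution,
                  repeats: Sequence[RepeatAnnotation],
                  chrom: str | None = None) -> AamrClassification:
    """Classify a resolved deletion as a candidate Alu-Alu rearrangement.

    The deletion is an AAMR candidate when both breakpoints fall inside
    Alu-family repeats on the same strand (directly oriented); it is
    additionally chimeric when junction microhomology is present, i.e. the
    event fused the two elements into a chimeric Alu.
    """
    chrom = chrom or resolution.chrom
    prox = _covering_repeat(repeats, chrom, resolution.proximal_interval)
    dist = _covering_repeat(repeats, chrom, resolution.distal_interval)
    if prox is None or dist is None:
        return AamrClassification(aamr_candidate=False)
    alu = prox.family.startswith("Alu") and dist.family.startswith("Alu")
    direct = prox.strand == dist.strand
    if not (alu and direct):
        return AamrClassification(aamr_candidate=False)
    return AamrClassification(
        aamr_candidate=True,
        pair=(prox.family, dist.family),
        chimeric=bool(resolution.microhomology),
    )
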
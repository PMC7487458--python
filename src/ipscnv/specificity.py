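"""Paired parental/iPSC comparison and cross-sample locus merging.

De novo (reprogramming-associated) CNVs are isolated by subtracting
inherited events: an iPSC segment overlapping any single parental segment of
the same donor by more than 50% of its own length is considered inherited
and removed.  Surviving segments from all samples are clustered into loci by
single-linkage under a 10% reciprocal-overlap criterion, and loci heavily
covered by control-cohort CNVs are excluded.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .probes import CnvSegment, GAIN, LOSS, FEMALE, MALE, _chrom_kind

ROLE_PARENTAL = "parental"
ROLE_IPSC = "ipsc"
ROLE_CONTROL = "control"


@dataclass(frozen=True)
class SampleRecord:
    """Identity, donor pairing, role and sex of one sample."""

    sample_id: str
    donor_id: str
    role: str  # parental | ipsc | control
    sex: str   # male | female

    def __post_init__(self) -> None:
        if self.role not in (ROLE_PARENTAL, ROLE_IPSC, ROLE_CONTROL):
            raise ValueError(f"unknown role {self.role!r}")
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"unknown sex {self.sex!r}")


class Manifest:
    """Validated sample manifest with donor-pairing and stratum lookups."""

    def __init__(self, records: Sequence[SampleRecord]):
        self.records = list(records)
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in manifest")
        self.by_id = {r.sample_id: r for r in self.records}
        self.parental_by_donor: dict[str, SampleRecord] = {}
        self.ipsc_by_donor: dict[str, list[SampleRecord]] = {}
        for r in self.records:
            if r.role == ROLE_PARENTAL:
                if r.donor_id in self.parental_by_donor:
                    raise ValueError(f"donor {r.donor_id} has two parental samples")
                self.parental_by_donor[r.donor_id] = r
            elif r.role == ROLE_IPSC:
                self.ipsc_by_donor.setdefault(r.donor_id, []).append(r)
        for donor, lines in self.ipsc_by_donor.items():
            if donor not in self.parental_by_donor:
                raise ValueError(f"iPSC line(s) of donor {donor} lack a parental sample")

    # -- cohort views ------------------------------------------------------

    def samples(self, role: str, sex: str | None = None) -> list[SampleRecord]:
        return [r for r in self.records
                if r.role == role and (sex is None or r.sex == sex)]

    def cohort_size(self, role: str, sex: str | None = None) -> int:
        return len(self.samples(role, sex))

    def donors(self) -> list[str]:
        return sorted(self.ipsc_by_donor)

    def role_of(self, sample_id: str) -> str:
        return self.by_id[sample_id].role


# -- interval arithmetic ---------------------------------------------------

def overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Shared base pairs of two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def reciprocal_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> float:
    """min(shared/len(a), shared/len(b)); 0 for different chromosomes."""
    if a[0] != b[0]:
        return 0.0
    shared = overlap_bp(a[1], a[2], b[1], b[2])
    if shared == 0:
        return 0.0
    return min(shared / (a[2] - a[1] + 1), shared / (b[2] - b[1] + 1))


# -- inherited-CNV subtraction ---------------------------------------------

def subtract_inherited(ipsc_segments: Sequence[CnvSegment],
                       parental_segments: Sequence[CnvSegment],
                       max_frac: float = 0.5,
                       manifest: Manifest | None = None) -> list[CnvSegment]:
    """Drop iPSC segments inherited from the parental cells.

    A segment is removed iff, for some *single* parental segment of any
    direction, shared bp / iPSC segment length exceeds ``max_frac`` (strict).
    When a manifest is supplied, both inputs must belong to one donor.
    """
    if manifest is not None:
        donors = {manifest.by_id[s.sample_id].donor_id
                  for s in list(ipsc_segments) + list(parental_segments)}
        if len(donors) > 1:
            raise ValueError(f"segments span several donors: {sorted(donors)}")
    by_chrom: dict[str, list[CnvSegment]] = {}
    for p in parental_segments:
        by_chrom.setdefault(p.chrom, []).append(p)
    kept = []
    for s in ipsc_segments:
        inherited = any(
            overlap_bp(s.start, s.end, p.start, p.end) / s.length > max_frac
            for p in by_chrom.get(s.chrom, ()))
        if not inherited:
            kept.append(s)
    return kept


# -- locus merging ---------------------------------------------------------

@dataclass
class Locus:
    """A cross-sample cluster of CNV segments (single-linkage at >=10% RO).

    Carrier bookkeeping (sample-id sets per cohort and direction) is filled
    by :func:`ipscnv.stats.annotate_carriers`; counts derive from the sets.
    """

    chrom: str
    start: int
    end: int
    members: tuple[CnvSegment, ...]
    stratum: str = "all"  # all | female_only | male_only
    ipsc_carriers: dict = field(default_factory=lambda: {GAIN: set(), LOSS: set()})
    control_carriers: dict = field(default_factory=lambda: {GAIN: set(), LOSS: set()})
    parental_carriers: set = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def carriers(self, cohort: str = "ipsc") -> set:
        d = self.ipsc_carriers if cohort == "ipsc" else self.control_carriers
        return d[GAIN] | d[LOSS]

    @property
    def carriers_ipsc_gain(self) -> int:
        return len(self.ipsc_carriers[GAIN])

    @property
    def carriers_ipsc_loss(self) -> int:
        return len(self.ipsc_carriers[LOSS])

    @property
    def carriers_control_gain(self) -> int:
        return len(self.control_carriers[GAIN])

    @property
    def carriers_control_loss(self) -> int:
        return len(self.control_carriers[LOSS])


class _DSU:
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
            self.parent[rj] = ri


def merge_loci(segments: Sequence[CnvSegment],
               threshold: float = 0.10) -> list[Locus]:
    """Cluster segments into loci by single linkage at reciprocal overlap >= threshold.

    Locus span is the min start / max end over members.  Every input segment
    belongs to exactly one locus.  Output is sorted by (chrom order of first
    appearance, start).
    """
    segs = list(segments)
    dsu = _DSU(len(segs))
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(segs):
        by_chrom.setdefault(s.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        idx.sort(key=lambda i: (segs[i].start, segs[i].end))
        active: list[int] = []  # indices with end >= current start, sorted scan
        for i in idx:
            s = segs[i]
            active = [j for j in active if segs[j].end >= s.start]
            for j in active:
                if reciprocal_overlap(
                        (s.chrom, s.start, s.end),
                        (s.chrom, segs[j].start, segs[j].end)) >= threshold:
                    dsu.union(i, j)
            active.append(i)
    clusters: dict[int, list[int]] = {}
    for i in range(len(segs)):
        clusters.setdefault(dsu.find(i), []).append(i)
    loci = []
    for members in clusters.values():
        ms = tuple(segs[i] for i in members)
        loci.append(Locus(
            chrom=ms[0].chrom,
            start=min(m.start for m in ms),
            end=max(m.end for m in ms),
            members=ms,
        ))
    loci.sort(key=lambda l: (l.chrom, l.start, l.end))
    return loci


# -- control-overlap filtering ---------------------------------------------

def _union_coverage_bp(start: int, end: int,
                       intervals: Iterable[tuple[int, int]]) -> int:
    """bp of [start, end] covered by the union of the given intervals."""
    clipped = sorted((max(start, s), min(end, e)) for s, e in intervals
                     if s <= end and e >= start)
    covered = 0
    cur_s: int | None = None
    cur_e = 0
    for s, e in clipped:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        covered += cur_e - cur_s + 1
    return covered


def filter_vs_controls(loci: Sequence[Locus],
                       control_segments: Sequence[CnvSegment],
                       max_cov: float = 0.10) -> list[Locus]:
    """Keep loci whose span is covered < ``max_cov`` (strict) by the union of
    control-cohort segments intersecting it (frequency-agnostic)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in control_segments:
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    kept = []
    for locus in loci:
        cov = _union_coverage_bp(locus.start, locus.end,
                                 by_chrom.get(locus.chrom, ()))
        if cov / locus.length < max_cov:
            kept.append(locus)
    return kept


def span_carriers(locus: Locus, segments: Sequence[CnvSegment],
                  threshold: float = 0.10) -> dict[str, set[str]]:
    """Samples whose segments place them at this locus, per direction.

    A non-member sample carries the locus iff one of its segments has
    reciprocal overlap >= ``threshold`` with the locus span — the same
    criterion used to merge segments into loci.
    """
    out: dict[str, set[str]] = {GAIN: set(), LOSS: set()}
    for s in segments:
        if s.chrom != locus.chrom:
            continue
        if reciprocal_overlap(locus.span, (s.chrom, s.start, s.end)) >= threshold:
            out[s.direction].add(s.sample_id)
    return out


def is_sex_chrom(chrom: str) -> bool:
    return _chrom_kind(chrom) in ("X", "Y")
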
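"""Probe-level copy-number calls and run-based CNV segmentation.

The analysis starts from integer copy-number states called per array probe
(one state per probe per sample).  A CNV is a maximal run of at least
``min_probes`` consecutive probes, in genomic order, whose states all lie
strictly on the same side of the sex-appropriate baseline copy number
(autosomes: 2; X: 2 in females, 1 in males; Y: 1 in males, excluded in
females).  A probe at baseline, or one deviating in the opposite direction,
terminates the run.  Runs never span chromosome boundaries.

Excluded regions (centromeres, immunoglobulin variable regions, T-cell
receptor loci, pseudoautosomal regions, the X-transposed region) are applied
by *masking probes before segmentation*, so an excluded region can neither
seed nor bridge a run.

All coordinates in memory are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

GAIN = "gain"
LOSS = "loss"

MALE = "male"
FEMALE = "female"

#: Categories recognised for exclusion intervals.
EXCLUSION_CATEGORIES = ("centromere", "Ig_variable", "TCR", "PAR", "XTR")


def _chrom_kind(chrom: str) -> str:
    """Classify a chromosome name as 'autosome', 'X' or 'Y'."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.upper() == "X":
        return "X"
    if name.upper() == "Y":
        return "Y"
    return "autosome"


def expected_copy_number(chrom: str, sex: str) -> int | None:
    """Baseline (expected) copy number for a chromosome given sample sex.

    Returns ``None`` for combinations that are not analysed (Y in females):
    such probes are dropped entirely rather than compared to a baseline.
    """
    if sex not in (MALE, FEMALE):
        raise ValueError(f"unknown sex {sex!r}; expected 'male' or 'female'")
    kind = _chrom_kind(chrom)
    if kind == "autosome":
        return 2
    if kind == "X":
        return 2 if sex == FEMALE else 1
    # Y
    return 1 if sex == MALE else None


class ProbeMap:
    """Ordered genomic positions of array probes, the lattice for segmentation.

    Positions are 1-based and strictly increasing within each chromosome;
    probe ids are unique genome-wide.  Probe order in aligned state vectors is
    chromosome-major (chromosomes in map order, positions ascending within).
    """

    def __init__(self, chroms: Sequence[str],
                 ids: Mapping[str, np.ndarray],
                 pos: Mapping[str, np.ndarray]):
        self.chroms = list(chroms)
        self._ids = {c: np.asarray(ids[c], dtype=object) for c in self.chroms}
        self._pos = {c: np.asarray(pos[c], dtype=np.int64) for c in self.chroms}
        self._validate()
        # chromosome-major offsets into aligned per-sample state vectors
        self._offsets: dict[str, int] = {}
        off = 0
        for c in self.chroms:
            self._offsets[c] = off
            off += len(self._pos[c])
        self.n_probes = off

    def _validate(self) -> None:
        seen: set[str] = set()
        for c in self.chroms:
            p = self._pos[c]
            i = self._ids[c]
            if len(p) != len(i):
                raise ValueError(f"{c}: probe id/position length mismatch")
            if len(p) and (p < 1).any():
                raise ValueError(f"{c}: positions must be >= 1")
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"{c}: positions not strictly increasing")
            ids = set(i.tolist())
            if len(ids) != len(i) or ids & seen:
                raise ValueError("probe ids not unique genome-wide")
            seen |= ids

    # -- accessors ---------------------------------------------------------

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos[chrom]

    def probe_ids(self, chrom: str) -> np.ndarray:
        return self._ids[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        """Slice selecting this chromosome's probes in an aligned state vector."""
        off = self._offsets[chrom]
        return slice(off, off + len(self._pos[chrom]))

    def all_probe_ids(self) -> np.ndarray:
        if not self.chroms:
            return np.empty(0, dtype=object)
        return np.concatenate([self._ids[c] for c in self.chroms])

    def __len__(self) -> int:
        return self.n_probes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeMap):
            return NotImplemented
        return (self.chroms == other.chroms
                and all(np.array_equal(self._pos[c], other._pos[c])
                        and np.array_equal(self._ids[c], other._ids[c])
                        for c in self.chroms))

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int]]) -> "ProbeMap":
        """Build from (probe_id, chrom, pos) records, preserving chromosome order."""
        chroms: list[str] = []
        ids: dict[str, list[str]] = {}
        pos: dict[str, list[int]] = {}
        for pid, chrom, p in records:
            if chrom not in ids:
                chroms.append(chrom)
                ids[chrom] = []
                pos[chrom] = []
            ids[chrom].append(pid)
            pos[chrom].append(int(p))
        return cls(chroms,
                   {c: np.asarray(v, dtype=object) for c, v in ids.items()},
                   {c: np.asarray(v, dtype=np.int64) for c, v in pos.items()})


@dataclass(frozen=True)
class CnvSegment:
    """One contiguous gain or loss call in one sample.

    ``start``/``end`` are the positions of the first and last probe of the
    run, 1-based inclusive; ``length`` is ``end - start + 1``.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    direction: str  # GAIN or LOSS
    n_probes: int

    def __post_init__(self) -> None:
        if self.direction not in (GAIN, LOSS):
            raise ValueError(f"direction must be gain/loss, got {self.direction!r}")
        if self.end < self.start:
            raise ValueError("segment end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ExclusionRegions:
    """Genomic intervals removed from analysis, 1-based inclusive in memory."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def add(self, chrom: str, start: int, end: int, category: str = "centromere") -> None:
        if end < start:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        self.intervals.append((chrom, int(start), int(end), category))

    def by_chrom(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _cat in self.intervals:
            out.setdefault(chrom, []).append((start, end))
        return out


@dataclass
class ProbeCallTrack:
    """Integer copy-number state per probe for one sample.

    ``states`` is aligned with the ProbeMap's chromosome-major probe order
    (one state per probe; missing states are not representable).
    """

    sample_id: str
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 1:
            raise ValueError("states must be a 1-D array")


def mask_probes(pmap: ProbeMap, excl: ExclusionRegions) -> ProbeMap:
    """Remove every probe whose position falls inside any exclusion interval.

    Probe order is preserved; a chromosome whose probes are all excluded
    disappears from the map.  Exclusion chromosomes absent from the map are
    ignored (logged at debug level).
    """
    pmap2, _keep = mask_probes_with_index(pmap, excl)
    return pmap2


def mask_probes_with_index(pmap: ProbeMap,
                           excl: ExclusionRegions) -> tuple[ProbeMap, np.ndarray]:
    """Like :func:`mask_probes` but also return the boolean keep-mask over the
    input map's probe order, for subsetting aligned state vectors."""
    by_chrom = excl.by_chrom()
    for chrom in by_chrom:
        if chrom not in pmap.chroms:
            logger.debug("exclusion chromosome %s absent from probe map; ignored", chrom)
    keep_parts: list[np.ndarray] = []
    chroms: list[str] = []
    ids: dict[str, np.ndarray] = {}
    pos: dict[str, np.ndarray] = {}
    for chrom in pmap.chroms:
        p = pmap.positions(chrom)
        keep = np.ones(len(p), dtype=bool)
        for start, end in by_chrom.get(chrom, ()):  # few intervals per chrom
            keep &= ~((p >= start) & (p <= end))
        keep_parts.append(keep)
        if keep.any():
            chroms.append(chrom)
            ids[chrom] = pmap.probe_ids(chrom)[keep]
            pos[chrom] = p[keep]
    full = np.concatenate(keep_parts) if keep_parts else np.empty(0, dtype=bool)
    return ProbeMap(chroms, ids, pos), full


def segment_track(track: ProbeCallTrack, pmap: ProbeMap, sex: str,
                  min_probes: int = 10) -> list[CnvSegment]:
    """Call CNV segments as maximal same-direction probe runs.

    A run is a maximal stretch of consecutive probes (in map order) whose
    states are all strictly above ("gain") or all strictly below ("loss") the
    sex-appropriate baseline; runs shorter than ``min_probes`` are dropped.
    Female-Y probes are not analysed.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    if len(track.states) != pmap.n_probes:
        raise ValueError(
            f"track {track.sample_id!r} has {len(track.states)} states "
            f"for a map of {pmap.n_probes} probes")
    segments: list[CnvSegment] = []
    for chrom in pmap.chroms:
        baseline = expected_copy_number(chrom, sex)
        if baseline is None:
            continue
        states = np.asarray(track.states[pmap.chrom_slice(chrom)], dtype=np.int64)
        if states.size == 0:
            continue
        if (states < 0).any():
            raise ValueError(f"negative copy-number state in track {track.sample_id!r}")
        sign = np.sign(states - baseline)
        # run boundaries: indices where the sign changes
        change = np.flatnonzero(np.diff(sign)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(sign)]))  # exclusive
        pos = pmap.positions(chrom)
        for i0, i1 in zip(starts, ends):
            s = sign[i0]
            if s == 0 or i1 - i0 < min_probes:
                continue
            segments.append(CnvSegment(
                sample_id=track.sample_id,
                chrom=chrom,
                start=int(pos[i0]),
                end=int(pos[i1 - 1]),
                direction=GAIN if s > 0 else LOSS,
                n_probes=int(i1 - i0),
            ))
    return segments


def filter_by_length(segments: Iterable[CnvSegment],
                     min_length_bp: int = 100_000) -> list[CnvSegment]:
    """Keep segments whose length is strictly greater than ``min_length_bp``."""
    return [s for s in segments if s.length > min_length_bp]
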
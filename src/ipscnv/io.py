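"""File formats: probe maps, call matrices, manifests, BED, segment and
locus tables, JSON run summaries.

On-disk conventions
-------------------
* All package-native TSVs use 1-based inclusive coordinates and carry a
  comment header stating so.
* BED input/output is 0-based half-open and converted exactly on read/write
  (``[start0, end0)`` on disk becomes ``[start0+1, end0]`` in memory).
* Malformed rows raise :class:`ParseError` naming the file and line; rows
  are never silently skipped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .probes import (CnvSegment, ExclusionRegions, GAIN, LOSS, ProbeCallTrack,
                     ProbeMap)
from .specificity import Locus, Manifest, SampleRecord

_COORD_HEADER = f"# coordinates: 1-based inclusive; ipscnv {__version__}\n"


class ParseError(ValueError):
    def __init__(self, path, lineno: int | None, message: str):
        where = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{where}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _int_field(path, lineno, name: str, value: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(path, lineno, f"field {name!r}: not an integer: {value!r}")


# -- probe map --------------------------------------------------------------

def read_probe_map(path: str | Path) -> ProbeMap:
    records = []
    header_seen = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not header_seen:
            if fields != ["probe_id", "chrom", "pos"]:
                raise ParseError(path, lineno,
                                 "expected header 'probe_id\\tchrom\\tpos'")
            header_seen = True
            continue
        if len(fields) != 3:
            raise ParseError(path, lineno, f"expected 3 fields, got {len(fields)}")
        records.append((fields[0], fields[1],
                        _int_field(path, lineno, "pos", fields[2])))
    if not header_seen:
        raise ParseError(path, None, "empty probe map")
    try:
        return ProbeMap.from_records(records)
    except ValueError as exc:
        raise ParseError(path, None, str(exc))


def write_probe_map(pmap: ProbeMap, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        fh.write("probe_id\tchrom\tpos\n")
        for chrom in pmap.chroms:
            for pid, pos in zip(pmap.probe_ids(chrom), pmap.positions(chrom)):
                fh.write(f"{pid}\t{chrom}\t{pos}\n")
    return path


# -- call matrix ------------------------------------------------------------

def read_call_matrix(path: str | Path,
                     pmap: ProbeMap) -> dict[str, ProbeCallTrack]:
    """Read a probes-by-samples integer state matrix aligned to ``pmap``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "probe_id":
        raise ParseError(path, None, "first column must be 'probe_id'")
    expected = pmap.all_probe_ids()
    got = df["probe_id"].to_numpy(dtype=object)
    if len(got) != len(expected) or not (got == expected).all():
        raise ParseError(path, None,
                         "probe rows do not match the probe map (same probes, "
                         "same order, required)")
    tracks = {}
    for col in df.columns[1:]:
        states = df[col].to_numpy()
        if not np.issubdtype(states.dtype, np.integer):
            raise ParseError(path, None, f"sample column {col!r} is not integer")
        tracks[str(col)] = ProbeCallTrack(str(col), states.astype(np.int64))
    return tracks


def write_call_matrix(pmap: ProbeMap,
                      tracks: Mapping[str, ProbeCallTrack],
                      path: str | Path) -> Path:
    path = Path(path)
    sample_ids = list(tracks)
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        fh.write("probe_id\t" + "\t".join(sample_ids) + "\n")
        ids = pmap.all_probe_ids()
        cols = np.column_stack([np.asarray(tracks[s].states) for s in sample_ids])
        for pid, row in zip(ids, cols):
            fh.write(str(pid) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    return path


# -- manifest ---------------------------------------------------------------

_MANIFEST_HEADER = ["sample_id", "donor_id", "role", "sex"]


def read_manifest(path: str | Path) -> Manifest:
    records = []
    header_seen = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not header_seen:
            if fields != _MANIFEST_HEADER:
                raise ParseError(path, lineno,
                                 "expected header 'sample_id\\tdonor_id\\trole\\tsex'")
            header_seen = True
            continue
        if len(fields) != 4:
            raise ParseError(path, lineno, f"expected 4 fields, got {len(fields)}")
        try:
            records.append(SampleRecord(*fields))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
    if not header_seen:
        raise ParseError(path, None, "empty manifest")
    try:
        return Manifest(records)
    except ValueError as exc:
        raise ParseError(path, None, str(exc))


def write_manifest(manifest: Manifest, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_MANIFEST_HEADER) + "\n")
        for r in manifest.records:
            fh.write(f"{r.sample_id}\t{r.donor_id}\t{r.role}\t{r.sex}\n")
    return path


# -- BED (0-based half-open on disk) ----------------------------------------

def read_exclusions_bed(path: str | Path) -> ExclusionRegions:
    excl = ExclusionRegions()
    for lineno, line in _data_lines(path):
        if line.startswith(("track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(path, lineno, "BED needs >= 3 fields")
        start0 = _int_field(path, lineno, "start", fields[1])
        end0 = _int_field(path, lineno, "end", fields[2])
        if end0 <= start0:
            raise ParseError(path, lineno, f"empty/invalid interval [{start0}, {end0})")
        category = fields[3] if len(fields) > 3 else "centromere"
        excl.add(fields[0], start0 + 1, end0, category)
    return excl


def write_exclusions_bed(excl: ExclusionRegions, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, start, end, category in excl.intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{category}\n")
    return path


def read_genes_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    genes = []
    for lineno, line in _data_lines(path):
        if line.startswith(("track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(path, lineno, "gene BED needs chrom/start/end/name")
        start0 = _int_field(path, lineno, "start", fields[1])
        end0 = _int_field(path, lineno, "end", fields[2])
        if end0 <= start0:
            raise ParseError(path, lineno, f"empty/invalid interval [{start0}, {end0})")
        genes.append((fields[0], start0 + 1, end0, fields[3]))
    return genes


# -- segments ---------------------------------------------------------------

_SEGMENT_HEADER = ["sample_id", "chrom", "start", "end", "direction",
                   "n_probes", "length"]


def write_segments(segments: Iterable[CnvSegment], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        fh.write("\t".join(_SEGMENT_HEADER) + "\n")
        for s in segments:
            fh.write(f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t"
                     f"{s.direction}\t{s.n_probes}\t{s.length}\n")
    return path


def read_segments(path: str | Path) -> list[CnvSegment]:
    segments = []
    header_seen = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not header_seen:
            if fields != _SEGMENT_HEADER:
                raise ParseError(path, lineno,
                                 "expected header " + "\\t".join(_SEGMENT_HEADER))
            header_seen = True
            continue
        if len(fields) != 7:
            raise ParseError(path, lineno, f"expected 7 fields, got {len(fields)}")
        if fields[4] not in (GAIN, LOSS):
            raise ParseError(path, lineno, f"direction must be gain/loss, got {fields[4]!r}")
        start = _int_field(path, lineno, "start", fields[2])
        end = _int_field(path, lineno, "end", fields[3])
        seg = CnvSegment(fields[0], fields[1], start, end, fields[4],
                         _int_field(path, lineno, "n_probes", fields[5]))
        if seg.length != _int_field(path, lineno, "length", fields[6]):
            raise ParseError(path, lineno, "length column inconsistent with start/end")
        segments.append(seg)
    if not header_seen:
        raise ParseError(path, None, "empty segments file")
    return segments


# -- loci and reports -------------------------------------------------------

def write_loci(loci: Sequence[Locus], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        fh.write("chrom\tstart\tend\tstratum\tn_ipsc_gain\tn_ipsc_loss\t"
                 "n_ctrl_gain\tn_ctrl_loss\tmember_count\n")
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.stratum}\t"
                     f"{l.carriers_ipsc_gain}\t{l.carriers_ipsc_loss}\t"
                     f"{l.carriers_control_gain}\t{l.carriers_control_loss}\t"
                     f"{len(l.members)}\n")
    return path


def write_hotspot_report(results, path: str | Path,
                         genes_by_locus: Sequence[Sequence[str]] | None = None,
                         bands: Mapping[tuple[str, int, int], str] | None = None) -> Path:
    """Hotspot table mirroring the printed layout: per-direction carrier
    counts in each cohort, formatted p, gene list."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        fh.write("chrom\tstart\tend\tlocus_band\tdup_ipsc\tdel_ipsc\t"
                 "dup_ctrl\tdel_ctrl\tp\tis_hotspot\tgenes\n")
        for i, r in enumerate(results):
            l = r.locus
            band = (bands or {}).get((l.chrom, l.start, l.end), "")
            genes = ",".join((genes_by_locus or [[]] * len(results))[i]) \
                if genes_by_locus else ""
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{band}\t"
                     f"{l.carriers_ipsc_gain}\t{l.carriers_ipsc_loss}\t"
                     f"{l.carriers_control_gain}\t{l.carriers_control_loss}\t"
                     f"{r.p_display}\t{int(r.is_hotspot)}\t{genes}\n")
    return path


def write_summary(summary: Mapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
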
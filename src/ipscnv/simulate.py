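"""Synthetic probe-level cohorts with planted truth.

The generator emulates the study design the pipeline targets: paired
parental/iPSC samples sharing inherited CNVs, de novo CNVs arising only in
iPSC lines (including recurrent "hotspot" loci with per-line carrier
probabilities), polymorphic regions whose presence is drawn independently
for each member of a pair (so they appear/disappear across reprogramming),
a large population control cohort with low carrier frequencies, and
isolated probe-level noise that can never satisfy the 10-probe run rule.

The default miniature genome is four 180-Mb autosomes plus a 120-Mb X at
5-kb probe spacing (168k probes) — array-like density at desk scale.
Planted event boundaries snap to probe positions, so truth spans equal
recoverable spans exactly, and planted events of different categories never
overlap (rejection sampling), keeping truth evaluation unambiguous.

Two defaults are fixed by explicit design calculations rather than taste:

* Planted hotspot carrier probabilities (0.16-0.45 across ten loci) come
  from a binomial power calculation: a planted locus must exceed the strict
  5% realized-frequency threshold (>=5 of 82 carrier lines, or >=3 of 42
  for the female-stratified X loci) with >=99.8% probability, so all ten
  loci are recoverable in essentially every simulated cohort.
* The genome length and the background event-length bounds (log-uniform
  110 kb - 1 Mb) keep genome occupancy by the ~370 random inherited +
  de novo events near 0.1, so the chance that background events chain (by
  single linkage at 10% reciprocal overlap) into an accidental >=5-carrier
  locus — a false "recurrent" CNV — stays at the few-percent level per
  cohort.  On a denser toy genome the background would no longer be
  low-frequency at the locus level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .probes import (CnvSegment, FEMALE, GAIN, LOSS, MALE, ProbeCallTrack,
                     ProbeMap, expected_copy_number)
from .specificity import (Locus, Manifest, ROLE_CONTROL, ROLE_IPSC,
                          ROLE_PARENTAL, SampleRecord)

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class HotspotSpec:
    """A recurrent de novo locus planted only in iPSC tracks."""
    chrom: str
    start: int
    end: int
    carrier_p: float
    gain_frac: float = 1.0        # probability a carrier's event is a gain
    restrict_sex: str | None = None  # plant only in lines of this sex


@dataclass(frozen=True)
class PolymorphicSpec:
    """A region drawn independently for every sample (study and control)."""
    chrom: str
    start: int
    end: int
    presence_p: float = 0.15          # per parental sample / per iPSC line
    control_presence_p: float = 0.15  # per control subject
    direction: str = GAIN


@dataclass(frozen=True)
class ControlLocusSpec:
    """A population CNV planted only in control subjects."""
    chrom: str
    start: int
    end: int
    carrier_freq: float
    direction: str = GAIN


def _default_genome() -> tuple[tuple[str, int, int], ...]:
    return (("chr1", 180_000_000, 5000), ("chr2", 180_000_000, 5000),
            ("chr3", 180_000_000, 5000), ("chr4", 180_000_000, 5000),
            ("chrX", 120_000_000, 5000))


def _default_hotspots() -> tuple[HotspotSpec, ...]:
    return (
        HotspotSpec("chr1", 5_000_000, 5_400_000, 0.16),
        HotspotSpec("chr1", 30_000_000, 30_300_000, 0.19),
        HotspotSpec("chr2", 8_000_000, 8_500_000, 0.22),
        HotspotSpec("chr2", 40_000_000, 40_250_000, 0.25),
        HotspotSpec("chr3", 12_000_000, 12_600_000, 0.29),
        HotspotSpec("chr3", 45_000_000, 45_350_000, 0.33),
        HotspotSpec("chr4", 10_000_000, 10_800_000, 0.37, gain_frac=0.9),
        HotspotSpec("chr4", 50_000_000, 50_400_000, 0.40),
        HotspotSpec("chrX", 15_000_000, 15_500_000, 0.30, restrict_sex=FEMALE),
        HotspotSpec("chrX", 40_000_000, 40_200_000, 0.45, restrict_sex=FEMALE),
    )


def _default_polymorphic() -> tuple[PolymorphicSpec, ...]:
    return (
        PolymorphicSpec("chr1", 45_000_000, 45_300_000),
        PolymorphicSpec("chr2", 20_000_000, 20_300_000),
        PolymorphicSpec("chr2", 52_000_000, 52_240_000),
        PolymorphicSpec("chr3", 25_000_000, 25_400_000),
        PolymorphicSpec("chr3", 55_000_000, 55_200_000),
        PolymorphicSpec("chr4", 30_000_000, 30_300_000),
        PolymorphicSpec("chr4", 57_000_000, 57_160_000),
    )


def _default_control_loci() -> tuple[ControlLocusSpec, ...]:
    return (
        ControlLocusSpec("chr1", 18_000_000, 18_300_000, 0.05),
        ControlLocusSpec("chr1", 55_000_000, 55_200_000, 0.01, direction=LOSS),
        ControlLocusSpec("chr2", 33_000_000, 33_200_000, 0.03),
        ControlLocusSpec("chr3", 5_000_000, 5_250_000, 0.02, direction=LOSS),
        ControlLocusSpec("chr4", 22_000_000, 22_300_000, 0.04),
    )


@dataclass
class SimConfig:
    """Study-design parameters of one synthetic cohort.

    Sample sizes default to the study layout (82 donors with one iPSC clone
    each, 42 female; 1093 controls, 568 female).  Inherited CNVs arrive at
    ~2 per donor and background de novo CNVs at ~2.5 per line (Poisson),
    with log-uniform lengths of 110 kb - 1.5 Mb so most, but not all,
    survive the >100 kb filter with >=10 probes.  Probe noise is isolated
    single-probe excursions at 1e-4 per probe per track.
    """

    seed: int = 0
    genome: tuple[tuple[str, int, int], ...] = field(default_factory=_default_genome)
    n_donors: int = 82
    clones_per_donor: int = 1
    female_donors: int = 42
    n_controls: int = 1093
    female_controls: int = 568
    inherited_rate: float = 2.0
    de_novo_rate: float = 2.5
    event_length_bp: tuple[int, int] = (110_000, 1_000_000)  # log-uniform
    hotspots: tuple[HotspotSpec, ...] = field(default_factory=_default_hotspots)
    polymorphic: tuple[PolymorphicSpec, ...] = field(default_factory=_default_polymorphic)
    control_loci: tuple[ControlLocusSpec, ...] = field(default_factory=_default_control_loci)
    noise_rate: float = 1e-4
    noise_run_len: int = 1

    def validate(self) -> None:
        spacing = {c: sp for c, _ln, sp in self.genome}
        lengths = {c: ln for c, ln, _sp in self.genome}
        if not (1 <= self.noise_run_len < 10):
            raise ValueError("noise runs must be shorter than 10 probes")
        if not (0 <= self.female_donors <= self.n_donors):
            raise ValueError("female_donors out of range")
        if not (0 <= self.female_controls <= self.n_controls):
            raise ValueError("female_controls out of range")
        planted = (list(self.hotspots) + list(self.polymorphic)
                   + list(self.control_loci))
        for spec in planted:
            if spec.chrom not in spacing:
                raise ValueError(f"planted locus on unknown chromosome {spec.chrom}")
            if spec.end > lengths[spec.chrom]:
                raise ValueError(f"planted locus beyond {spec.chrom} end")
            n_probes = _span_probe_count(spec.start, spec.end, spacing[spec.chrom])
            if n_probes < 10:
                raise ValueError(
                    f"planted span {spec.chrom}:{spec.start}-{spec.end} holds "
                    f"{n_probes} probes (< 10) at {spacing[spec.chrom]} bp spacing")
            if spec.end - spec.start + 1 <= 100_000:
                raise ValueError(
                    f"planted span {spec.chrom}:{spec.start}-{spec.end} "
                    "does not exceed 100 kb")
        for i, a in enumerate(planted):
            for b in planted[i + 1:]:
                if (a.chrom == b.chrom and a.start <= b.end
                        and b.start <= a.end):
                    raise ValueError(
                        "planted spans of different events overlap: "
                        f"{a.chrom}:{a.start}-{a.end} vs {b.chrom}:{b.start}-{b.end}")


def _span_probe_count(start: int, end: int, spacing: int) -> int:
    first = -(-start // spacing)              # ceil(start/spacing)
    last = end // spacing
    return max(0, last - first + 1)


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class SyntheticCohort:
    probe_map: ProbeMap
    matrix: np.ndarray           # (n_samples, n_probes) int8
    sample_ids: list[str]
    manifest: Manifest
    truth: pd.DataFrame
    config: SimConfig

    def track(self, sample_id: str) -> ProbeCallTrack:
        return ProbeCallTrack(sample_id,
                              self.matrix[self.sample_ids.index(sample_id)])

    def tracks(self) -> dict[str, ProbeCallTrack]:
        return {sid: ProbeCallTrack(sid, self.matrix[i])
                for i, sid in enumerate(self.sample_ids)}


# ---------------------------------------------------------------------------
# generation


def generate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate a cohort; deterministic (byte-identical) given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # probe lattice
    chroms = [c for c, _l, _s in cfg.genome]
    ids = {}
    pos = {}
    for chrom, length, spacing in cfg.genome:
        p = np.arange(spacing, length + 1, spacing, dtype=np.int64)
        pos[chrom] = p
        ids[chrom] = np.array([f"{chrom}_p{i:06d}" for i in range(len(p))],
                              dtype=object)
    pmap = ProbeMap(chroms, ids, pos)

    # manifest
    donor_sexes = np.array([FEMALE] * cfg.female_donors
                           + [MALE] * (cfg.n_donors - cfg.female_donors))
    rng.shuffle(donor_sexes)
    control_sexes = np.array([FEMALE] * cfg.female_controls
                             + [MALE] * (cfg.n_controls - cfg.female_controls))
    rng.shuffle(control_sexes)
    records: list[SampleRecord] = []
    for d in range(cfg.n_donors):
        donor = f"D{d + 1:03d}"
        records.append(SampleRecord(f"{donor}_P", donor, ROLE_PARENTAL,
                                    donor_sexes[d]))
        for j in range(cfg.clones_per_donor):
            records.append(SampleRecord(f"{donor}_iPSC{j + 1}", donor,
                                        ROLE_IPSC, donor_sexes[d]))
    for c in range(cfg.n_controls):
        records.append(SampleRecord(f"CTRL{c + 1:04d}", f"CTRL{c + 1:04d}",
                                    ROLE_CONTROL, control_sexes[c]))
    manifest = Manifest(records)
    sample_ids = [r.sample_id for r in records]
    row_of = {sid: i for i, sid in enumerate(sample_ids)}
    sex_of = {r.sample_id: r.sex for r in records}

    # baseline matrix
    matrix = np.full((len(records), pmap.n_probes), 2, dtype=np.int8)
    male_rows = [i for i, r in enumerate(records) if r.sex == MALE]
    for chrom in chroms:
        base_m = expected_copy_number(chrom, MALE)
        sl = pmap.chrom_slice(chrom)
        if base_m is None:  # female Y handled below; male Y baseline exists
            continue
        if base_m != 2:
            matrix[male_rows, sl] = base_m
        base_f = expected_copy_number(chrom, FEMALE)
        if base_f is None:  # Y in females: not analysed; park at 1
            female_rows = [i for i, r in enumerate(records) if r.sex == FEMALE]
            matrix[female_rows, sl] = 1

    # planted-span bookkeeping (global probe-index intervals)
    reserved: list[tuple[int, int]] = []

    def span_to_index(chrom: str, start: int, end: int) -> tuple[int, int]:
        p = pmap.positions(chrom)
        off = pmap.chrom_slice(chrom).start
        i0 = int(np.searchsorted(p, start, side="left"))
        i1 = int(np.searchsorted(p, end, side="right")) - 1
        return off + i0, off + i1

    for spec in (list(cfg.hotspots) + list(cfg.polymorphic)
                 + list(cfg.control_loci)):
        reserved.append(span_to_index(spec.chrom, spec.start, spec.end))
    reserved.sort()
    res_start = np.array([a for a, _b in reserved], dtype=np.int64)
    res_end = np.array([b for _a, b in reserved], dtype=np.int64)

    def hits_reserved(g0: int, g1: int) -> bool:
        k = int(np.searchsorted(res_end, g0, side="left"))
        return k < len(res_start) and res_start[k] <= g1

    sample_events: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(records))}
    truth_rows: list[tuple] = []

    def apply_event(row: int, chrom: str, g0: int, g1: int, direction: str,
                    category: str, locus_id: str, magnitude: int = 1) -> None:
        sid = sample_ids[row]
        base = expected_copy_number(chrom, sex_of[sid])
        if base is None:
            return
        state = base + magnitude if direction == GAIN else max(base - magnitude, 0)
        matrix[row, g0:g1 + 1] = state
        sample_events[row].append((g0, g1))
        off = pmap.chrom_slice(chrom).start
        p = pmap.positions(chrom)
        truth_rows.append((category, sid, chrom,
                           int(p[g0 - off]), int(p[g1 - off]),
                           direction, locus_id))

    # random (inherited / de novo) event placement with rejection sampling
    chrom_lengths = np.array([ln for _c, ln, _s in cfg.genome], dtype=float)
    chrom_weights = chrom_lengths / chrom_lengths.sum()
    lo, hi = cfg.event_length_bp

    def draw_span(existing: list[tuple[int, int]]) -> tuple[str, int, int] | None:
        for _attempt in range(60):
            ci = int(rng.choice(len(chroms), p=chrom_weights))
            chrom, length, spacing = cfg.genome[ci]
            ev_len = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            start = int(rng.integers(spacing, max(length - ev_len, spacing) + 1))
            g0, g1 = span_to_index(chrom, start, start + ev_len - 1)
            if g1 < g0:
                continue
            if hits_reserved(g0, g1):
                continue
            if any(a <= g1 and g0 <= b for a, b in existing):
                continue
            return chrom, g0, g1
        return None

    # inherited CNVs: both members of every pair
    for d in range(cfg.n_donors):
        donor = f"D{d + 1:03d}"
        rows = [row_of[f"{donor}_P"]] + [row_of[f"{donor}_iPSC{j + 1}"]
                                         for j in range(cfg.clones_per_donor)]
        existing: list[tuple[int, int]] = []
        for _k in range(rng.poisson(cfg.inherited_rate)):
            drawn = draw_span(existing)
            if drawn is None:
                continue
            chrom, g0, g1 = drawn
            existing.append((g0, g1))
            direction = GAIN if rng.random() < 0.5 else LOSS
            for row in rows:
                apply_event(row, chrom, g0, g1, direction, "inherited", "")

    # background de novo CNVs: iPSC lines only
    for r in manifest.samples(ROLE_IPSC):
        row = row_of[r.sample_id]
        for _k in range(rng.poisson(cfg.de_novo_rate)):
            drawn = draw_span(sample_events[row])
            if drawn is None:
                continue
            chrom, g0, g1 = drawn
            direction = GAIN if rng.random() < 0.5 else LOSS
            apply_event(row, chrom, g0, g1, direction, "de_novo", "")

    # planted hotspots: iPSC lines only
    for h, spec in enumerate(cfg.hotspots):
        locus_id = f"hotspot_{h + 1}"
        g0, g1 = span_to_index(spec.chrom, spec.start, spec.end)
        for r in manifest.samples(ROLE_IPSC):
            if spec.restrict_sex is not None and r.sex != spec.restrict_sex:
                continue
            if rng.random() >= spec.carrier_p:
                continue
            direction = GAIN if rng.random() < spec.gain_frac else LOSS
            magnitude = 2 if (direction == GAIN and rng.random() < 0.2) else 1
            apply_event(row_of[r.sample_id], spec.chrom, g0, g1, direction,
                        "hotspot_member", locus_id, magnitude)

    # polymorphic regions: independent presence per study sample and control
    for q, spec in enumerate(cfg.polymorphic):
        locus_id = f"polymorphic_{q + 1}"
        g0, g1 = span_to_index(spec.chrom, spec.start, spec.end)
        for r in records:
            if r.role == ROLE_CONTROL:
                p_present = spec.control_presence_p
                category = "control"
            else:
                p_present = spec.presence_p
                category = "polymorphic_member"
            if rng.random() < p_present:
                apply_event(row_of[r.sample_id], spec.chrom, g0, g1,
                            spec.direction, category, locus_id)

    # population control loci: controls only
    for q, spec in enumerate(cfg.control_loci):
        locus_id = f"control_{q + 1}"
        g0, g1 = span_to_index(spec.chrom, spec.start, spec.end)
        for r in manifest.samples(ROLE_CONTROL):
            if rng.random() < spec.carrier_freq:
                apply_event(row_of[r.sample_id], spec.chrom, g0, g1,
                            spec.direction, "control", locus_id)

    # isolated probe noise (kept clear of planted spans and of itself)
    run = cfg.noise_run_len
    for row in range(len(records)):
        k = rng.poisson(cfg.noise_rate * pmap.n_probes)
        placed: list[int] = []
        for _j in range(k):
            for _attempt in range(20):
                g0 = int(rng.integers(0, pmap.n_probes - run + 1))
                g1 = g0 + run - 1
                if hits_reserved(max(g0 - 2, 0), g1 + 2):
                    continue
                if any(a - run - 1 <= g1 and g0 <= b + run + 1
                       for a, b in sample_events[row]):
                    continue
                if any(abs(g0 - q) <= run + 1 for q in placed):
                    continue
                placed.append(g0)
                # stay within one chromosome
                chrom = _chrom_at(pmap, g0)
                if _chrom_at(pmap, g1) != chrom:
                    continue
                sid = sample_ids[row]
                base = expected_copy_number(chrom, sex_of[sid])
                if base is None:
                    break
                up = rng.random() < 0.5
                state = base + 1 if up else max(base - 1, 0)
                if state == base:  # loss off a baseline of 0 is impossible
                    state = base + 1
                matrix[row, g0:g1 + 1] = state
                break

    truth = pd.DataFrame(truth_rows, columns=[
        "category", "sample_id", "chrom", "start", "end", "direction",
        "locus_id"])
    return SyntheticCohort(pmap, matrix, sample_ids, manifest, truth, cfg)


def _chrom_at(pmap: ProbeMap, global_idx: int) -> str:
    for chrom in pmap.chroms:
        sl = pmap.chrom_slice(chrom)
        if sl.start <= global_idx < sl.stop:
            return chrom
    raise IndexError(global_idx)


# ---------------------------------------------------------------------------
# printed-table fixture (statistics regression) and worked example

#: The ten hotspot contingency rows as printed: chrom, start, end, cytoband,
#: iPSC duplication/deletion carriers, control duplication/deletion carriers.
HOTSPOT_TABLE_ROWS: tuple[tuple, ...] = (
    ("chr4", 62690392, 62945462, "q13.1", 5, 0, 1, 0),
    ("chr4", 92930866, 94220988, "q22.1-q22.2", 38, 2, 0, 1),
    ("chr5", 147202104, 147449067, "q32", 8, 0, 0, 0),
    ("chr6", 94291842, 94849832, "q16.1", 2, 2, 0, 0),
    ("chr7", 121549706, 122245008, "q31.32", 12, 0, 1, 0),
    ("chr10", 54932474, 55398702, "q21.1", 6, 0, 0, 0),
    ("chr13", 55695571, 56471149, "q21.1", 5, 0, 0, 2),
    ("chr20", 29620219, 31558271, "q11.21", 5, 0, 0, 0),
    ("chrX", 112880475, 113795367, "q23", 27, 0, 0, 0),
    ("chrX", 114766295, 114897324, "q23", 8, 0, 0, 0),
)

N_IPSC = 82
N_CONTROL = 1093
N_IPSC_FEMALE = 42
N_CONTROL_FEMALE = 568


def hotspot_table_contingency() -> list[dict]:
    """Pooled 2x2 carrier tables for the ten printed hotspot rows.

    X-chromosome rows use the female strata (42 iPSC lines vs 568 controls);
    autosomal rows use the full cohorts (82 vs 1093).
    """
    out = []
    for chrom, start, end, band, dup_i, del_i, dup_c, del_c in HOTSPOT_TABLE_ROWS:
        sex_stratified = chrom in ("chrX", "X")
        n_ipsc = N_IPSC_FEMALE if sex_stratified else N_IPSC
        n_ctrl = N_CONTROL_FEMALE if sex_stratified else N_CONTROL
        ci = dup_i + del_i  # directions never co-occur in one printed sample
        cc = dup_c + del_c
        out.append({
            "label": f"{chrom}:{start}-{end} {band}",
            "chrom": chrom, "start": start, "end": end, "band": band,
            "table": np.array([[ci, n_ipsc - ci], [cc, n_ctrl - cc]]),
            "n_ipsc": n_ipsc, "n_control": n_ctrl,
        })
    return out


def hotspot_table_fixture() -> tuple[Manifest, list[Locus]]:
    """Reconstruct loci and a matching manifest from the printed table.

    Carrier identities are synthetic (the table prints only counts); female
    lines are assigned first so X-row carriers fall in the female stratum.
    This reconstruction feeds carrier_frequency/call_hotspots regression
    tests without any array data.
    """
    records = []
    for i in range(N_IPSC):
        donor = f"T1D{i + 1:03d}"
        sex = FEMALE if i < N_IPSC_FEMALE else MALE
        records.append(SampleRecord(f"{donor}_P", donor, ROLE_PARENTAL, sex))
        records.append(SampleRecord(f"{donor}_iPSC1", donor, ROLE_IPSC, sex))
    for i in range(N_CONTROL):
        sex = FEMALE if i < N_CONTROL_FEMALE else MALE
        records.append(SampleRecord(f"T1C{i + 1:04d}", f"T1C{i + 1:04d}",
                                    ROLE_CONTROL, sex))
    manifest = Manifest(records)
    ipsc_ids = [r.sample_id for r in manifest.samples(ROLE_IPSC)]
    ctrl_ids = [r.sample_id for r in manifest.samples(ROLE_CONTROL)]
    loci = []
    for chrom, start, end, band, dup_i, del_i, dup_c, del_c in HOTSPOT_TABLE_ROWS:
        members = []
        gain_set, loss_set = set(), set()
        for k in range(dup_i):
            sid = ipsc_ids[k]
            members.append(CnvSegment(sid, chrom, start, end, GAIN, 10))
            gain_set.add(sid)
        for k in range(del_i):
            sid = ipsc_ids[dup_i + k]
            members.append(CnvSegment(sid, chrom, start, end, LOSS, 10))
            loss_set.add(sid)
        locus = Locus(chrom=chrom, start=start, end=end,
                      members=tuple(members),
                      stratum=("female_only" if chrom in ("chrX", "X")
                               else "all"))
        locus.ipsc_carriers = {GAIN: gain_set, LOSS: loss_set}
        locus.control_carriers = {GAIN: set(ctrl_ids[:dup_c]),
                                  LOSS: set(ctrl_ids[dup_c:dup_c + del_c])}
        locus.parental_carriers = set()
        loci.append(locus)
    return manifest, loci


def worked_example() -> tuple[ProbeMap, dict[str, ProbeCallTrack], Manifest,
                              list[CnvSegment]]:
    """A hand-checkable probe-track example: one 600-kb chromosome, 60 probes
    at 10-kb spacing, one donor pair.

    The parental track carries a 15-probe inherited gain (410-550 kb); the
    iPSC track carries the same gain, a 15-probe de novo loss (60-200 kb),
    a 9-probe gain run (too short to call) and one isolated noise probe.
    Expected segments (>=10 probes, then >100 kb) are returned alongside.
    """
    spacing = 10_000
    p = np.arange(spacing, 600_001, spacing, dtype=np.int64)
    pmap = ProbeMap(["chr1"], {"chr1": np.array(
        [f"wp{i:03d}" for i in range(len(p))], dtype=object)}, {"chr1": p})
    parental = np.full(60, 2, dtype=np.int64)
    parental[40:55] = 3                      # inherited gain, probes 41..55
    ipsc = parental.copy()
    ipsc[5:20] = 1                           # de novo loss, probes 6..20
    ipsc[25] = 3                             # isolated noise probe
    ipsc[28:37] = 3                          # 9-probe run: below threshold
    control = np.full(60, 2, dtype=np.int64)  # one quiet control subject
    tracks = {"W1_P": ProbeCallTrack("W1_P", parental),
              "W1_iPSC1": ProbeCallTrack("W1_iPSC1", ipsc),
              "WC1": ProbeCallTrack("WC1", control)}
    manifest = Manifest([
        SampleRecord("W1_P", "W1", ROLE_PARENTAL, FEMALE),
        SampleRecord("W1_iPSC1", "W1", ROLE_IPSC, FEMALE),
        SampleRecord("WC1", "WC1", ROLE_CONTROL, FEMALE),
    ])
    expected = [
        CnvSegment("W1_P", "chr1", 410_000, 550_000, GAIN, 15),
        CnvSegment("W1_iPSC1", "chr1", 60_000, 200_000, LOSS, 15),
        CnvSegment("W1_iPSC1", "chr1", 410_000, 550_000, GAIN, 15),
    ]
    return pmap, tracks, manifest, expected


def write_fixture_suite(outdir: str | Path) -> dict[str, Path]:
    """Write the printed-table fixture and the worked probe-track example."""
    from . import io as iomod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    t1 = outdir / "hotspot_table.tsv"
    with open(t1, "w") as fh:
        fh.write("# pooled carrier counts; cohorts: 82 iPSC lines vs 1093 "
                 "controls (X rows: 42 female lines vs 568 female controls)\n")
        fh.write("chrom\tstart\tend\tband\tdup_ipsc\tdel_ipsc\tdup_ctrl\tdel_ctrl\n")
        for row in HOTSPOT_TABLE_ROWS:
            fh.write("\t".join(str(x) for x in row) + "\n")
    paths["hotspot_table"] = t1

    pmap, tracks, manifest, expected = worked_example()
    paths["probe_map"] = iomod.write_probe_map(pmap, outdir / "worked_probe_map.tsv")
    paths["calls"] = iomod.write_call_matrix(
        pmap, tracks, outdir / "worked_calls.tsv")
    paths["manifest"] = iomod.write_manifest(manifest, outdir / "worked_manifest.tsv")
    paths["expected_segments"] = iomod.write_segments(
        expected, outdir / "worked_expected_segments.tsv")
    return paths
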
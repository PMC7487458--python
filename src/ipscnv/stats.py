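"""Cohort-level statistics: carrier frequencies, likelihood-ratio chi-square
(G) tests, hotspot and polymorphic-region classification, CNV burden and
size-distribution summaries.

A *hotspot* is a locus whose iPSC carrier frequency exceeds 5% while no
paired parental sample carries it and the control-cohort carrier frequency
is below 0.2%, with a G-test p-value at or below the Bonferroni-adjusted
threshold (alpha divided by the number of loci tested in the run).

A *polymorphic region with frequent rearrangement* is a region common in the
study pool (parental + iPSC, frequency > 5%) whose frequency does not differ
from the population controls (G-test p > 0.05) and which is present in
exactly one member of a parental/iPSC pair (an XOR, "mutually exclusive"
event) in more than 10 donors.

Autosomal loci are analysed in all samples; sex-chromosome loci within one
sex stratum (carriers and denominators restricted to that sex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .probes import CnvSegment, GAIN, LOSS, FEMALE, MALE
from .specificity import (Locus, Manifest, ROLE_CONTROL, ROLE_IPSC,
                          ROLE_PARENTAL, is_sex_chrom, span_carriers)

STRATUM_ALL = "all"
STRATUM_FEMALE = "female_only"
STRATUM_MALE = "male_only"


def _chrom_sort_key(chrom: str):
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    try:
        return (0, int(name))
    except ValueError:
        return (1, name)


# -- likelihood-ratio chi-square -------------------------------------------

def g_test(table) -> tuple[float, float]:
    """Likelihood-ratio chi-square (G) test of independence.

    G = 2 * sum O_ij * ln(O_ij / E_ij), with expectations from the row and
    column margins, convention 0*ln(0) = 0 and no continuity correction.
    The p-value is the upper-tail chi-square probability at
    df = (rows-1)*(cols-1).  A table with an all-zero row or column margin
    is uninformative and returns (0, 1).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("g_test expects a 2-D contingency table")
    if (obs < 0).any():
        raise ValueError("negative counts in contingency table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0
    expected = np.outer(rows, cols) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = max(2.0 * float(terms.sum()), 0.0)
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return g, float(sps.chi2.sf(g, df))


# -- carrier bookkeeping ---------------------------------------------------

def annotate_carriers(loci: Sequence[Locus], manifest: Manifest,
                      control_segments: Sequence[CnvSegment] = (),
                      parental_segments: Sequence[CnvSegment] = (),
                      threshold: float = 0.10) -> None:
    """Fill per-locus carrier sets and sex stratum in place.

    iPSC carriers come from the locus members themselves; control and
    parental carriers are samples with a segment at >= ``threshold``
    reciprocal overlap with the locus span (the merge criterion).  One sample
    counts once per direction however many member segments it contributes.
    """
    for locus in loci:
        locus.ipsc_carriers = {GAIN: set(), LOSS: set()}
        for m in locus.members:
            if manifest.by_id[m.sample_id].role == ROLE_IPSC:
                locus.ipsc_carriers[m.direction].add(m.sample_id)
        ctrl = span_carriers(locus, control_segments, threshold)
        locus.control_carriers = {
            GAIN: {s for s in ctrl[GAIN]
                   if manifest.by_id[s].role == ROLE_CONTROL},
            LOSS: {s for s in ctrl[LOSS]
                   if manifest.by_id[s].role == ROLE_CONTROL},
        }
        par = span_carriers(locus, parental_segments, threshold)
        locus.parental_carriers = {
            s for s in par[GAIN] | par[LOSS]
            if manifest.by_id[s].role == ROLE_PARENTAL}
        locus.stratum = _stratum_for(locus, manifest)


def _stratum_for(locus: Locus, manifest: Manifest) -> str:
    if not is_sex_chrom(locus.chrom):
        return STRATUM_ALL
    carriers = locus.carriers("ipsc")
    if not carriers:  # fall back to member samples of any role
        carriers = {m.sample_id for m in locus.members}
    n_female = sum(manifest.by_id[s].sex == FEMALE for s in carriers)
    n_male = len(carriers) - n_female
    return STRATUM_FEMALE if n_female >= n_male else STRATUM_MALE


def _stratum_sex(stratum: str) -> str | None:
    return {STRATUM_ALL: None, STRATUM_FEMALE: FEMALE, STRATUM_MALE: MALE}[stratum]


def _restrict(sample_ids: Iterable[str], manifest: Manifest,
              sex: str | None) -> set[str]:
    if sex is None:
        return set(sample_ids)
    return {s for s in sample_ids if manifest.by_id[s].sex == sex}


def carrier_frequency(locus: Locus, manifest: Manifest) -> tuple[float, float]:
    """(iPSC, control) carrier frequencies within the locus stratum.

    Carriers are distinct samples with at least one qualifying segment of any
    direction; denominators are the stratum cohort sizes (all lines for
    autosomes, same-sex subsets for X/Y).
    """
    sex = _stratum_sex(locus.stratum)
    n_ipsc = manifest.cohort_size(ROLE_IPSC, sex)
    n_ctrl = manifest.cohort_size(ROLE_CONTROL, sex)
    if n_ipsc == 0 or n_ctrl == 0:
        raise ValueError(
            f"empty {locus.stratum} stratum for locus "
            f"{locus.chrom}:{locus.start}-{locus.end}")
    ci = len(_restrict(locus.carriers("ipsc"), manifest, sex))
    cc = len(_restrict(locus.carriers("control"), manifest, sex))
    return ci / n_ipsc, cc / n_ctrl


# -- hotspot classification ------------------------------------------------

@dataclass
class HotspotResult:
    locus: Locus
    freq_ipsc: float
    freq_control: float
    g: float
    p: float
    alpha_adjusted: float
    is_hotspot: bool
    direction_summary: tuple[int, int]  # (n gain carriers, n loss carriers)

    @property
    def p_display(self) -> str:
        return "< 0.0001" if self.p < 1e-4 else f"{self.p:.4g}"


def call_hotspots(loci: Sequence[Locus], manifest: Manifest,
                  alpha: float = 0.05, hotspot_freq: float = 0.05,
                  control_freq: float = 0.002,
                  pooled: bool = True) -> list[HotspotResult]:
    """Test every locus and flag reprogramming-associated CNV hotspots.

    The Bonferroni denominator is the number of loci actually tested in this
    run (``alpha_adjusted = alpha / len(loci)``).  Loci must have been
    annotated with carriers (:func:`annotate_carriers`).  ``pooled`` selects
    the default 2x2 test on carriers of any direction; ``pooled=False`` uses
    a per-direction 2x3 table (gain / loss / neither).
    """
    m = len(loci)
    if m == 0:
        return []
    alpha_adjusted = alpha / m
    results = []
    for locus in loci:
        sex = _stratum_sex(locus.stratum)
        n_ipsc = manifest.cohort_size(ROLE_IPSC, sex)
        n_ctrl = manifest.cohort_size(ROLE_CONTROL, sex)
        freq_ipsc, freq_control = carrier_frequency(locus, manifest)
        gain_i = _restrict(locus.ipsc_carriers[GAIN], manifest, sex)
        loss_i = _restrict(locus.ipsc_carriers[LOSS], manifest, sex)
        if pooled:
            ci = len(_restrict(locus.carriers("ipsc"), manifest, sex))
            cc = len(_restrict(locus.carriers("control"), manifest, sex))
            table = [[ci, n_ipsc - ci], [cc, n_ctrl - cc]]
        else:
            gain_c = _restrict(locus.control_carriers[GAIN], manifest, sex)
            loss_c = _restrict(locus.control_carriers[LOSS], manifest, sex)
            table = [
                [len(gain_i), len(loss_i),
                 n_ipsc - len(gain_i | loss_i)],
                [len(gain_c), len(loss_c),
                 n_ctrl - len(gain_c | loss_c)],
            ]
        g, p = g_test(table)
        is_hotspot = (freq_ipsc > hotspot_freq
                      and freq_control < control_freq
                      and p <= alpha_adjusted
                      and not locus.parental_carriers)
        results.append(HotspotResult(
            locus=locus, freq_ipsc=freq_ipsc, freq_control=freq_control,
            g=g, p=p, alpha_adjusted=alpha_adjusted, is_hotspot=is_hotspot,
            direction_summary=(len(gain_i), len(loss_i))))
    results.sort(key=lambda r: (_chrom_sort_key(r.locus.chrom),
                                r.locus.start, r.locus.end))
    return results


# -- polymorphic rearranging regions ---------------------------------------

@dataclass
class PolymorphicRegion:
    region: Locus
    freq_total: float
    p_vs_controls: float
    n_mutually_exclusive_subjects: int
    is_polymorphic: bool


def find_polymorphic(pool_regions: Sequence[Locus], manifest: Manifest,
                     control_segments: Sequence[CnvSegment],
                     freq_threshold: float = 0.05,
                     min_subjects: int = 10,
                     common_alpha: float = 0.05,
                     overlap_threshold: float = 0.10) -> list[PolymorphicRegion]:
    """Flag polymorphic CNV regions that rearrange between pair members.

    ``pool_regions`` are loci merged from the pooled parental + iPSC segment
    set *before* inherited-CNV subtraction.  A region is polymorphic iff its
    frequency over all parental + iPSC samples exceeds ``freq_threshold``,
    a G-test against the control cohort gives p > ``common_alpha`` (the
    region is as common in the population), and the region is present in the
    parental sample XOR in at least one iPSC line of the donor for strictly
    more than ``min_subjects`` donors.
    """
    if not manifest.ipsc_by_donor:
        raise ValueError("manifest contains no parental/iPSC pairings")
    results = []
    for region in pool_regions:
        sex = _stratum_sex(region.stratum)
        study = [r for r in manifest.records
                 if r.role in (ROLE_PARENTAL, ROLE_IPSC)
                 and (sex is None or r.sex == sex)]
        n_study = len(study)
        n_ctrl = manifest.cohort_size(ROLE_CONTROL, sex)
        member_samples = {m.sample_id for m in region.members}
        carriers_study = _restrict(
            {s for s in member_samples
             if manifest.by_id[s].role in (ROLE_PARENTAL, ROLE_IPSC)},
            manifest, sex)
        freq_total = len(carriers_study) / n_study if n_study else 0.0
        ctrl = span_carriers(region, control_segments, overlap_threshold)
        carriers_ctrl = _restrict(
            {s for s in ctrl[GAIN] | ctrl[LOSS]
             if manifest.by_id[s].role == ROLE_CONTROL},
            manifest, sex)
        _, p = g_test([[len(carriers_study), n_study - len(carriers_study)],
                       [len(carriers_ctrl), n_ctrl - len(carriers_ctrl)]])
        n_xor = 0
        present = member_samples  # presence = contributed a member segment
        for donor, lines in manifest.ipsc_by_donor.items():
            in_parental = manifest.parental_by_donor[donor].sample_id in present
            in_ipsc = any(l.sample_id in present for l in lines)
            if in_parental != in_ipsc:
                n_xor += 1
        results.append(PolymorphicRegion(
            region=region,
            freq_total=freq_total,
            p_vs_controls=p,
            n_mutually_exclusive_subjects=n_xor,
            is_polymorphic=(freq_total > freq_threshold
                            and p > common_alpha
                            and n_xor > min_subjects)))
    results.sort(key=lambda r: (_chrom_sort_key(r.region.chrom),
                                r.region.start, r.region.end))
    return results


# -- CNV burden ------------------------------------------------------------

@dataclass
class BurdenResult:
    pairs: list[tuple[str, int, int]]  # (ipsc sample, ipsc count, parental count)
    t: float
    df: int
    p: float
    degenerate: bool = False


def burden_test(manifest: Manifest,
                segments_by_sample: Mapping[str, Sequence[CnvSegment]]) -> BurdenResult:
    """Paired t-test of total CNV count, iPSC line vs its parental cells.

    One pair per iPSC line (a donor's parental count is reused across its
    clones).  t = mean(d) / (sd(d)/sqrt(n)) with d = iPSC - parental count,
    two-sided p at df = n - 1.  Zero variance: (t=0, p=1) when the mean
    difference is also zero, else p = 0 with the degenerate flag set.
    """
    pairs = []
    for donor in manifest.donors():
        parental = manifest.parental_by_donor[donor]
        n_par = len(segments_by_sample.get(parental.sample_id, ()))
        for line in sorted(manifest.ipsc_by_donor[donor],
                           key=lambda r: r.sample_id):
            n_line = len(segments_by_sample.get(line.sample_id, ()))
            pairs.append((line.sample_id, n_line, n_par))
    if len(pairs) < 2:
        raise ValueError("burden test requires at least 2 pairs")
    d = np.array([a - b for _, a, b in pairs], dtype=float)
    n = len(d)
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return BurdenResult(pairs, 0.0, n - 1, 1.0)
        return BurdenResult(pairs, math.copysign(math.inf, mean), n - 1, 0.0,
                            degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return BurdenResult(pairs, float(t), n - 1, p)


# -- size distribution -----------------------------------------------------

#: Left edges of the reporting bins (lengths already exceed the 100 kb filter).
SIZE_BIN_EDGES = (500_000, 1_000_000, 5_000_000)
SIZE_BIN_LABELS = ("<500kb", "500kb-1Mb", "1Mb-5Mb", ">=5Mb")


@dataclass
class SizeDistribution:
    counts: tuple[int, int, int, int]
    fractions: tuple[float, float, float, float]
    empty: bool = False


def size_distribution(segments: Sequence[CnvSegment]) -> SizeDistribution:
    """Fractions of segments per length bin; bins left-closed at the edges."""
    lengths = [s.length for s in segments]
    if not lengths:
        return SizeDistribution((0, 0, 0, 0), (0.0, 0.0, 0.0, 0.0), empty=True)
    counts = [0, 0, 0, 0]
    for ln in lengths:
        counts[int(np.searchsorted(SIZE_BIN_EDGES, ln, side="right"))] += 1
    total = len(lengths)
    return SizeDistribution(tuple(counts),
                            tuple(c / total for c in counts))


# -- gene annotation -------------------------------------------------------

def annotate_genes(loci: Sequence[Locus],
                   genes: Sequence[tuple[str, int, int, str]]) -> list[list[str]]:
    """Gene symbols overlapping each locus by >= 1 bp, deduplicated, ordered
    by gene start."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, symbol in genes:
        by_chrom.setdefault(chrom, []).append((int(start), int(end), symbol))
    for v in by_chrom.values():
        v.sort()
    out = []
    for locus in loci:
        seen: set[str] = set()
        symbols: list[str] = []
        for start, end, symbol in by_chrom.get(locus.chrom, ()):
            if start <= locus.end and end >= locus.start and symbol not in seen:
                seen.add(symbol)
                symbols.append(symbol)
        out.append(symbols)
    return out
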
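"""End-to-end workflow: mask -> segment -> length-filter -> subtract
inherited -> merge loci -> control filter -> hotspot test, plus the
polymorphic-region scan, CNV burden and size-distribution summaries.

The pipeline is a pure function of (inputs, thresholds): identical inputs
give identical outputs, and every threshold used appears verbatim in the
run summary.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

from .probes import (CnvSegment, ExclusionRegions, ProbeCallTrack, ProbeMap,
                     filter_by_length, mask_probes_with_index, segment_track)
from .specificity import (Locus, Manifest, ROLE_CONTROL, ROLE_IPSC,
                          ROLE_PARENTAL, filter_vs_controls, merge_loci,
                          subtract_inherited)
from .stats import (BurdenResult, HotspotResult, PolymorphicRegion,
                    SizeDistribution, annotate_carriers, annotate_genes,
                    burden_test, call_hotspots, find_polymorphic,
                    size_distribution)


@dataclass(frozen=True)
class Thresholds:
    """All tunable cutoffs, defaulting to the study's values."""

    min_probes: int = 10            # probes per run
    min_length: int = 100_000       # bp, strict lower bound
    inherited_frac: float = 0.5     # overlap fraction vs any parental segment
    merge_reciprocal: float = 0.10  # reciprocal-overlap locus merge
    control_cov: float = 0.10       # max control coverage of a locus (strict)
    hotspot_freq: float = 0.05      # min iPSC carrier frequency (strict)
    control_freq: float = 0.002     # max control carrier frequency (strict)
    alpha: float = 0.05             # family-wise level before Bonferroni
    polymorphic_freq: float = 0.05  # min pooled study frequency (strict)
    polymorphic_min_subjects: int = 10  # XOR donors, strict lower bound
    common_alpha: float = 0.05      # "as common as controls" level

    def __post_init__(self) -> None:
        for name in ("inherited_frac", "merge_reciprocal", "control_cov",
                     "hotspot_freq", "control_freq", "alpha",
                     "polymorphic_freq", "common_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class CohortResult:
    thresholds: Thresholds
    probe_map: ProbeMap                       # post-masking
    segments_by_sample: dict[str, list[CnvSegment]]
    ipsc_specific: list[CnvSegment]
    loci_tested: list[Locus]
    hotspots: list[HotspotResult]
    polymorphic: list[PolymorphicRegion]
    burden: BurdenResult | None
    sizes: SizeDistribution
    genes_by_hotspot_locus: list[list[str]] | None = None

    @property
    def hotspot_calls(self) -> list[HotspotResult]:
        return [r for r in self.hotspots if r.is_hotspot]

    @property
    def polymorphic_calls(self) -> list[PolymorphicRegion]:
        return [r for r in self.polymorphic if r.is_polymorphic]

    def summary(self) -> dict:
        m = len(self.loci_tested)
        return {
            "thresholds": asdict(self.thresholds),
            "n_probes": self.probe_map.n_probes,
            "n_samples": len(self.segments_by_sample),
            "n_segments_total": sum(len(v) for v in
                                    self.segments_by_sample.values()),
            "n_ipsc_specific_segments": len(self.ipsc_specific),
            "n_loci_tested": m,
            "bonferroni_m": m,
            "alpha_adjusted": (self.thresholds.alpha / m) if m else None,
            "n_hotspots": len(self.hotspot_calls),
            "n_polymorphic": len(self.polymorphic_calls),
            "burden": None if self.burden is None else {
                "t": self.burden.t, "df": self.burden.df,
                "p": self.burden.p, "n_pairs": len(self.burden.pairs),
                "degenerate": self.burden.degenerate,
            },
            "size_distribution": {
                "fractions": list(self.sizes.fractions),
                "counts": list(self.sizes.counts),
                "empty": self.sizes.empty,
            },
        }


def segment_cohort(pmap: ProbeMap,
                   tracks: Mapping[str, ProbeCallTrack],
                   manifest: Manifest,
                   thresholds: Thresholds = Thresholds(),
                   exclusions: ExclusionRegions | None = None,
                   ) -> tuple[ProbeMap, dict[str, list[CnvSegment]]]:
    """Mask excluded probes, segment every track, apply the length filter."""
    if exclusions is not None:
        pmap, keep = mask_probes_with_index(pmap, exclusions)
    else:
        keep = None
    segments_by_sample: dict[str, list[CnvSegment]] = {}
    for sample_id, track in tracks.items():
        record = manifest.by_id[sample_id]
        states = track.states if keep is None else track.states[keep]
        segs = segment_track(ProbeCallTrack(sample_id, states), pmap,
                             record.sex, thresholds.min_probes)
        segments_by_sample[sample_id] = filter_by_length(
            segs, thresholds.min_length)
    return pmap, segments_by_sample


def analyze_segments(segments_by_sample: Mapping[str, Sequence[CnvSegment]],
                     manifest: Manifest,
                     thresholds: Thresholds = Thresholds(),
                     probe_map: ProbeMap | None = None,
                     genes: Sequence[tuple[str, int, int, str]] | None = None,
                     ) -> CohortResult:
    """Run the statistical pipeline on per-sample, length-filtered segments."""
    control_segments = [s for r in manifest.samples(ROLE_CONTROL)
                        for s in segments_by_sample.get(r.sample_id, ())]
    parental_segments = [s for r in manifest.samples(ROLE_PARENTAL)
                         for s in segments_by_sample.get(r.sample_id, ())]

    # paired subtraction of inherited CNVs, per donor
    ipsc_specific: list[CnvSegment] = []
    for donor in manifest.donors():
        par = segments_by_sample.get(
            manifest.parental_by_donor[donor].sample_id, [])
        for line in manifest.ipsc_by_donor[donor]:
            ipsc_specific.extend(subtract_inherited(
                segments_by_sample.get(line.sample_id, []), par,
                thresholds.inherited_frac))

    merged = merge_loci(ipsc_specific, thresholds.merge_reciprocal)
    annotate_carriers(merged, manifest, control_segments, parental_segments,
                      thresholds.merge_reciprocal)
    loci_tested = filter_vs_controls(merged, control_segments,
                                     thresholds.control_cov)
    hotspots = call_hotspots(loci_tested, manifest,
                             alpha=thresholds.alpha,
                             hotspot_freq=thresholds.hotspot_freq,
                             control_freq=thresholds.control_freq)

    # polymorphic scan on the pooled, pre-subtraction parental + iPSC set
    pooled = parental_segments + [
        s for r in manifest.samples(ROLE_IPSC)
        for s in segments_by_sample.get(r.sample_id, ())]
    pool_regions = merge_loci(pooled, thresholds.merge_reciprocal)
    annotate_carriers(pool_regions, manifest, control_segments, (),
                      thresholds.merge_reciprocal)
    polymorphic = find_polymorphic(
        pool_regions, manifest, control_segments,
        freq_threshold=thresholds.polymorphic_freq,
        min_subjects=thresholds.polymorphic_min_subjects,
        common_alpha=thresholds.common_alpha,
        overlap_threshold=thresholds.merge_reciprocal)

    burden = None
    if manifest.ipsc_by_donor and sum(
            len(v) for v in manifest.ipsc_by_donor.values()) >= 2:
        burden = burden_test(manifest, segments_by_sample)

    sizes = size_distribution(ipsc_specific)
    genes_by_locus = None
    if genes is not None:
        genes_by_locus = annotate_genes(
            [r.locus for r in hotspots], genes)
    return CohortResult(
        thresholds=thresholds,
        probe_map=probe_map if probe_map is not None else ProbeMap([], {}, {}),
        segments_by_sample={k: list(v) for k, v in segments_by_sample.items()},
        ipsc_specific=ipsc_specific,
        loci_tested=loci_tested,
        hotspots=hotspots,
        polymorphic=polymorphic,
        burden=burden,
        sizes=sizes,
        genes_by_hotspot_locus=genes_by_locus,
    )


def analyze_cohort(pmap: ProbeMap,
                   tracks: Mapping[str, ProbeCallTrack],
                   manifest: Manifest,
                   thresholds: Thresholds = Thresholds(),
                   exclusions: ExclusionRegions | None = None,
                   genes: Sequence[tuple[str, int, int, str]] | None = None,
                   ) -> CohortResult:
    """The full pipeline, from probe states to hotspot and polymorphic calls."""
    masked, segments_by_sample = segment_cohort(
        pmap, tracks, manifest, thresholds, exclusions)
    return analyze_segments(segments_by_sample, manifest, thresholds,
                            probe_map=masked, genes=genes)
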
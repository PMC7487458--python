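"""Scan a synthetic cohort for reprogramming-induced CNV hotspots.

Generates a small paired cohort (24 donors, 150 controls) with three
planted recurrent loci, runs the full pipeline and prints the tested loci
with carrier frequencies, G-test p-values and the Bonferroni threshold.
"""

from ipscnv import SimConfig, analyze_cohort, generate_cohort
from ipscnv.simulate import ControlLocusSpec, HotspotSpec, PolymorphicSpec

cfg = SimConfig(
    seed=12,
    genome=(("chr1", 20_000_000, 5000), ("chr2", 20_000_000, 5000),
            ("chrX", 10_000_000, 5000)),
    n_donors=24, female_donors=12, n_controls=150, female_controls=75,
    inherited_rate=1.0, de_novo_rate=1.0,
    hotspots=(
        HotspotSpec("chr1", 2_000_000, 2_200_000, 0.45),
        HotspotSpec("chr2", 5_000_000, 5_300_000, 0.40),
        HotspotSpec("chrX", 3_000_000, 3_200_000, 0.50, restrict_sex="female"),
    ),
    polymorphic=(PolymorphicSpec("chr1", 8_000_000, 8_250_000, 0.25, 0.25),),
    control_loci=(ControlLocusSpec("chr1", 15_000_000, 15_200_000, 0.05),),
)

cohort = generate_cohort(cfg)
result = analyze_cohort(cohort.probe_map, cohort.tracks(), cohort.manifest)

m = len(result.loci_tested)
print(f"{m} loci tested; Bonferroni-adjusted alpha = 0.05/{m} = {0.05 / m:.2e}")
print()
print("called hotspots (iPSC freq > 5%, control freq < 0.2%, p <= adjusted,")
print("no carrier among paired parental cells):")
for r in result.hotspot_calls:
    l = r.locus
    print(f"  {l.chrom}:{l.start}-{l.end} [{l.stratum}]  "
          f"iPSC {100 * r.freq_ipsc:.1f}%  control {100 * r.freq_control:.2f}%  "
          f"G={r.g:.1f}  p={r.p_display}  "
          f"({r.direction_summary[0]} gain / {r.direction_summary[1]} loss)")
print()
print("Every called locus matches a planted recurrent locus; the ~1 CNV/line")
print("random background stays below the 5% recurrence threshold, and the")
print("planted polymorphic/population loci are removed by the control filter.")
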
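"""G-test, carrier frequencies, hotspot and polymorphic classification,
burden and size summaries — checked against scipy oracles and at every
strict threshold boundary."""

import numpy as np
import pytest
from scipy import stats as sps

from ipscnv.probes import CnvSegment, GAIN, LOSS
from ipscnv.specificity import Locus, Manifest, SampleRecord, merge_loci
from ipscnv.stats import (annotate_carriers, annotate_genes, burden_test,
                          call_hotspots, carrier_frequency, find_polymorphic,
                          g_test, size_distribution)


def seg(sample, start, end, direction=GAIN, chrom="chr1"):
    return CnvSegment(sample, chrom, start, end, direction, 10)


def build_manifest(n_donors=100, n_controls=1000, female_donors=50,
                   female_controls=500, prefix=""):
    records = []
    for i in range(n_donors):
        donor = f"{prefix}D{i:03d}"
        sex = "female" if i < female_donors else "male"
        records.append(SampleRecord(f"{donor}_P", donor, "parental", sex))
        records.append(SampleRecord(f"{donor}_iPSC1", donor, "ipsc", sex))
    for i in range(n_controls):
        sex = "female" if i < female_controls else "male"
        records.append(SampleRecord(f"{prefix}C{i:04d}", f"{prefix}C{i:04d}",
                                    "control", sex))
    return Manifest(records)


# -- G-test ------------------------------------------------------------------

def test_g_test_zero_at_independence():
    g, p = g_test([[10, 90], [10, 90]])
    assert g == 0.0
    assert p == 1.0


def test_g_test_empty_margin_returns_uninformative():
    assert g_test([[0, 0], [5, 10]]) == (0.0, 1.0)
    assert g_test([[0, 5], [0, 10]]) == (0.0, 1.0)


def test_g_test_rejects_negative_counts():
    with pytest.raises(ValueError):
        g_test([[-1, 5], [2, 3]])


def test_g_test_table1_style_row_is_strongly_significant():
    # 5/82 iPSC carriers vs 1/1093 control carriers
    g, p = g_test([[5, 77], [1, 1092]])
    assert p < 1e-4
    assert g == pytest.approx(21.7, rel=0.02)
    assert p == pytest.approx(3e-6, rel=0.3)


def test_g_test_matches_scipy_log_likelihood_oracle():
    rng = np.random.default_rng(31)
    for _ in range(100):
        table = rng.integers(1, 500, size=(2, 2))
        g, p = g_test(table)
        g2, p2, _, _ = sps.chi2_contingency(
            table, correction=False, lambda_="log-likelihood")
        assert g == pytest.approx(g2, rel=1e-12)
        assert p == pytest.approx(p2, rel=1e-12)


def test_g_test_agrees_with_pearson_when_expectations_large():
    # asymptotic G ~ Pearson equivalence holds near independence; sample
    # both rows from a common carrier proportion to stay in that regime
    rng = np.random.default_rng(37)
    checked = 0
    while checked < 30:
        prop = rng.uniform(0.1, 0.9)
        n1, n2 = int(rng.integers(100, 500)), int(rng.integers(100, 500))
        a, c = rng.binomial(n1, prop), rng.binomial(n2, prop)
        table = np.array([[a, n1 - a], [c, n2 - c]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        if expected.min() < 5:
            continue
        g, _ = g_test(table)
        chi2 = ((table - expected) ** 2 / expected).sum()
        if chi2 > 0.5:
            assert g == pytest.approx(chi2, rel=0.15)
        checked += 1


def test_g_test_supports_two_by_three_direction_table():
    g, p = g_test([[10, 5, 85], [10, 5, 985]])
    g2, p2, _, _ = sps.chi2_contingency(
        [[10, 5, 85], [10, 5, 985]], correction=False,
        lambda_="log-likelihood")
    assert (g, p) == (pytest.approx(g2), pytest.approx(p2))


# -- carrier frequency -------------------------------------------------------

def annotated_locus(manifest, n_gain=0, n_loss=0, n_ctrl=0, chrom="chr1",
                    parental=()):
    ipsc_ids = [r.sample_id for r in manifest.samples("ipsc")]
    ctrl_ids = [r.sample_id for r in manifest.samples("control")]
    members = tuple(
        [seg(ipsc_ids[k], 1, 200_000, GAIN, chrom) for k in range(n_gain)]
        + [seg(ipsc_ids[n_gain + k], 1, 200_000, LOSS, chrom)
           for k in range(n_loss)])
    locus = Locus(chrom=chrom, start=1, end=200_000, members=members)
    locus.ipsc_carriers = {
        GAIN: {ipsc_ids[k] for k in range(n_gain)},
        LOSS: {ipsc_ids[n_gain + k] for k in range(n_loss)},
    }
    locus.control_carriers = {GAIN: set(ctrl_ids[:n_ctrl]), LOSS: set()}
    locus.parental_carriers = set(parental)
    locus.stratum = "all" if chrom not in ("chrX", "chrY") else "female_only"
    return locus


def test_carrier_frequency_counts_distinct_samples_any_direction():
    manifest = build_manifest(n_donors=82, n_controls=1093,
                              female_donors=42, female_controls=568)
    locus = annotated_locus(manifest, n_gain=38, n_loss=2, n_ctrl=0)
    fi, fc = carrier_frequency(locus, manifest)
    assert fi == pytest.approx(40 / 82)
    assert round(100 * fi, 1) == 48.8
    assert fc == 0.0


def test_zero_carriers_zero_frequency():
    manifest = build_manifest(10, 20, 5, 10)
    locus = annotated_locus(manifest)
    assert carrier_frequency(locus, manifest) == (0.0, 0.0)


def test_sex_stratified_denominators_on_x():
    manifest = build_manifest(n_donors=82, n_controls=1093,
                              female_donors=42, female_controls=568)
    locus = annotated_locus(manifest, n_gain=27, chrom="chrX")
    fi, fc = carrier_frequency(locus, manifest)
    assert fi == pytest.approx(27 / 42)


def test_empty_stratum_is_an_error():
    manifest = build_manifest(n_donors=4, n_controls=4, female_donors=4,
                              female_controls=4)  # no males anywhere
    locus = annotated_locus(manifest, n_gain=1, chrom="chrX")
    locus.stratum = "male_only"
    with pytest.raises(ValueError, match="stratum"):
        carrier_frequency(locus, manifest)


def test_frequencies_match_direct_recount():
    rng = np.random.default_rng(41)
    manifest = build_manifest(30, 200, 15, 100)
    ipsc_ids = [r.sample_id for r in manifest.samples("ipsc")]
    for _ in range(20):
        carriers = set(rng.choice(ipsc_ids, size=int(rng.integers(0, 20)),
                                  replace=False))
        locus = annotated_locus(manifest)
        locus.ipsc_carriers = {GAIN: carriers, LOSS: set()}
        fi, _ = carrier_frequency(locus, manifest)
        assert fi == len(carriers) / 30


# -- hotspot classification --------------------------------------------------

def test_hotspot_requires_frequency_above_five_percent():
    manifest = build_manifest(82, 1093, 42, 568)
    low = annotated_locus(manifest, n_gain=3)   # 3.7%: never a hotspot
    ok = annotated_locus(manifest, n_gain=6)    # 7.3%
    results = call_hotspots([low, ok], manifest)
    assert [r.is_hotspot for r in results] == [False, True]
    # boundary: 5% exactly is not strictly greater
    n100 = build_manifest(100, 1000, 50, 500)
    at = annotated_locus(n100, n_gain=5)        # 5.0%
    above = annotated_locus(n100, n_gain=6)
    assert [r.is_hotspot for r in call_hotspots([at, above], n100)] == \
        [False, True]


def test_hotspot_control_frequency_boundary_is_strict():
    manifest = build_manifest(100, 1000, 50, 500)
    at = annotated_locus(manifest, n_gain=30, n_ctrl=2)    # 0.2%: rejected
    below = annotated_locus(manifest, n_gain=30, n_ctrl=1)  # 0.1%: accepted
    results = call_hotspots([at, below], manifest)
    assert [r.is_hotspot for r in results] == [False, True]


def test_parental_carrier_revokes_hotspot():
    manifest = build_manifest(82, 1093, 42, 568)
    locus = annotated_locus(manifest, n_gain=10, parental=("D000_P",))
    assert call_hotspots([locus], manifest)[0].is_hotspot is False


def test_bonferroni_alpha_times_m_is_alpha():
    manifest = build_manifest(82, 1093, 42, 568)
    loci = [annotated_locus(manifest, n_gain=6) for _ in range(7)]
    results = call_hotspots(loci, manifest, alpha=0.05)
    for r in results:
        assert r.alpha_adjusted * len(loci) == 0.05


def test_adding_control_carriers_only_revokes_hotspot_status():
    manifest = build_manifest(82, 1093, 42, 568)
    was_hotspot = None
    for n_ctrl in range(0, 6):
        locus = annotated_locus(manifest, n_gain=10, n_ctrl=n_ctrl)
        now = call_hotspots([locus], manifest)[0].is_hotspot
        if was_hotspot is not None:
            assert not (now and not was_hotspot)
        was_hotspot = now


def test_x_locus_tested_in_female_stratum():
    manifest = build_manifest(82, 1093, 42, 568)
    locus = annotated_locus(manifest, n_gain=8, chrom="chrX")
    r = call_hotspots([locus], manifest)[0]
    assert r.freq_ipsc == pytest.approx(8 / 42)
    assert r.is_hotspot


# -- polymorphic regions -----------------------------------------------------

def polymorphic_setup(n_xor, n_both=18, n_donors=100, n_controls=500):
    """Construct a pooled-region scenario with a controlled XOR-subject count
    and a frequency-matched control cohort."""
    manifest = build_manifest(n_donors=n_donors, n_controls=n_controls,
                              female_donors=n_donors // 2,
                              female_controls=n_controls // 2)
    donors = manifest.donors()
    pool = []
    for d in donors[:n_xor]:  # iPSC only: mutually exclusive
        pool.append(seg(manifest.ipsc_by_donor[d][0].sample_id, 1, 200_000))
    for d in donors[n_xor:n_xor + n_both]:  # both members: concordant
        pool.append(seg(manifest.parental_by_donor[d].sample_id, 1, 200_000))
        pool.append(seg(manifest.ipsc_by_donor[d][0].sample_id, 1, 200_000))
    n_study_carriers = n_xor + 2 * n_both
    match_freq = n_study_carriers / (2 * n_donors)
    ctrl_ids = [r.sample_id for r in manifest.samples("control")]
    controls = [seg(c, 1, 200_000)
                for c in ctrl_ids[:round(match_freq * n_controls)]]
    regions = merge_loci(pool, threshold=0.10)
    annotate_carriers(regions, manifest, controls, ())
    return regions, manifest, controls


def test_eleven_xor_subjects_flag_polymorphic():
    regions, manifest, controls = polymorphic_setup(n_xor=11)
    results = find_polymorphic(regions, manifest, controls)
    assert len(results) == 1
    r = results[0]
    assert r.n_mutually_exclusive_subjects == 11
    assert r.freq_total > 0.05
    assert r.p_vs_controls > 0.05
    assert r.is_polymorphic


def test_ten_xor_subjects_is_not_enough():
    regions, manifest, controls = polymorphic_setup(n_xor=10)
    r = find_polymorphic(regions, manifest, controls)[0]
    assert r.n_mutually_exclusive_subjects == 10
    assert not r.is_polymorphic


def test_concordant_pairs_yield_zero_xor():
    regions, manifest, controls = polymorphic_setup(n_xor=0, n_both=30)
    r = find_polymorphic(regions, manifest, controls)[0]
    assert r.n_mutually_exclusive_subjects == 0
    assert not r.is_polymorphic


def test_region_rare_in_controls_is_not_polymorphic():
    regions, manifest, _ = polymorphic_setup(n_xor=15)
    r = find_polymorphic(regions, manifest, [])[0]  # absent from controls
    assert r.p_vs_controls < 0.05
    assert not r.is_polymorphic


def test_polymorphic_requires_pairings():
    manifest = Manifest([SampleRecord("C1", "C1", "control", "female")])
    with pytest.raises(ValueError, match="pairing"):
        find_polymorphic([], manifest, [])


# -- burden ------------------------------------------------------------------

def burden_manifest(n=4):
    return build_manifest(n_donors=n, n_controls=0, female_donors=n // 2,
                          female_controls=0)


def counts_to_segments(manifest, ipsc_counts, parental_counts):
    by_sample = {}
    for i, d in enumerate(manifest.donors()):
        line = manifest.ipsc_by_donor[d][0].sample_id
        par = manifest.parental_by_donor[d].sample_id
        by_sample[line] = [seg(line, 1 + 300_000 * k, 200_000 + 300_000 * k)
                           for k in range(ipsc_counts[i])]
        by_sample[par] = [seg(par, 1 + 300_000 * k, 200_000 + 300_000 * k)
                          for k in range(parental_counts[i])]
    return by_sample


def test_burden_symmetric_differences_give_t_zero():
    manifest = burden_manifest(4)
    by_sample = counts_to_segments(manifest, [3, 2, 1, 2], [2, 2, 2, 2])
    r = burden_test(manifest, by_sample)  # d = (1, 0, -1, 0)
    assert r.t == pytest.approx(0.0)
    assert r.p == pytest.approx(1.0)
    assert r.df == 3


def test_burden_constant_nonzero_difference_is_degenerate():
    manifest = burden_manifest(4)
    by_sample = counts_to_segments(manifest, [4, 4, 4, 4], [2, 2, 2, 2])
    r = burden_test(manifest, by_sample)
    assert r.degenerate
    assert r.p == 0.0


def test_burden_zero_difference_everywhere():
    manifest = burden_manifest(3)
    by_sample = counts_to_segments(manifest, [2, 2, 2], [2, 2, 2])
    r = burden_test(manifest, by_sample)
    assert (r.t, r.p) == (0.0, 1.0)
    assert not r.degenerate


def test_burden_requires_two_pairs():
    manifest = burden_manifest(1)
    with pytest.raises(ValueError):
        burden_test(manifest, {})


def test_burden_matches_scipy_paired_t():
    rng = np.random.default_rng(43)
    for _ in range(10):
        n = int(rng.integers(3, 12))
        manifest = burden_manifest(n)
        a = rng.integers(0, 8, size=n)
        b = rng.integers(0, 8, size=n)
        if (a - b).std(ddof=1) == 0:
            continue
        by_sample = counts_to_segments(manifest, list(a), list(b))
        r = burden_test(manifest, by_sample)
        t2, p2 = sps.ttest_rel(a, b)
        assert r.t == pytest.approx(t2)
        assert r.p == pytest.approx(p2)


# -- size distribution -------------------------------------------------------

def test_size_distribution_single_bin():
    segs = [seg("S", 1, 200_000) for _ in range(5)]
    assert size_distribution(segs).fractions == (1.0, 0.0, 0.0, 0.0)


def test_size_distribution_one_per_bin_left_closed_edges():
    segs = [seg("S", 1, 200_000),          # < 500 kb
            seg("S", 1, 500_000),          # exactly 500 kb: second bin
            seg("S", 1, 1_000_000),        # exactly 1 Mb: third bin
            seg("S", 1, 5_000_000)]        # exactly 5 Mb: last bin
    assert size_distribution(segs).fractions == (0.25, 0.25, 0.25, 0.25)


def test_size_distribution_empty_flagged():
    d = size_distribution([])
    assert d.empty
    assert d.fractions == (0.0, 0.0, 0.0, 0.0)


def test_size_distribution_matches_direct_binning():
    rng = np.random.default_rng(47)
    segs = [seg("S", 1, int(rng.integers(100_001, 8_000_000)))
            for _ in range(300)]
    d = size_distribution(segs)
    # direct recount with left-closed bins at 500kb/1Mb/5Mb
    expected = [
        sum(1 for s in segs if s.length < 500_000),
        sum(1 for s in segs if 500_000 <= s.length < 1_000_000),
        sum(1 for s in segs if 1_000_000 <= s.length < 5_000_000),
        sum(1 for s in segs if s.length >= 5_000_000),
    ]
    assert list(d.counts) == expected
    assert sum(d.fractions) == pytest.approx(1.0)


# -- gene annotation ---------------------------------------------------------

def test_gene_annotation_brute_force_join():
    rng = np.random.default_rng(53)
    loci = [Locus("chr1", s := int(rng.integers(1, 50_000)),
                  s + int(rng.integers(100, 10_000)), members=())
            for _ in range(15)]
    genes = []
    for k in range(60):
        s = int(rng.integers(1, 60_000))
        genes.append(("chr1" if k % 3 else "chr2", s,
                      s + int(rng.integers(10, 5_000)), f"G{k}"))
    got = annotate_genes(loci, genes)
    for locus, symbols in zip(loci, got):
        expected = sorted(
            [g for g in genes
             if g[0] == locus.chrom and g[1] <= locus.end and g[2] >= locus.start],
            key=lambda g: g[1])
        assert symbols == [g[3] for g in expected]


def test_gene_annotation_trivial_cases():
    locus = Locus("chr1", 100, 200, members=())
    assert annotate_genes([locus], []) == [[]]
    assert annotate_genes([locus], [("chr1", 100, 200, "EXACT")]) == [["EXACT"]]
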
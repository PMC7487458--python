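# Methods

## Problem and model

Reprogramming somatic cells to iPSCs can introduce copy-number variants, and
some genomic regions acquire them recurrently. Given per-probe integer
copy-number states for paired parental/iPSC samples and a population control
cohort, the package asks two questions about every genomic locus:

* **Hotspot:** do iPSC lines acquire CNVs here de novo (absent from their
  own parental cells), recurrently (>5% of lines), while the region is
  quiet in the general population (<0.2% of controls), with the
  case/control difference significant under a likelihood-ratio chi-square
  test after Bonferroni correction?
* **Polymorphic rearranging region:** is the region a common population
  polymorphism (study frequency >5%, not significantly different from
  controls, G-test p > 0.05) that nevertheless flips — appears or
  disappears — between the two members of a parental/iPSC pair in more than
  10 donors ("mutually exclusive" events)?

The unit of evidence is a **probe run**: at least 10 consecutive array
probes whose states lie strictly on the same side of the sex-appropriate
baseline (autosome 2; X female 2, male 1; Y male 1; female-Y probes are
dropped). Direction, not the exact state, defines run homogeneity — states
3 and 4 may share a gain run — and a single baseline or opposite-direction
probe terminates a run (the strictest deterministic reading; no gap
tolerance). Segment coordinates are the first/last probe positions, 1-based
inclusive, and a segment must exceed 100 kb (strict) to be analysed.

## Pipeline order and conventions

Masking of excluded regions (centromeres, Ig variable regions, TCR loci,
PAR, XTR) happens *before* segmentation, so an excluded region can neither
seed nor bridge a run. Inherited-CNV subtraction is one-way and
per-segment: an iPSC segment is inherited iff some single parental segment
of the same donor (any direction) covers more than 50% of the iPSC
segment's length; the union of parental segments is deliberately not used.
Locus merging is single linkage at reciprocal overlap ≥ 10% — clusters are
independent of input order — and a locus spans the envelope
(min start, max end) of its members. The control filter is positional and
frequency-agnostic: a locus is dropped when the union of control segments
covers ≥ 10% of its span; the separate <0.2% rule is a carrier-frequency
condition. Carriers are counted per sample (per iPSC line, not per donor).
Samples that are not locus members (controls; parental cells in the
germline check) count as carriers when one of their segments has reciprocal
overlap ≥ 10% with the locus span — the same criterion that merges members.

The G-test is computed in-package as `G = 2 Σ O ln(O/E)` with
margin-derived expectations, 0·ln 0 = 0 and no continuity correction;
p-values come from the chi-square survival function (scipy). The default
test pools gains and losses into one 2×2 carrier table (the published
per-locus tables report a single p per row); a per-direction 2×3 variant is
available (`call_hotspots(..., pooled=False)`). The Bonferroni denominator
is the number of loci actually tested in the run, recomputed each run and
reported in the summary rather than hard-coded. Sex-chromosome loci are
analysed within one sex stratum; the stratum is the sex contributing more
iPSC carriers (ties go to female). p-values are kept at full precision and
formatted as "< 0.0001" below that threshold only in reports.

Burden is a paired t-test on per-line total (post-length-filter) CNV
counts, the donor's parental count reused across clones; zero-variance
differences return t=0, p=1 when the mean difference is also zero and are
flagged degenerate (p=0) otherwise. Size fractions use left-closed bins at
500 kb, 1 Mb and 5 Mb.

All in-memory coordinates are 1-based inclusive; BED files are converted
exactly at the boundary. The pipeline is a pure function of (inputs,
thresholds): no hidden state, no wall-clock dependence, and every threshold
appears verbatim in the JSON run summary.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 82 donors
(42 female) each contributing one parental sample and one iPSC clone by
default, and 1093 controls (568 female). Planted structure, all snapped to
probe positions and mutually non-overlapping by rejection sampling so the
truth table is unambiguous:

* **Inherited CNVs** (~2 per donor, Poisson) written to both pair members —
  these must vanish in the subtraction step.
* **Background de novo CNVs** (~2.5 per line, Poisson) at random positions,
  log-uniform lengths 110 kb–1 Mb — individually real, collectively
  low-frequency.
* **Ten hotspot loci** planted only in iPSC tracks with per-line carrier
  probabilities 0.16–0.45 (two X loci restricted to female lines).
* **Seven polymorphic regions** whose presence is drawn independently per
  parental sample, per iPSC line and per control (presence 0.15 each).
* **Population control loci** (1–5% carrier frequency, controls only), and
  isolated single-probe noise (1e-4 per probe; configurable run length up
  to 9 to stress the 10-probe rule) that can never satisfy the run rule.

The default genome is four 180-Mb autosomes plus a 120-Mb X at 5-kb probe
spacing (168k probes) — array-like probe density at a desk scale that keeps
a full 1257-sample cohort under 2 s to generate and analyse.

Two defaults come from explicit design calculations rather than taste:

* **Carrier probabilities.** The strict >5% frequency threshold needs ≥5 of
  82 carrier lines (≥3 of 42 on female-stratified X). A locus planted at
  probability 0.06 would miss that bar in 45% of cohorts
  (P(Bin(82,0.06) ≥ 5) = 0.55) — an unusable positive control. The lowest
  default, 0.16, keeps the per-locus miss probability at 0.19%, so all ten
  planted loci are recoverable in ≈99.8% of cohorts.
* **Genome length and background lengths.** Random background segments can
  chain by single linkage into an accidental ≥5-carrier locus — a false
  "recurrent" CNV. At ~370 random events the chaining probability is
  governed by genome occupancy: on a 300-Mb toy genome with 110 kb–1.5 Mb
  lengths it is ≈0.67 per cohort; the 840-Mb default with 110 kb–1 Mb
  lengths brings it to ≈2%, so the background behaves as the low-frequency
  noise floor it represents. The tighter length ceiling also matches the
  observed size spectrum of reprogramming-induced CNVs (majority < 500 kb,
  almost none > 5 Mb).

What the generator does **not** emulate: raw hybridisation intensities and
their noise structure, B-allele frequencies, mosaicism, genotype-calling
artefacts, probe-density variation along the genome, linkage between CNVs,
or realistic population CNV architecture. Passing the planted-truth suites
therefore demonstrates that the pipeline's logic and statistics are correct
under the stated generative model, not that a particular array platform's
data would be called with the same sensitivity.

## Statistical behaviour worth knowing

* The polymorphic-region filter requires a per-region G-test p > 0.05
  against controls. For a region whose control frequency genuinely matches
  the study frequency this filter still fails with ≈5% (type-I)
  probability, so with seven true regions per cohort all seven are
  recovered in only ≈0.95⁷ ≈ 70% of cohorts — an intrinsic property of
  using an unadjusted significance filter as an inclusion criterion, not an
  implementation artefact. Joint recovery of many such regions cannot be
  made near-certain at any sample size.
* Single-linkage merging can chain neighbouring events into loci much wider
  than any member; carrier counts are per member sample, so the statistics
  are unaffected, but reported locus spans should be read as envelopes.
* With pooled 2×2 tables and zero control carriers, G-test p-values at ≥5
  of 82 carriers are far below typical Bonferroni thresholds (~1e-7), so
  the binding hotspot condition in practice is the 5% frequency rule.

## Limitations

* Upstream probe-state calling (and its quality control) is trusted as
  given; there is no re-calling, no mosaicism model and no intensity-level
  evidence.
* The >50% inherited-overlap rule is one-way against single parental
  segments; a de novo CNV nested inside a larger parental CNV is treated as
  inherited.
* Cytoband labels are echoed from input configuration when provided, not
  derived from an ideogram; gene annotation is a plain interval join.
* Sex-stratum choice at an X/Y locus follows the carriers observed in the
  cohort; loci carried equally by both sexes are assigned to the female
  stratum deterministically rather than tested twice.
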
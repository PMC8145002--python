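# Methods

This note documents the models and procedures implemented in `oncopanel`,
the defaults they ship with, and what the synthetic-data tests do and do
not demonstrate about behavior on real sequencing data.

## Copy-number calling

**Normalization.** Per-target mean depths are converted to fractional
coverage (depth divided by the sample's median target depth), and each
target's reference level is the median fractional coverage across a panel
of normals (at least 2 profiles; more is better). The log2 ratio is
`log2(sample fractional coverage / reference median)`. Median-of-ratios
was chosen over mean-based scaling for robustness to a minority of
misbehaving targets. Targets whose reference median fractional coverage is
zero cannot be normalized and are dropped with a warning; targets with
zero sample depth are dropped for the same reason (their log2 ratio is not
finite), which means a complete focal dropout surfaces as missing targets
rather than a called event — a known limitation, acceptable on a panel
whose targets are rarely at zero in practice. No GC or mappability
correction is applied; the assumption is that such biases are shared
between sample and normals and cancel in the ratio.

**Purity mixture model.** A specimen is modelled as tumor cells at
cellularity `c` carrying `CN` copies mixed with normal diploid cells at
`1 - c`:

    r(CN, c) = log2( (c·CN + (1 − c)·2) / 2 )

so `r(2, c) = 0` for every purity, and the inverse

    CN(r, c) = (2^(r+1) − 2(1 − c)) / c   (floored at 0)

gives the purity-corrected copy number of a called event. The pair is an
exact closed-form inverse (tested to 1e-9 over CN ∈ [0, 20], c ∈ (0, 1]).
The model assumes a single tumor clone and an otherwise diploid genome;
subclonal events yield fractional copy numbers, which are reported as-is.

**Event formation.** Maximal runs of adjacent same-chromosome targets
whose ratios strictly exceed the gain threshold (+0.3) or fall strictly
below the loss threshold (−0.4) become one event; a target at exactly a
threshold never calls. The event log2 is the median of member ratios
(robust to one noisy probe). The thresholds are applied per target for run
formation; the event median necessarily also respects them. Under these
thresholds the mixture model yields a detection floor of 3 copies for
gains and a ceiling of 1 copy for deletions at up to 50% non-tumor
infiltration (`lod_curve`), and deletions become undetectable when
infiltration exceeds roughly 75% (CN=0 at c=0.25 gives r = −0.415, barely
detectable; at c=0.2 it does not reach −0.4).

Because detection is a strict per-target threshold, an event whose true
ratio sits barely above the threshold (e.g. CN=3 at 50% purity, expected
r = 0.322) can fragment into adjacent calls when per-target noise dips a
member below 0.3. The copy-number estimate of the surviving calls remains
accurate (within ±0.3 of truth in the recovery tests); only the boundary
is fragmented. Segmentation methods that borrow strength across targets
(e.g. CBS) would avoid this and are intentionally out of scope.

**Credibility SCORE.** Each event gets a 0–10 score,
`10·(0.4·A + 0.3·B + 0.2·C + 0.1·D)`:

- `A` — ratio magnitude relative to twice its calling threshold, capped at 1;
- `B` — `log10(size/500 bp)/3` clipped to [0, 1]: 0 at ≤500 bp, saturating
  at 0.5 Mb;
- `C` — fraction of member targets individually beyond the threshold;
- `D` — 1 if no opposite-direction event lies within 1 Mb, else 0
  (opposing neighbors suggest normalization waves).

Classes: *high* strictly above 8, *medium* in (4, 8], *low* otherwise. The
component weights and the size saturation points are design choices made
so that sub-0.5 kb events (B = 0) can never reach the high class — the
same events the reproducibility analysis excludes. All constants are
module-level and overridable.

**Copy-neutral LOH.** Runs of ≥10 consecutive control-heterozygous SNPs
with |BAF − 0.5| > 0.15 whose overlapping coverage targets all stay within
|r| ≤ 0.1 are flagged as cnLOH with copy number 2. The run length, BAF
deviation and neutrality band are defaults chosen to require sustained
allelic imbalance over a megabase-scale region at typical SNP spacing
while rejecting imbalance explained by a concurrent gain or loss; all
three are parameters. The score reuses the event formula with `A` taken
from the mean BAF deviation scaled by its 0.5 maximum.

Sex chromosomes are called but flagged, so concordance analyses can
exclude them (X/Y imbalance is expected and not a reproducibility defect).

## Microsatellite instability

Each of the 110 panel markers is summarized as a repeat-length read
histogram. The baseline is built from ≥3 microsatellite-stable samples:
per marker, the mean of the normalized reference histograms, with an
instability threshold equal to the largest total-variation (TV) distance
any reference shows against that mean plus a 0.05 margin (capped at 1).
TV was chosen as the deviation statistic because it is bounded in [0, 1],
symmetric, distribution-free and insensitive to the repeat-length scale;
the margin guarantees every baseline sample self-classifies stable with
headroom. With only 3 reference samples the empirical max-deviation is a
noisy threshold estimate and a test sample's sampling noise can push a few
stable markers over it; at the band granularity below this inflates the
instability fraction by a few percent without affecting the class. More
reference samples tighten it.

A marker is *valid* at ≥30 supporting reads (parameter; the count below
which the normalized histogram is too noisy to compare), *unstable* when
valid and its TV statistic exceeds its threshold. The instability fraction
is unstable/valid markers, kept as an exact rational. Classification
requires ≥99 valid markers; below that the sample is a no-call. Bands are
half-open with inclusive lower bounds:

| fraction | class |
|---|---|
| [0, 0.18) | MSS |
| [0.18, 0.21) | inconclusive |
| [0.21, 0.31) | MSI-L |
| [0.31, 1] | MSI-H |

The two-decimal band edges leave the intervals (0.17, 0.18), (0.20, 0.21)
and (0.30, 0.31) formally unassigned; closing them as above keeps every
two-decimal edge in its stated class while classifying exact fractions
such as 31/99 deterministically.

## Variant prioritization and tiering

Deprioritization is a flag, never a deletion: downstream review sees every
record with the list of rules that fired. Rules (all boundaries
inclusive): depth ≤ 20, VAF ≤ 0.05, internal-database artifact or benign
status, population frequency ≥ 0.02, effect ∈ {exonic synonymous, intronic
non-splicing}. A missing population frequency never fires the population
rule — absence of evidence is not evidence of benignity. The rule set is
order-independent and monotone: tightening any threshold never promotes a
deprioritized record.

Only pathogenic/likely-pathogenic variants receive clinical tiers
(therapy / diagnosis / prognosis / resistance × level I guideline-backed /
level II literature-backed), by matching gene plus protein change (exact
or codon prefix, so `G12` covers `G12D`), exon region, gene-level
alteration, fusion name or MSI status against an editable TSV knowledge
table, restricted by tumor type (`any` matches all). Ties collapse to the
best level per category. The bundled table seeds the canonical solid-tumor
actionability assertions (BRAF V600E/K, KRAS G12, EGFR exon 19 del,
EML4-ALK, NCOA4-RET, BRCA2 biallelic loss, NRAS G13/Q61, KIT L576P,
PIK3CA hotspots) and is meant to be extended locally.

Pharmacogenetic genotypes for the 10-SNP table use VAF bands — alt/alt at
≥0.85, ref/alt in [0.15, 0.85), ref/ref below — which assume germline
input; positions absent from the variant table are ref/ref only when
covering depth evidence exists, otherwise no-call. The bundled SNP table
lists representative high-evidence oncology pharmacogenetic loci and is,
like the knowledge table, an editable default; the bundled microsatellite
marker definition file likewise carries synthetic placeholder coordinates
(only marker identities and counts enter any computation).

## Validation metrics

- **QC gates:** Q30 > 80%, cluster PF > 70%, DIN > 2 (all strict),
  reads ≥ 26 M.
- **Accuracy:** truth variants below the 5% VAF limit of detection are
  excluded from the sensitivity denominator; CNV matching requires same
  direction and reciprocal overlap ≥ 0.5; per-position specificity is
  computed only when the truth set defines an interrogated space, and is
  reported missing otherwise (never silently 0).
- **Replicate concordance:** each replicate's call set is filtered by
  per-analyte exclusion rules — SNVs: VAF > 5%, PASS, not within 5 bp of a
  same-base run of ≥5 (homopolymer slippage artifacts); CNVs: ≥0.5 kb,
  score strictly > 8, autosomes only; fusions: ≥10 supporting reads — and
  concordance is 100 × |in all| / |in any| over the filtered union, with
  every exclusion recorded. The homopolymer rule operationalizes
  "proximity to a homopolymer" as a concrete window/run-length pair; both
  are parameters.
- **VAF repeatability:** CV = 100 × sample sd (n−1) / mean, pass < 25%.
- **Saturation:** a sample plateaus at the smallest grid read count after
  which every successive increment gains < 0.5 percentage points of DP100
  per 2 M reads; the final grid point cannot certify a plateau (no
  increment follows it). The recommended run minimum is the largest
  plateau among plateauing samples.
- **Samples per run:** floor(kit cluster capacity / 13 M clusters per
  sample), with capacities 169 M (mid-output) and 416 M (high-output) as
  config constants.
- **Cohort frequencies:** per tumor type, the percentage of cases with ≥1
  qualifying finding per gene × alteration class (a case counts once
  however many findings it has), compared against a static reference
  table — never a live service.

## Synthetic data

Generators are pure functions of a seeded configuration (`SimConfig`):
identical seeds give identical bytes. Coverage uses log-normal
multiplicative noise (default sd 0.05 on the log2 scale, a typical
hybrid-capture panel's per-target dispersion after normalization) around
the mixture-model expectation; VAFs are binomial read draws at the
configured depth; marker histograms are multinomial draws from a 5-point
stutter shape, with unstable markers shifted by ≥2 repeat units (the
typical somatic MSI signal). Replicates derive per-replicate seeds from
the master seed.

What the generators do **not** emulate: GC/mappability waves, FFPE
deamination artifacts, strand bias, UMI-collapse errors, subclonal
heterogeneity, and real microsatellite stutter asymmetry. Passing recovery
tests therefore demonstrates the correctness of the calling logic under
its own noise model, not assay performance on tissue; the analytical
claims about real samples remain the province of wet-lab validation.

Default problem sizes used throughout the tests and the reproduction
script (200-target panels, 110 markers at 200 reads, cohorts of ~100
synthetic cases, 10–100 seeds per property) were chosen so the full suite
exercises every code path in well under a minute while keeping binomial /
multinomial sampling error far below the decision thresholds being tested.
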
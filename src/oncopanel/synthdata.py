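"""Seeded synthetic-data generators for every input the pipeline consumes.

Every generator is a pure function of a :class:`SimConfig`: the same seed
yields byte-identical outputs, and each generator returns the ground truth
alongside the data so downstream metrics can be checked exactly.

Noise models (the simplest models matching each data type's support):
log-normal multiplicative noise on per-target coverage, binomial read
sampling for variant allele fractions, multinomial read-length sampling
for microsatellite histograms.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field

from oncopanel.cnv_caller import CnvDirection, CnvEvent, expected_log2_ratio
from oncopanel.core_io import (
    CoverageProfile,
    Effect,
    FunctionalClass,
    RegionKind,
    TargetRegion,
    ValidationError,
    VariantRecord,
)
from oncopanel.msi_caller import (
    MIN_MARKER_COVERAGE,
    MarkerHistogram,
    MsiClass,
    classify_msi,
)

# Canonical stutter shape of a stable microsatellite: most reads at the
# modal repeat length with symmetric +/-1, +/-2 slippage tails.
STABLE_SHAPE_OFFSETS = (-2, -1, 0, 1, 2)
STABLE_SHAPE_PROBS = (0.05, 0.2, 0.5, 0.2, 0.05)


class CnvSpecItem(BaseModel):
    """One injected CNV: a run of targets set to an integer copy number."""

    first_target: int = Field(ge=0)
    n_targets: int = Field(ge=1)
    copy_number: float = Field(ge=0)


class VariantSpecItem(BaseModel):
    gene: str
    effect: Effect = Effect.missense
    vaf: float = Field(ge=0.0, le=1.0)
    depth: int = Field(gt=0)
    chrom: str = "chr1"
    pos: int = 0  # 0 = auto-place
    functional_class: FunctionalClass = FunctionalClass.unclassified
    protein_change: str = ""
    popmax_af: float | None = None


class MsiSpec(BaseModel):
    n_markers: int = 110
    fraction_unstable: float = Field(0.0, ge=0.0, le=1.0)
    length_shift: int = Field(2, ge=1)
    reads_per_marker: int = Field(200, ge=0)


class SimConfig(BaseModel):
    """Study conditions for the synthetic generators."""

    seed: int = 0
    n_targets: int = 200
    targets_per_chrom: int = 50
    target_size: int = 120
    target_spacing: int = 5_000
    coverage_mean: float = 500.0
    log2_noise_sd: float = 0.05
    purity: float = Field(1.0, gt=0.0, le=1.0)
    n_references: int = Field(4, ge=2)
    cnv_spec: list[CnvSpecItem] = Field(default_factory=list)
    msi_spec: MsiSpec = Field(default_factory=MsiSpec)
    variant_spec: list[VariantSpecItem] = Field(default_factory=list)
    replicate_noise_sd: float = 0.05


def make_panel(cfg: SimConfig) -> tuple[TargetRegion, ...]:
    """Deterministic target layout: ``targets_per_chrom`` evenly spaced
    targets per autosome, in genomic order."""
    targets = []
    for i in range(cfg.n_targets):
        chrom_idx = i // cfg.targets_per_chrom + 1
        within = i % cfg.targets_per_chrom
        start = 1_000_000 + within * (cfg.target_size + cfg.target_spacing)
        targets.append(
            TargetRegion(
                chrom=f"chr{chrom_idx}",
                start=start,
                end=start + cfg.target_size,
                name=f"t{i:04d}",
                gene=f"GENE{chrom_idx}",
                kind=RegionKind.on_target,
            )
        )
    return tuple(targets)


# ---------------------------------------------------------------------------
# Coverage with injected CNVs
# ---------------------------------------------------------------------------


def gen_coverage(
    cfg: SimConfig,
) -> tuple[CoverageProfile, list[CoverageProfile], list[CnvEvent]]:
    """Tumor coverage with injected CNVs at the configured purity, a panel
    of diploid reference profiles, and the exact truth events.

    Per-target tumor depth = mean * 2^(expected log2 ratio + N(0, sd));
    references are generated at CN=2 with the same noise model.
    """
    rng = np.random.default_rng(cfg.seed)
    targets = make_panel(cfg)

    covered = np.zeros(cfg.n_targets, dtype=bool)
    cn_by_target = np.full(cfg.n_targets, 2.0)
    truth: list[CnvEvent] = []
    for item in cfg.cnv_spec:
        lo, hi = item.first_target, item.first_target + item.n_targets
        if hi > cfg.n_targets:
            raise ValidationError(f"cnv_spec run {lo}:{hi} beyond target layout")
        if covered[lo:hi].any():
            raise ValidationError(f"cnv_spec runs overlap at targets {lo}:{hi}")
        if len({targets[i].chrom for i in range(lo, hi)}) != 1:
            raise ValidationError(f"cnv_spec run {lo}:{hi} crosses a chromosome")
        covered[lo:hi] = True
        cn_by_target[lo:hi] = item.copy_number
        direction = (
            CnvDirection.gain if item.copy_number > 2 else CnvDirection.loss
        )
        truth.append(
            CnvEvent(
                chrom=targets[lo].chrom,
                start=targets[lo].start,
                end=targets[hi - 1].end,
                direction=direction,
                n_targets=item.n_targets,
                event_log2=expected_log2_ratio(item.copy_number, cfg.purity),
                copy_number=item.copy_number,
            )
        )

    expected = np.array(
        [expected_log2_ratio(cn, cfg.purity) for cn in cn_by_target]
    )
    tumor_depths = cfg.coverage_mean * 2.0 ** (
        expected + rng.normal(0.0, cfg.log2_noise_sd, cfg.n_targets)
    )
    tumor = CoverageProfile("tumor", targets, tumor_depths)

    references = []
    for r in range(cfg.n_references):
        depths = cfg.coverage_mean * 2.0 ** rng.normal(
            0.0, cfg.log2_noise_sd, cfg.n_targets
        )
        references.append(CoverageProfile(f"ref{r}", targets, depths))
    return tumor, references, truth


# ---------------------------------------------------------------------------
# MSI histograms
# ---------------------------------------------------------------------------


def _marker_shape(reference_length: int, shift: int = 0) -> tuple[list[int], list[float]]:
    lengths = [max(reference_length + shift + o, 0) for o in STABLE_SHAPE_OFFSETS]
    return lengths, list(STABLE_SHAPE_PROBS)


def gen_msi(
    cfg: SimConfig,
) -> tuple[dict[str, MarkerHistogram], list[dict[str, MarkerHistogram]], MsiClass]:
    """A test sample's marker histograms, three MSS reference samples, and
    the truth MSI class.

    The first ``round(fraction_unstable * n_markers)`` markers draw read
    lengths from the stable shape shifted by ``length_shift`` repeat
    units; the rest (and all reference samples) draw from the unshifted
    shape.  The truth class applies the classifier's bands to the
    configured unstable fraction over markers with valid coverage.
    """
    import warnings

    spec = cfg.msi_spec
    rng = np.random.default_rng(cfg.seed + 1)
    if 0 < spec.reads_per_marker < MIN_MARKER_COVERAGE:
        warnings.warn(
            f"reads_per_marker {spec.reads_per_marker} is below the default "
            f"marker validity threshold {MIN_MARKER_COVERAGE}; markers will be invalid",
            stacklevel=2,
        )
    reference_lengths = {
        f"m{i:03d}": 10 + (i % 15) for i in range(spec.n_markers)
    }
    n_unstable = round(spec.fraction_unstable * spec.n_markers)

    def draw(marker_id: str, ref_len: int, shift: int) -> MarkerHistogram:
        lengths, probs = _marker_shape(ref_len, shift)
        counts_vec = rng.multinomial(spec.reads_per_marker, probs)
        counts: dict[int, int] = {}
        for length, n in zip(lengths, counts_vec):
            if n:
                counts[length] = counts.get(length, 0) + int(n)
        return MarkerHistogram(marker_id, counts)

    references = [
        {
            mid: draw(mid, ref_len, 0)
            for mid, ref_len in reference_lengths.items()
        }
        for _ in range(3)
    ]
    sample = {}
    for i, (mid, ref_len) in enumerate(reference_lengths.items()):
        shift = spec.length_shift if i < n_unstable else 0
        sample[mid] = draw(mid, ref_len, shift)

    n_valid = sum(
        1 for h in sample.values() if h.coverage >= MIN_MARKER_COVERAGE
    )
    if n_valid == 0:
        truth = MsiClass.no_call
    else:
        truth = classify_msi(n_unstable / spec.n_markers, n_valid)
    return sample, references, truth


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=A,Type=String,Description="Protein effect class">
##INFO=<ID=POPMAX_AF,Number=A,Type=Float,Description="Max population allele frequency">
##INFO=<ID=FUNC_CLASS,Number=A,Type=String,Description="Functional classification">
##INFO=<ID=PCHANGE,Number=A,Type=String,Description="Protein change">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
"""


def gen_variants(
    cfg: SimConfig,
    out_vcf: str | Path | None = None,
    dilution: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord], str]:
    """Observed variant records with binomially sampled VAFs, the truth
    records carrying the pre-noise VAFs, and the VCF text.

    ``dilution`` scales every true VAF before read sampling (a 1:1 mix
    with a negative control is ``dilution=0.5``).  When ``out_vcf`` is
    given the VCF text is also written there.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    observed: list[VariantRecord] = []
    truth: list[VariantRecord] = []
    body_lines = []
    contigs = sorted(
        {v.chrom for v in cfg.variant_spec}, key=lambda c: c.lstrip("chr")
    )
    header = _VCF_HEADER + "".join(f"##contig=<ID={c}>\n" for c in contigs)
    header += "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n"

    auto_pos = 10_000
    entries = []
    for item in cfg.variant_spec:
        pos = item.pos or auto_pos
        auto_pos += 1_000
        entries.append((item, pos))
    entries.sort(key=lambda e: (e[0].chrom, e[1]))

    for item, pos in entries:
        true_vaf = item.vaf * dilution
        alt_reads = int(rng.binomial(item.depth, true_vaf))
        obs_vaf = alt_reads / item.depth
        common = dict(
            chrom=item.chrom,
            pos=pos,
            ref="A",
            alt="G",
            gene=item.gene,
            effect=item.effect,
            depth=item.depth,
            popmax_af=item.popmax_af,
            functional_class=item.functional_class,
            protein_change=item.protein_change,
        )
        truth.append(VariantRecord(vaf=true_vaf, **common))
        if alt_reads > 0:
            observed.append(VariantRecord(vaf=obs_vaf, **common))
            info = (
                f"GENE={item.gene};EFFECT={item.effect.value}"
                + (f";POPMAX_AF={item.popmax_af}" if item.popmax_af is not None else "")
                + (
                    f";FUNC_CLASS={item.functional_class.value}"
                    if item.functional_class != FunctionalClass.unclassified
                    else ""
                )
                + (f";PCHANGE={item.protein_change}" if item.protein_change else "")
            )
            body_lines.append(
                f"{item.chrom}\t{pos}\t.\tA\tG\t.\tPASS\t{info}\tAF:DP:AD\t"
                f"{obs_vaf:.6f}:{item.depth}:{item.depth - alt_reads},{alt_reads}"
            )
    vcf_text = header + "\n".join(body_lines) + ("\n" if body_lines else "")
    if out_vcf is not None:
        Path(out_vcf).write_text(vcf_text)
    return observed, truth, vcf_text


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------


def replicate_seed(master_seed: int, index: int) -> int:
    """Per-replicate seed derived from the master seed, kept below 2^31."""
    return (master_seed * 1_000 + index + 1) % (2**31)


def gen_variant_replicates(
    cfg: SimConfig, n: int, dilution: float = 1.0
) -> tuple[list[list[VariantRecord]], list[VariantRecord]]:
    """``n`` independently read-sampled variant call sets sharing one truth."""
    if n < 2:
        raise ValidationError(f"need n >= 2 replicates, got {n}")
    replicates = []
    truth: list[VariantRecord] = []
    for i in range(n):
        rng = np.random.default_rng(replicate_seed(cfg.seed, i))
        observed, truth, _ = gen_variants(cfg, dilution=dilution, rng=rng)
        replicates.append(observed)
    return replicates, truth


def gen_coverage_replicates(
    cfg: SimConfig, n: int
) -> tuple[list[tuple[CoverageProfile, list[CoverageProfile]]], list[CnvEvent]]:
    """``n`` coverage datasets (tumor + references) with shared truth."""
    if n < 2:
        raise ValidationError(f"need n >= 2 replicates, got {n}")
    out = []
    truth: list[CnvEvent] = []
    for i in range(n):
        rep_cfg = cfg.model_copy(
            update={
                "seed": replicate_seed(cfg.seed, i),
                "log2_noise_sd": cfg.replicate_noise_sd,
            }
        )
        tumor, refs, truth = gen_coverage(rep_cfg)
        out.append((tumor, refs))
    return out, truth
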
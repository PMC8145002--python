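"""Analytical-validation computations for the panel pipeline.

Covers the quality gates applied to runs and samples, accuracy of call
sets against truth materials, intra-/inter-run replicate concordance with
the assay's exclusion rules, VAF repeatability (coefficient of variation),
read-saturation analysis with the samples-per-run arithmetic, and cohort
alteration-frequency tables against a static reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from oncopanel.core_io import (
    RunMetrics,
    SampleMeta,
    ValidationError,
    VariantRecord,
)
from oncopanel.variant_prioritizer import CaseSummary

# ---------------------------------------------------------------------------
# QC gates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QcGates:
    """Run/sample acceptance thresholds.

    Q30 and cluster-PF gates are strict (measures must exceed 80% and 70%);
    the DIN gate is strict above 2; read count must reach the 26M floor at
    which coverage saturates.
    """

    min_q30_pct: float = 80.0
    min_pf_pct: float = 70.0
    min_din: float = 2.0
    min_reads: float = 26e6
    dp100_target_pct: float = 96.2


@dataclass
class QcReport:
    gates: dict[str, bool]
    overall_pass: bool
    failures: list[str]


def run_qc(metrics: RunMetrics, meta: SampleMeta, gates: QcGates = QcGates()) -> QcReport:
    """Evaluate every quality gate; overall pass requires all gates."""
    results = {
        "q30": metrics.q30_pct > gates.min_q30_pct,
        "clusters_pf": metrics.clusters_pf_pct > gates.min_pf_pct,
        "din": meta.din > gates.min_din,
        "reads": metrics.n_reads >= gates.min_reads,
    }
    failures = [name for name, ok in results.items() if not ok]
    return QcReport(results, not failures, failures)


# ---------------------------------------------------------------------------
# Accuracy against truth
# ---------------------------------------------------------------------------


class Analyte(str, Enum):
    snv = "snv"
    cnv = "cnv"
    msi = "msi"
    fusion = "fusion"
    pgx = "pgx"


@dataclass
class TruthSet:
    """Expected findings plus the interrogated space for specificity.

    ``variants`` use (chrom, pos, ref, alt) identity; ``cnv_events`` match
    calls by direction and reciprocal overlap; ``n_interrogated_positions``
    (when known) defines the negative space for per-position specificity.
    """

    variants: list[VariantRecord] = field(default_factory=list)
    cnv_events: list = field(default_factory=list)
    msi_class: str | None = None
    fusions: list[str] = field(default_factory=list)
    pgx_genotypes: dict[str, str] = field(default_factory=dict)
    n_interrogated_positions: int | None = None
    lod_vaf: float = 0.05


@dataclass
class ClassMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return None if denom == 0 else self.tp / denom

    @property
    def specificity(self) -> float | None:
        if self.tn is None:
            return None
        denom = self.tn + self.fp
        return None if denom == 0 else self.tn / denom


@dataclass
class AccuracyReport:
    per_class: dict[str, ClassMetrics]
    excluded_truth: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class MatchingConfig:
    cnv_reciprocal_overlap: float = 0.5


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def accuracy(
    called_variants: Sequence[VariantRecord] = (),
    called_cnvs: Sequence = (),
    called_msi_class: str | None = None,
    called_pgx: Mapping[str, str] | None = None,
    truth: TruthSet = None,
    matching: MatchingConfig = MatchingConfig(),
) -> AccuracyReport:
    """Confusion metrics per analyte class for one sample vs its truth.

    Truth variants below the assay's VAF limit of detection are excluded
    from the sensitivity denominator — the assay is only claimed to detect
    above the LOD.  Per-position specificity is reported only when the
    truth set defines an interrogated space.
    """
    if truth is None:
        raise ValidationError("truth set required")
    per_class: dict[str, ClassMetrics] = {}
    excluded: list[str] = []

    # --- small variants -----------------------------------------------------
    eligible = []
    for t in truth.variants:
        if t.vaf < truth.lod_vaf:
            excluded.append(f"variant {t.key()} below LOD (VAF {t.vaf})")
        else:
            eligible.append(t)
    truth_keys = {t.key() for t in eligible}
    call_keys = {v.key() for v in called_variants}
    m = ClassMetrics(
        tp=len(truth_keys & call_keys),
        fp=len(call_keys - truth_keys),
        fn=len(truth_keys - call_keys),
    )
    if truth.n_interrogated_positions is not None:
        m.tn = truth.n_interrogated_positions - len(truth_keys) - m.fp
    if truth.variants or called_variants:
        per_class[Analyte.snv.value] = m

    # --- CNVs ---------------------------------------------------------------
    if truth.cnv_events or called_cnvs:
        tp = fn = 0
        matched_calls: set[int] = set()
        for t in truth.cnv_events:
            hit = False
            for i, c in enumerate(called_cnvs):
                if (
                    c.direction == t.direction
                    and c.chrom == t.chrom
                    and _reciprocal_overlap(c.start, c.end, t.start, t.end)
                    >= matching.cnv_reciprocal_overlap
                ):
                    hit = True
                    matched_calls.add(i)
            tp += hit
            fn += not hit
        fp = len(called_cnvs) - len(matched_calls)
        per_class[Analyte.cnv.value] = ClassMetrics(tp=tp, fp=fp, fn=fn)

    # --- MSI ----------------------------------------------------------------
    if truth.msi_class is not None and called_msi_class is not None:
        concordant = called_msi_class == truth.msi_class
        per_class[Analyte.msi.value] = ClassMetrics(
            tp=int(concordant), fp=int(not concordant), fn=int(not concordant)
        )

    # --- PGx ----------------------------------------------------------------
    if truth.pgx_genotypes and called_pgx is not None:
        tp = sum(
            1
            for rsid, gt in truth.pgx_genotypes.items()
            if called_pgx.get(rsid) == gt
        )
        miss = len(truth.pgx_genotypes) - tp
        per_class[Analyte.pgx.value] = ClassMetrics(tp=tp, fp=miss, fn=miss)

    return AccuracyReport(per_class, excluded)


# ---------------------------------------------------------------------------
# Replicate concordance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionRules:
    """Pre-concordance exclusion rules per analyte.

    SNVs must exceed the VAF limit of detection, be quality-PASS and not
    lie near a homopolymer (likely slippage artifacts).  CNVs must be at
    least 0.5 kb, score strictly above the high-confidence bound and lie
    on autosomes (sex chromosomes may be legitimately imbalanced).
    Fusion evidence needs >= 10 supporting reads.
    """

    snv_min_vaf: float = 0.05
    snv_require_pass: bool = True
    snv_homopolymer_min_run: int = 5
    snv_homopolymer_window: int = 5
    cnv_min_size_bp: int = 500
    cnv_min_score: float = 8.0
    cnv_autosomes_only: bool = True
    fusion_min_coverage: int = 10


def near_homopolymer(
    context: str, variant_offset: int, min_run: int = 5, window: int = 5
) -> bool:
    """True when a same-base run of >= ``min_run`` lies within ``window``
    bases of the variant position in the provided reference context."""
    if not context:
        return False
    runs = []
    start = 0
    for i in range(1, len(context) + 1):
        if i == len(context) or context[i] != context[start]:
            if i - start >= min_run:
                runs.append((start, i))
            start = i
    return any(
        r_start - window <= variant_offset < r_end + window for r_start, r_end in runs
    )


@dataclass
class ConcordanceReport:
    analyte: str
    n_union: int
    n_in_all: int
    concordance_pct: float
    excluded: list[tuple[str, str]]  # (item description, rule)


def _snv_excluded(v: VariantRecord, rules: ExclusionRules, context: str = "") -> str | None:
    if v.vaf <= rules.snv_min_vaf:
        return "vaf_at_or_below_lod"
    if rules.snv_require_pass and not v.quality_pass:
        return "not_pass"
    if context and near_homopolymer(
        context, len(context) // 2, rules.snv_homopolymer_min_run,
        rules.snv_homopolymer_window,
    ):
        return "homopolymer_proximity"
    return None


def _cnv_excluded(ev, rules: ExclusionRules) -> str | None:
    if ev.size_bp < rules.cnv_min_size_bp:
        return "size_below_0.5kb"
    if ev.score <= rules.cnv_min_score:
        return "score_at_or_below_8"
    if rules.cnv_autosomes_only and ev.sex_chromosome:
        return "sex_chromosome"
    return None


def replicate_concordance(
    replicates: Sequence[Sequence],
    analyte: Analyte | str,
    rules: ExclusionRules = ExclusionRules(),
    contexts: Mapping[tuple, str] | None = None,
) -> ConcordanceReport:
    """Concordance of >= 2 replicate call sets from the same material.

    Each replicate is filtered by the analyte's exclusion rules; the
    concordance is 100 x |items in all replicates| / |items in any|.
    Every excluded occurrence is recorded with the rule that removed it.
    """
    if len(replicates) < 2:
        raise ValidationError(f"need >= 2 replicates, got {len(replicates)}")
    analyte = Analyte(analyte)
    excluded: list[tuple[str, str]] = []
    filtered_keys: list[set] = []
    for rep in replicates:
        keys = set()
        for item in rep:
            if analyte == Analyte.snv:
                ctx = (contexts or {}).get(item.key(), "")
                rule = _snv_excluded(item, rules, ctx)
                key = item.key()
            elif analyte == Analyte.cnv:
                rule = _cnv_excluded(item, rules)
                key = item.key()
            elif analyte == Analyte.fusion:
                coverage = item[1] if isinstance(item, tuple) else item.coverage
                name = item[0] if isinstance(item, tuple) else item.name
                rule = (
                    "coverage_below_10" if coverage < rules.fusion_min_coverage else None
                )
                key = name
            else:  # msi / pgx call sets: items are hashable labels
                rule, key = None, item
            if rule is not None:
                excluded.append((str(key), rule))
            else:
                keys.add(key)
        filtered_keys.append(keys)

    union = set().union(*filtered_keys)
    in_all = set.intersection(*filtered_keys) if filtered_keys else set()
    pct = 100.0 if not union else 100.0 * len(in_all) / len(union)
    return ConcordanceReport(analyte.value, len(union), len(in_all), pct, excluded)


# ---------------------------------------------------------------------------
# VAF repeatability
# ---------------------------------------------------------------------------

VAF_CV_PASS_PCT = 25.0


def vaf_cv(vafs: Sequence[float], pass_below_pct: float = VAF_CV_PASS_PCT):
    """Coefficient of variation (%) of replicate VAF measurements of one
    variant: 100 * sample sd (n-1 denominator) / mean; passes below 25%."""
    values = np.asarray(vafs, dtype=float)
    if len(values) < 2 or not np.all(np.isfinite(values)):
        raise ValidationError("need >= 2 finite VAFs")
    mean = values.mean()
    if mean == 0:
        raise ValidationError("mean VAF is 0: CV undefined")
    cv = 100.0 * values.std(ddof=1) / mean
    return cv, bool(cv < pass_below_pct)


# ---------------------------------------------------------------------------
# Saturation and samples per run
# ---------------------------------------------------------------------------

PLATEAU_DELTA_PP = 0.5
PLATEAU_DELTA_READS = 2e6
PER_SAMPLE_CLUSTERS = 13_000_000
KIT_CLUSTER_CAPACITY = {"mid_output": 169_000_000, "high_output": 416_000_000}


@dataclass
class SaturationReport:
    plateau_reads: dict[str, float | None]  # sample -> plateau read count
    non_plateauing: list[str]
    recommended_min_reads: float | None


def saturation_analysis(
    observations: Mapping[str, Sequence[tuple[float, float]]],
    plateau_delta: float = PLATEAU_DELTA_PP,
    delta_reads: float = PLATEAU_DELTA_READS,
) -> SaturationReport:
    """Find, per sample, the read count beyond which DP100 stops improving.

    ``observations`` maps sample id -> increasing grid of
    (n_reads, dp100_pct).  The plateau is the smallest grid read count
    after which every successive increment gains less than
    ``plateau_delta`` percentage points per ``delta_reads`` reads.  The
    recommended run minimum is the largest plateau among samples that
    reach one; samples that never plateau are flagged.
    """
    plateau: dict[str, float | None] = {}
    non_plateauing: list[str] = []
    for sample, grid in observations.items():
        if len(grid) < 3:
            raise ValidationError(f"{sample}: need >= 3 grid points")
        reads = [g[0] for g in grid]
        if any(b <= a for a, b in zip(reads, reads[1:])):
            raise ValidationError(f"{sample}: grid must be strictly increasing in reads")
        found = None
        # the last grid point cannot certify a plateau: no increment follows it
        for i in range(len(grid) - 1):
            ok = True
            for j in range(i, len(grid) - 1):
                dn = grid[j + 1][0] - grid[j][0]
                gain = grid[j + 1][1] - grid[j][1]
                if gain >= plateau_delta * (dn / delta_reads):
                    ok = False
                    break
            if ok:
                found = grid[i][0]
                break
        plateau[sample] = found
        if found is None:
            non_plateauing.append(sample)
    reached = [p for p in plateau.values() if p is not None]
    return SaturationReport(
        plateau, non_plateauing, max(reached) if reached else None
    )


def samples_per_run(
    kit_cluster_capacity: float, per_sample_clusters: float = PER_SAMPLE_CLUSTERS
) -> int:
    """How many samples fit in a run while guaranteeing each its minimum
    cluster count: floor(capacity / per-sample clusters)."""
    if kit_cluster_capacity <= 0 or per_sample_clusters <= 0:
        raise ValidationError("capacity and per-sample clusters must be positive")
    n = math.floor(kit_cluster_capacity / per_sample_clusters)
    if n == 0:
        import logging

        logging.getLogger(__name__).warning(
            "kit capacity %.0f below the per-sample minimum %.0f: 0 samples fit",
            kit_cluster_capacity,
            per_sample_clusters,
        )
    return n


# ---------------------------------------------------------------------------
# Cohort frequencies
# ---------------------------------------------------------------------------


def cohort_frequencies(
    summaries: Sequence[CaseSummary],
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Percentage of cases per tumor type affected by each gene x
    alteration class, with optional deltas against a static reference
    frequency table (columns tumor_type, gene, alteration_class, pct).

    A case counts once per gene x class regardless of how many qualifying
    findings it carries.  Percentages are rounded to 2 decimals.
    """
    if not summaries:
        raise ValidationError("empty cohort")
    cohort_sizes: dict[str, int] = {}
    counts: dict[tuple[str, str, str], int] = {}
    for s in summaries:
        cohort_sizes[s.tumor_type] = cohort_sizes.get(s.tumor_type, 0) + 1
        for alteration_class, genes in s.genes_by_class.items():
            for gene in genes:
                key = (s.tumor_type, gene, alteration_class)
                counts[key] = counts.get(key, 0) + 1
    rows = []
    for (tumor_type, gene, alteration_class), n in sorted(counts.items()):
        size = cohort_sizes[tumor_type]
        rows.append(
            {
                "tumor_type": tumor_type,
                "gene": gene,
                "alteration_class": alteration_class,
                "n_affected": n,
                "cohort_size": size,
                "pct": round(100.0 * n / size, 2),
            }
        )
    table = pd.DataFrame(rows)
    if reference is not None:
        ref = reference.rename(columns={"pct": "reference_pct"})
        table = table.merge(
            ref, on=["tumor_type", "gene", "alteration_class"], how="left"
        )
        table["delta_pct"] = (table["pct"] - table["reference_pct"]).round(2)
    return table
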
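"""Four-phase whole-genome prioritisation funnel with a per-phase audit
trail.

Phase 1 keeps variants impacting panel genes (CNVs by >=1 bp overlap with
a gene span from a user-supplied BED); phase 2 keeps high-quality variants
(membership in an aggregated high-quality site list, or FILTER PASS when
no list is supplied); phase 3 applies the panel-driven filter engine;
phase 4 keeps variants with a canonical-transcript annotation that are
present in fewer than ``k`` of the ``n`` cohort individuals.  CNVs, which
may lack transcript annotation, are exempt from the canonical test and
subject only to the presence test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .engine import FilterConfig, GeneAssessment, RetainedVariant, prioritise_individual
from .panel import Panel
from .variants import (
    InclusionLists,
    TranscriptAnnotation,
    VariantCall,
    VariantKey,
)

PHASES = ("panel_overlap", "high_quality", "panel_filter", "canonical_cohort")


class FunnelConfigError(ValueError):
    """Inconsistent funnel configuration (e.g. CNVs without gene spans)."""


@dataclass
class FunnelReport:
    """Per-phase retained counts and the final retained set for one
    individual — the funnel audit trail."""

    sample_id: str
    per_phase_counts: dict[str, int] = field(default_factory=dict)
    retained_final: list[RetainedVariant] = field(default_factory=list)
    assessments: list[GeneAssessment] = field(default_factory=list)
    cnv_canonical_exempt: int = 0  # CNVs passing phase 4 without the canonical test

    def counts(self) -> list[int]:
        return [self.per_phase_counts[p] for p in PHASES if p in self.per_phase_counts]


def phase1_panel_overlap(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, Sequence[TranscriptAnnotation]],
    panel: Panel,
    gene_spans: Mapping[str, IntervalTree] | None = None,
) -> list[VariantCall]:
    """Keep calls annotated to a panel gene; CNVs also qualify by >=1 bp
    overlap with a panel gene span (0-based half-open BED intervals whose
    name column is the gene symbol)."""
    genes = panel.gene_set()
    kept: list[VariantCall] = []
    for call in calls:
        in_panel = any(
            ann.gene_symbol in genes for ann in annotations.get(call.key, ())
        )
        if not in_panel and call.is_cnv:
            if gene_spans is None:
                raise FunnelConfigError(
                    "CNV present but no gene-region BED supplied for overlap"
                )
            tree = gene_spans.get(call.chrom)
            if tree is not None:
                start, end = call.span
                in_panel = any(iv.data in genes for iv in tree.overlap(start, end))
        if in_panel:
            kept.append(call)
    return kept


def phase2_high_quality(
    calls: Sequence[VariantCall], hq_sites: set[VariantKey] | None = None
) -> list[VariantCall]:
    """Keep high-quality calls: members of the aggregated high-quality
    site list when one is given, otherwise calls whose FILTER is PASS or
    empty."""
    if hq_sites is not None:
        return [c for c in calls if c.key in hq_sites]
    return [c for c in calls if c.quality_ok]


def phase3_panel_filter(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, Sequence[TranscriptAnnotation]],
    panel: Panel,
    lists: InclusionLists,
    config: FilterConfig,
) -> tuple[list[VariantCall], list[GeneAssessment], list[RetainedVariant]]:
    """Delegate to the filter engine; retained = qualifying variants of
    genes whose allelic requirement is satisfied."""
    assessments, retained = prioritise_individual(
        calls, annotations, panel, lists, config
    )
    keys = {r.variant_key for r in retained}
    kept = [c for c in calls if c.key in keys]
    return kept, assessments, retained


def cohort_presence(
    cohort_callsets: Iterable[Sequence[VariantCall]],
) -> dict[VariantKey, int]:
    """Number of individuals (not alleles) carrying each normalised key."""
    counts: dict[VariantKey, int] = {}
    for calls in cohort_callsets:
        for key in {c.key for c in calls}:
            counts[key] = counts.get(key, 0) + 1
    return counts


def phase4_canonical_cohort(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, Sequence[TranscriptAnnotation]],
    presence: Mapping[VariantKey, int],
    k: int = 4,
    n: int = 10,
) -> tuple[list[VariantCall], int]:
    """Keep calls with >=1 canonical-transcript annotation that are
    present in fewer than ``k`` of the ``n`` individuals (strict '<').

    CNVs skip the canonical test; the second return value counts them.
    """
    if k > n:
        raise FunnelConfigError(f"k={k} exceeds cohort size n={n}")
    kept: list[VariantCall] = []
    cnv_exempt = 0
    for call in calls:
        if presence.get(call.key, 0) >= k:
            continue
        if call.is_cnv:
            kept.append(call)
            cnv_exempt += 1
        elif any(ann.canonical for ann in annotations.get(call.key, ())):
            kept.append(call)
    return kept, cnv_exempt


def run_funnel(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, Sequence[TranscriptAnnotation]],
    panel: Panel,
    lists: InclusionLists,
    config: FilterConfig,
    *,
    sample_id: str,
    presence: Mapping[VariantKey, int],
    gene_spans: Mapping[str, IntervalTree] | None = None,
    hq_sites: set[VariantKey] | None = None,
    k: int = 4,
    n: int = 10,
) -> FunnelReport:
    """Run phases 1-4 for one individual and record per-phase counts.

    Counts are non-increasing across phases since every phase is a subset
    filter.  ``presence`` is the per-key individual count over the ``n``
    analysed individuals (see :func:`cohort_presence`).
    """
    report = FunnelReport(sample_id=sample_id)
    p1 = phase1_panel_overlap(calls, annotations, panel, gene_spans)
    report.per_phase_counts["panel_overlap"] = len(p1)
    p2 = phase2_high_quality(p1, hq_sites)
    report.per_phase_counts["high_quality"] = len(p2)
    p3, assessments, retained = phase3_panel_filter(
        p2, annotations, panel, lists, config
    )
    report.per_phase_counts["panel_filter"] = len(p3)
    p4, cnv_exempt = phase4_canonical_cohort(p3, annotations, presence, k=k, n=n)
    report.per_phase_counts["canonical_cohort"] = len(p4)
    final_keys = {c.key for c in p4}
    report.retained_final = [r for r in retained if r.variant_key in final_keys]
    report.assessments = assessments
    report.cnv_canonical_exempt = cnv_exempt
    return report
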
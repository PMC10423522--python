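"""Single-sample tiering comparator in the style of the NHS Genomic
Medicine Service / Genomics England triage scheme.

SNVs and indels go to tier 1/2/3: all tiers require the variant to be
rare for its inheritance pattern and protein-altering (at least one high-
or moderate-impact annotation).  Tier 1 and 2 are in-panel (tier 1 for
high impact or a known-pathogenic assertion, tier 2 for moderate impact);
tier 3 is out-of-panel.  CNVs go to TierA (high quality, overlapping the
panel) or TierNull (high quality, >2 kb, not overlapping).  The reviewable
set a clinical scientist looks at is tier1 + tier2 + TierA.

De-novo promotion and family segregation need trio data and are skipped in
single-sample mode (recorded in the assignment's reasons).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .panel import AllelicRequirement, Panel
from .variants import TranscriptAnnotation, VariantCall, VariantKey


class Tier(str, Enum):
    TIER1 = "tier1"
    TIER2 = "tier2"
    TIER3 = "tier3"
    TIER_A = "tierA"
    TIER_NULL = "tierNull"
    UNTIED = "untied"


SMALL_VARIANT_TIERS = {Tier.TIER1, Tier.TIER2, Tier.TIER3}
CNV_TIERS = {Tier.TIER_A, Tier.TIER_NULL}
REVIEWABLE_TIERS = {Tier.TIER1, Tier.TIER2, Tier.TIER_A}


@dataclass(frozen=True)
class TierAssignment:
    variant_key: VariantKey
    tier: Tier
    reasons: tuple[str, ...] = ()


# Rarity limits per inheritance pattern.  The scheme publishes no numeric
# values; these defaults are assumptions and must stay config-exposed.
DEFAULT_AF_LIMITS: dict[AllelicRequirement, float] = {
    AllelicRequirement.MONOALLELIC: 0.001,
    AllelicRequirement.BIALLELIC: 0.01,
    AllelicRequirement.HEMIZYGOUS: 0.001,
    AllelicRequirement.MONOALLELIC_AND_BIALLELIC: 0.01,
    AllelicRequirement.MITOCHONDRIAL: 0.002,
}


def _is_rare(
    annotations: Sequence[TranscriptAnnotation],
    requirements: Sequence[AllelicRequirement],
    af_limits: Mapping[AllelicRequirement, float],
) -> bool:
    af = max(
        (a.max_pop_af for a in annotations if a.max_pop_af is not None),
        default=None,
    )
    if af is None:
        return True
    if requirements:
        limit = max(af_limits[r] for r in requirements)
    else:
        limit = max(af_limits.values())  # out-of-panel: most permissive limit
    return af <= limit


def tier_small_variant(
    call: VariantCall,
    annotations: Sequence[TranscriptAnnotation],
    panel: Panel,
    known_pathogenic: set[VariantKey] = frozenset(),
    af_limits: Mapping[AllelicRequirement, float] | None = None,
) -> TierAssignment:
    """Tier one SNV/indel.

    Untied when not rare or without any high/moderate-impact annotation;
    otherwise tier1/2 by in-panel impact (a known-pathogenic assertion
    promotes to tier1 regardless of impact), tier3 out-of-panel.
    """
    af_limits = dict(af_limits or DEFAULT_AF_LIMITS)
    reasons = ["single-sample mode: de novo promotion and segregation skipped"]
    impacts = {a.impact for a in annotations}
    protein_altering = bool(impacts & {"high", "moderate"})
    panel_genes = panel.gene_set()
    in_panel_anns = [a for a in annotations if a.gene_symbol in panel_genes]
    requirements = tuple(
        {
            e.allelic_requirement
            for a in in_panel_anns
            for e in panel.entries_for_gene(a.gene_symbol)
        }
    )
    if not _is_rare(annotations, requirements, af_limits):
        if call.key in known_pathogenic and in_panel_anns:
            # known pathogenic assertion rescues an allele-frequency exclusion
            reasons.append("known pathogenic assertion overrides frequency")
            return TierAssignment(call.key, Tier.TIER1, tuple(reasons))
        reasons.append("not rare for inheritance pattern")
        return TierAssignment(call.key, Tier.UNTIED, tuple(reasons))
    if not protein_altering:
        reasons.append("no high/moderate impact annotation")
        return TierAssignment(call.key, Tier.UNTIED, tuple(reasons))
    if in_panel_anns:
        high = any(a.impact == "high" for a in in_panel_anns)
        if high or call.key in known_pathogenic:
            reasons.append(
                "in-panel high impact" if high else "in-panel known pathogenic"
            )
            return TierAssignment(call.key, Tier.TIER1, tuple(reasons))
        reasons.append("in-panel moderate impact")
        return TierAssignment(call.key, Tier.TIER2, tuple(reasons))
    reasons.append("protein-altering outside the virtual panel")
    return TierAssignment(call.key, Tier.TIER3, tuple(reasons))


def tier_cnv(
    cnv: VariantCall,
    gene_spans: Mapping[str, IntervalTree],
    panel: Panel,
    min_size: int = 2000,
) -> TierAssignment:
    """Tier one CNV: TierA for high-quality CNVs overlapping a panel gene
    span; TierNull for high-quality non-overlapping CNVs larger than
    ``min_size`` bp; untied otherwise."""
    if not cnv.quality_ok:
        return TierAssignment(cnv.key, Tier.UNTIED, ("CNV failed quality",))
    genes = panel.gene_set()
    tree = gene_spans.get(cnv.chrom)
    start, end = cnv.span
    overlaps = tree is not None and any(
        iv.data in genes for iv in tree.overlap(start, end)
    )
    if overlaps:
        return TierAssignment(cnv.key, Tier.TIER_A, ("overlaps panel gene span",))
    size = (cnv.end - cnv.pos + 1) if cnv.end is not None else len(cnv.ref)
    if size > min_size:
        return TierAssignment(
            cnv.key, Tier.TIER_NULL, (f"no panel overlap, {size} bp > {min_size} bp",)
        )
    return TierAssignment(
        cnv.key, Tier.UNTIED, (f"no panel overlap and {size} bp <= {min_size} bp",)
    )


@dataclass
class TierReport:
    assignments: list[TierAssignment] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def reviewable(self) -> list[TierAssignment]:
        """tier1 + tier2 + TierA — the set presented for clinical review."""
        return [a for a in self.assignments if a.tier in REVIEWABLE_TIERS]


def tier_report(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, Sequence[TranscriptAnnotation]],
    panel: Panel,
    gene_spans: Mapping[str, IntervalTree],
    known_pathogenic: set[VariantKey] = frozenset(),
    af_limits: Mapping[AllelicRequirement, float] | None = None,
    min_cnv_size: int = 2000,
) -> TierReport:
    """Tier every call and tally counts per tier.

    Each variant receives exactly one tier label (or untied); the
    reviewable set and counts are invariant to input record order.
    """
    assignments: list[TierAssignment] = []
    for call in calls:
        if call.is_cnv:
            assignments.append(tier_cnv(call, gene_spans, panel, min_cnv_size))
        else:
            assignments.append(
                tier_small_variant(
                    call,
                    list(annotations.get(call.key, ())),
                    panel,
                    known_pathogenic,
                    af_limits,
                )
            )
    assignments.sort(key=lambda a: a.variant_key)
    counts = Counter(a.tier.value for a in assignments)
    return TierReport(
        assignments=assignments,
        counts={t.value: counts.get(t.value, 0) for t in Tier},
    )
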
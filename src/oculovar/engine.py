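"""The panel-driven variant filter.

For each variant x panel-entry pair the engine decides whether the variant
*qualifies* — either through the standard route (population frequency below
the requirement-specific cut-off AND a consequence consistent with the
entry's disease mechanism) or through an inclusion-list override (known
pathogenic allele, splice-flagged allele, hypomorphic allele).  Per gene it
then decides whether the allelic requirement is satisfied by the qualifying
variants, and emits the qualifying variants of satisfied genes.

Frequency cut-offs default to 0.001 for monoallelic and 0.05 for biallelic
genes; hemizygous and mitochondrial entries use the stricter monoallelic
cut-off.  Comparisons are non-strict (af <= threshold passes); a missing
frequency is treated as rare so novel variants are never discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .panel import AllelicRequirement, MutationConsequence, Panel, PanelEntry
from .variants import (
    InclusionLists,
    TranscriptAnnotation,
    VarClass,
    VariantCall,
    VariantKey,
    Zygosity,
)

# Accepted Sequence Ontology terms per disease mechanism.  Loss-of-function
# entries admit missense and in-frame changes as well as canonical LoF
# classes: curated LoF genes frequently harbour pathogenic missense alleles,
# and UTR/deep-intronic diagnoses enter via the inclusion lists instead.
LOF_TERMS = frozenset(
    {
        "transcript_ablation",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "frameshift_variant",
        "stop_lost",
        "start_lost",
        "missense_variant",
        "inframe_insertion",
        "inframe_deletion",
        "splice_region_variant",
    }
)
MISSENSE_INFRAME_TERMS = frozenset(
    {"missense_variant", "inframe_insertion", "inframe_deletion"}
)
ALTERED_PROTEIN_TERMS = MISSENSE_INFRAME_TERMS | {"stop_lost", "start_lost"}

DEFAULT_CONSEQUENCE_MAP: dict[MutationConsequence, frozenset[str]] = {
    MutationConsequence.LOSS_OF_FUNCTION: LOF_TERMS,
    MutationConsequence.ALL_MISSENSE_OR_INFRAME: MISSENSE_INFRAME_TERMS,
    MutationConsequence.DOMINANT_NEGATIVE: ALTERED_PROTEIN_TERMS,
    MutationConsequence.ACTIVATING: ALTERED_PROTEIN_TERMS,
    MutationConsequence.UNCERTAIN: LOF_TERMS | ALTERED_PROTEIN_TERMS,
}


class QualifyReason(str, Enum):
    CONSEQUENCE = "consequence"
    KNOWN_PATHOGENIC = "known_pathogenic"
    SPLICE_FLAGGED = "splice_flagged"
    HYPOMORPHIC = "hypomorphic"


class SatisfactionMode(str, Enum):
    MONOALLELIC_HIT = "monoallelic_hit"
    HOMOZYGOUS = "homozygous"
    PUTATIVE_COMPOUND_HET = "putative_compound_het"
    HEMIZYGOUS = "hemizygous"
    NOT_SATISFIED = "not_satisfied"


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds and maps for the filter engine."""

    af_monoallelic: float = 0.001
    af_biallelic: float = 0.05
    splice_delta_threshold: float = 0.5
    consequence_map: Mapping[MutationConsequence, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MAP)
    )
    canonical_only: bool = False
    retain_carrier_hets_x: bool = False

    def __post_init__(self) -> None:
        for name in ("af_monoallelic", "af_biallelic", "splice_delta_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        missing = [m for m in MutationConsequence if m not in self.consequence_map]
        if missing:
            raise ValueError(
                f"consequence_map missing {[m.value for m in missing]}"
            )

    def af_threshold(self, requirement: AllelicRequirement) -> float:
        if requirement is AllelicRequirement.BIALLELIC:
            return self.af_biallelic
        # monoallelic, hemizygous, mitochondrial: the stricter cut-off
        return self.af_monoallelic


QualifyingVariant = tuple[VariantCall, TranscriptAnnotation, QualifyReason]


@dataclass
class GeneAssessment:
    """Outcome of assessing one panel entry against one individual."""

    gene_symbol: str
    panel_entry: PanelEntry
    qualifying: list[QualifyingVariant] = field(default_factory=list)
    satisfied: bool = False
    satisfaction_mode: SatisfactionMode = SatisfactionMode.NOT_SATISFIED

    def __post_init__(self) -> None:
        assert self.satisfied == (
            self.satisfaction_mode is not SatisfactionMode.NOT_SATISFIED
        )


def frequency_pass(
    annotation: TranscriptAnnotation,
    requirement: AllelicRequirement,
    config: FilterConfig,
) -> bool:
    """True iff the population frequency is absent or at most the cut-off
    for this allelic requirement."""
    if annotation.max_pop_af is None:
        return True
    return annotation.max_pop_af <= config.af_threshold(requirement)


def consequence_pass(
    annotation: TranscriptAnnotation,
    entry: PanelEntry,
    config: FilterConfig,
    *,
    call: VariantCall | None = None,
) -> bool:
    """True iff a consequence term is consistent with the entry's disease
    mechanism.  A CNV deletion overlapping the gene counts as a
    transcript-ablating loss-of-function allele for LoF entries."""
    if (
        call is not None
        and call.var_class is VarClass.CNV_DEL
        and entry.mutation_consequence is MutationConsequence.LOSS_OF_FUNCTION
    ):
        return True
    accepted = config.consequence_map[entry.mutation_consequence]
    return bool(set(annotation.so_terms) & set(accepted))


def inclusion_override(
    variant_key: VariantKey, lists: InclusionLists, config: FilterConfig
) -> QualifyReason | None:
    """Inclusion-list check; any hit bypasses both the frequency and the
    consequence filter.  Precedence: known pathogenic, then splice-flagged
    (delta >= threshold), then hypomorphic."""
    if variant_key in lists.known_pathogenic:
        return QualifyReason.KNOWN_PATHOGENIC
    delta = lists.splice_flagged.get(variant_key)
    if delta is not None and delta >= config.splice_delta_threshold:
        return QualifyReason.SPLICE_FLAGGED
    if variant_key in lists.hypomorphic:
        return QualifyReason.HYPOMORPHIC
    return None


def _qualify(
    call: VariantCall,
    annotation: TranscriptAnnotation,
    entry: PanelEntry,
    lists: InclusionLists,
    config: FilterConfig,
) -> QualifyReason | None:
    override = inclusion_override(call.key, lists, config)
    if override is not None:
        return override
    if frequency_pass(annotation, entry.allelic_requirement, config) and consequence_pass(
        annotation, entry, config, call=call
    ):
        return QualifyReason.CONSEQUENCE
    return None


def assess_gene(
    entry: PanelEntry,
    variants: Sequence[tuple[VariantCall, TranscriptAnnotation]],
    lists: InclusionLists,
    config: FilterConfig,
) -> GeneAssessment:
    """Decide whether the entry's allelic requirement is satisfied by the
    qualifying variants among ``variants`` (all annotated to the entry's
    gene).

    Satisfaction rules:

    * monoallelic / mitochondrial — any qualifying variant;
    * biallelic — a homozygous qualifying variant, or two or more distinct
      qualifying het alleles (a qualifying CNV deletion het counts as one
      allele; phase is unknown, so two hets are a *putative* compound het);
    * hemizygous — a hemizygous or homozygous qualifying variant; a het
      (carrier) qualifies only when ``retain_carrier_hets_x`` is set.
    """
    for call, ann in variants:
        if ann.gene_symbol != entry.gene_symbol:
            raise ValueError(
                f"variant {call.key} annotated to {ann.gene_symbol!r}, "
                f"expected {entry.gene_symbol!r}"
            )
    qualifying: list[QualifyingVariant] = []
    seen: set[VariantKey] = set()  # one qualifying record per allele key
    for call, ann in variants:
        if call.key in seen:
            continue
        reason = _qualify(call, ann, entry, lists, config)
        if reason is not None:
            qualifying.append((call, ann, reason))
            seen.add(call.key)

    requirement = entry.allelic_requirement
    mode = SatisfactionMode.NOT_SATISFIED
    zygs = [call.zygosity for call, _, _ in qualifying]
    if qualifying:
        if requirement in (
            AllelicRequirement.MONOALLELIC,
            AllelicRequirement.MITOCHONDRIAL,
        ):
            mode = SatisfactionMode.MONOALLELIC_HIT
        elif requirement is AllelicRequirement.BIALLELIC:
            if Zygosity.HOM_ALT in zygs:
                mode = SatisfactionMode.HOMOZYGOUS
            elif sum(1 for z in zygs if z is Zygosity.HET) >= 2:
                mode = SatisfactionMode.PUTATIVE_COMPOUND_HET
        elif requirement is AllelicRequirement.HEMIZYGOUS:
            if Zygosity.HEMIZYGOUS in zygs or Zygosity.HOM_ALT in zygs:
                mode = SatisfactionMode.HEMIZYGOUS
            elif config.retain_carrier_hets_x and Zygosity.HET in zygs:
                mode = SatisfactionMode.HEMIZYGOUS
        else:  # monoallelic_and_biallelic should have been expanded upstream
            raise ValueError(
                f"unexpanded allelic requirement {requirement}; call "
                "Panel.expand_requirements() first"
            )
    return GeneAssessment(
        gene_symbol=entry.gene_symbol,
        panel_entry=entry,
        qualifying=qualifying,
        satisfied=mode is not SatisfactionMode.NOT_SATISFIED,
        satisfaction_mode=mode,
    )


@dataclass
class RetainedVariant:
    """One row of the prioritisation report."""

    sample: str
    gene_symbol: str
    variant_key: VariantKey
    zygosity: Zygosity
    qualify_reason: QualifyReason
    satisfaction_mode: SatisfactionMode


def prioritise_individual(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, Sequence[TranscriptAnnotation]],
    panel: Panel,
    lists: InclusionLists,
    config: FilterConfig,
) -> tuple[list[GeneAssessment], list[RetainedVariant]]:
    """Run the full filter for one individual.

    Returns one :class:`GeneAssessment` per panel entry whose gene has at
    least one overlapping variant, plus the retained-variant report
    (qualifying variants of satisfied genes, ordered by chrom, pos, gene).
    """
    if not panel.entries:
        raise ValueError("empty panel")
    panel = panel.expand_requirements()

    per_gene: dict[str, list[tuple[VariantCall, TranscriptAnnotation]]] = {}
    for call in calls:
        for ann in annotations.get(call.key, ()):
            if config.canonical_only and not ann.canonical:
                continue
            if ann.gene_symbol:
                per_gene.setdefault(ann.gene_symbol, []).append((call, ann))

    assessments: list[GeneAssessment] = []
    retained: list[RetainedVariant] = []
    for entry in panel.entries:
        variants = per_gene.get(entry.gene_symbol)
        if not variants:
            continue
        assessment = assess_gene(entry, variants, lists, config)
        assessments.append(assessment)
        if assessment.satisfied:
            for call, _ann, reason in assessment.qualifying:
                retained.append(
                    RetainedVariant(
                        sample=call.sample,
                        gene_symbol=entry.gene_symbol,
                        variant_key=call.key,
                        zygosity=call.zygosity,
                        qualify_reason=reason,
                        satisfaction_mode=assessment.satisfaction_mode,
                    )
                )
    retained.sort(key=lambda r: (r.variant_key[0], r.variant_key[1], r.gene_symbol,
                                 r.variant_key[2], r.variant_key[3]))
    assessments.sort(key=lambda a: (a.gene_symbol, a.panel_entry.disease_name,
                                    a.panel_entry.allelic_requirement.value))
    return assessments, retained


def retained_keys(retained: Iterable[RetainedVariant]) -> set[VariantKey]:
    return {r.variant_key for r in retained}
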
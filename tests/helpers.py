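"""Small builders shared across the test modules."""

from __future__ import annotations

from pathlib import Path

from oculovar.panel import (
    AllelicRequirement,
    Confidence,
    MutationConsequence,
    Panel,
    PanelEntry,
)
from oculovar.variants import TranscriptAnnotation, VarClass, VariantCall, Zygosity


def mk_call(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    zygosity=Zygosity.HET,
    var_class=VarClass.SNV,
    end=None,
    sample="S1",
    filters=(),
    quality_ok=True,
) -> VariantCall:
    return VariantCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        var_class=var_class,
        zygosity=zygosity,
        sample=sample,
        end=end,
        filters=tuple(filters),
        quality_ok=quality_ok,
    )


def mk_ann(
    call: VariantCall,
    gene="GENE1",
    so_terms=("missense_variant",),
    canonical=True,
    impact="moderate",
    af=None,
    transcript="T1",
) -> TranscriptAnnotation:
    return TranscriptAnnotation(
        variant_key=call.key,
        gene_symbol=gene,
        transcript_id=transcript,
        so_terms=tuple(so_terms),
        canonical=canonical,
        impact=impact,
        max_pop_af=af,
    )


def mk_entry(
    gene="GENE1",
    requirement=AllelicRequirement.BIALLELIC,
    mechanism=MutationConsequence.LOSS_OF_FUNCTION,
    confidence=Confidence.CONFIRMED,
    disease=None,
) -> PanelEntry:
    return PanelEntry(
        gene_symbol=gene,
        disease_name=disease or f"{gene} disorder",
        allelic_requirement=requirement,
        mutation_consequence=mechanism,
        confidence=confidence,
    )


def mk_panel(*entries: PanelEntry) -> Panel:
    return Panel(entries=list(entries), name="test")


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##contig=<ID=chrX,length=1000000>
##FILTER=<ID=LowQual,Description="Low quality">
##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: Allele|Consequence|IMPACT|SYMBOL|Feature|CANONICAL|MAX_AF">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(path: Path, records: list[str], sample: str = "S1") -> Path:
    """Write a small plain-text VCF; ``records`` are tab-joined body lines."""
    path.write_text(VCF_HEADER.format(sample=sample) + "\n".join(records) + "\n")
    return path
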
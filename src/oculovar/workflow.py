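"""Convenience orchestration: load a per-individual VCF with its
annotations, and run the four-phase funnel across a cohort directory."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pysam
from intervaltree import IntervalTree

from .engine import FilterConfig
from .funnel import FunnelReport, cohort_presence, run_funnel
from .panel import Panel
from .variants import (
    InclusionLists,
    TranscriptAnnotation,
    VariantCall,
    VariantIOError,
    VariantKey,
    read_annotations,
    read_callset,
)


def vcf_sample(path: str | Path) -> str:
    """The single sample name of a per-individual VCF."""
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    vcf.close()
    if len(samples) != 1:
        raise VariantIOError(
            f"{path}: expected exactly one sample, found {samples}"
        )
    return samples[0]


def load_individual(
    path: str | Path, sample: str | None = None
) -> tuple[str, list[VariantCall], dict[VariantKey, list[TranscriptAnnotation]]]:
    """Read one individual's calls and CSQ annotations from a merged VCF."""
    sample = sample or vcf_sample(path)
    calls = read_callset(path, sample)
    annotations = read_annotations(path)
    return sample, calls, annotations


def run_cohort_funnel(
    vcf_paths: Sequence[str | Path],
    panel: Panel,
    lists: InclusionLists,
    config: FilterConfig,
    *,
    gene_spans: Mapping[str, IntervalTree] | None = None,
    hq_sites: set[VariantKey] | None = None,
    k: int = 4,
) -> list[FunnelReport]:
    """Run the whole-genome funnel for every individual of a cohort.

    Cohort presence (phase 4) is counted over exactly these individuals;
    ``n`` is the number of VCFs supplied.
    """
    individuals = [load_individual(p) for p in vcf_paths]
    presence = cohort_presence([calls for _, calls, _ in individuals])
    n = len(individuals)
    return [
        run_funnel(
            calls,
            annotations,
            panel,
            lists,
            config,
            sample_id=sample,
            presence=presence,
            gene_spans=gene_spans,
            hq_sites=hq_sites,
            k=k,
            n=n,
        )
        for sample, calls, annotations in individuals
    ]
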
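"""Report writers: TSV for analysts, JSON twins for machines.

Column orders are frozen; both formats are byte-deterministic for the
same inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .engine import GeneAssessment, RetainedVariant
from .funnel import PHASES, FunnelReport
from .tiering import TierReport

RETAINED_COLUMNS = (
    "sample",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "zygosity",
    "qualify_reason",
    "satisfaction_mode",
)


def retained_tsv(retained: Sequence[RetainedVariant]) -> str:
    lines = ["\t".join(RETAINED_COLUMNS)]
    for r in retained:
        chrom, pos, ref, alt = r.variant_key
        lines.append(
            "\t".join(
                [
                    r.sample,
                    r.gene_symbol,
                    chrom,
                    str(pos),
                    ref,
                    alt,
                    r.zygosity.value,
                    r.qualify_reason.value,
                    r.satisfaction_mode.value,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def assessments_json(assessments: Sequence[GeneAssessment]) -> str:
    payload = [
        {
            "gene": a.gene_symbol,
            "disease": a.panel_entry.disease_name,
            "allelic_requirement": a.panel_entry.allelic_requirement.value,
            "mutation_consequence": a.panel_entry.mutation_consequence.value,
            "satisfied": a.satisfied,
            "satisfaction_mode": a.satisfaction_mode.value,
            "qualifying": [
                {
                    "key": list(call.key),
                    "zygosity": call.zygosity.value,
                    "reason": reason.value,
                }
                for call, _ann, reason in a.qualifying
            ],
        }
        for a in assessments
    ]
    return json.dumps(payload, indent=2, sort_keys=True)


def funnel_json(reports: Sequence[FunnelReport]) -> str:
    payload = [
        {
            "sample": rep.sample_id,
            "per_phase_counts": {p: rep.per_phase_counts[p] for p in PHASES},
            "cnv_canonical_exempt": rep.cnv_canonical_exempt,
            "retained_final": [
                {
                    "gene": r.gene_symbol,
                    "key": list(r.variant_key),
                    "zygosity": r.zygosity.value,
                    "qualify_reason": r.qualify_reason.value,
                    "satisfaction_mode": r.satisfaction_mode.value,
                }
                for r in rep.retained_final
            ],
        }
        for rep in reports
    ]
    return json.dumps(payload, indent=2, sort_keys=True)


def funnel_tsv(reports: Sequence[FunnelReport]) -> str:
    lines = ["\t".join(["sample", *PHASES])]
    for rep in reports:
        lines.append(
            "\t".join([rep.sample_id, *[str(rep.per_phase_counts[p]) for p in PHASES]])
        )
    return "\n".join(lines) + "\n"


def tier_json(report: TierReport) -> str:
    payload = {
        "counts": report.counts,
        "reviewable": [
            {"key": list(a.variant_key), "tier": a.tier.value, "reasons": list(a.reasons)}
            for a in report.reviewable
        ],
        "assignments": [
            {"key": list(a.variant_key), "tier": a.tier.value, "reasons": list(a.reasons)}
            for a in report.assignments
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def write_text(path: str | Path, text: str) -> None:
    Path(path).write_text(text)
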
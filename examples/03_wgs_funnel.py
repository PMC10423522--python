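"""The four-phase whole-genome funnel with its audit trail.

Phase 1 keeps panel-gene variants, phase 2 high-quality calls, phase 3
applies the panel filter, phase 4 keeps canonical-transcript variants seen
in fewer than k of the n cohort individuals.
"""

import tempfile

from oculovar import FilterConfig, read_inclusion_lists
from oculovar.funnel import PHASES
from oculovar.simulate import make_cohort, make_panel
from oculovar.workflow import run_cohort_funnel

fixture = make_panel(n_genes=10, seed=7)
with tempfile.TemporaryDirectory() as tmp:
    cohort = make_cohort(fixture, n_individuals=10, seed=7, out_dir=tmp)
    lists = read_inclusion_lists(
        cohort.known_pathogenic, cohort.splice_flagged, cohort.hypomorphic
    )
    reports = run_cohort_funnel(
        sorted(cohort.vcf_paths.values()),
        fixture.panel,
        lists,
        FilterConfig(),
        gene_spans=fixture.gene_spans(),
        k=4,
    )

print("sample  " + "  ".join(f"{p:>16}" for p in PHASES))
for rep in reports:
    counts = "  ".join(f"{rep.per_phase_counts[p]:>16}" for p in PHASES)
    print(f"{rep.sample_id:6}  {counts}")

recovered = sum(len(r.retained_final) for r in reports)
print(
    f"\nCounts shrink monotonically; {recovered} variants survive in total.\n"
    "A rare allele shared by five individuals is removed at the final\n"
    "cohort-presence step (present in >= 4 of 10), while every planted\n"
    "causal genotype survives all four phases."
)
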
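"""Single-sample tiering: SNVs/indels to tier 1/2/3, CNVs to
TierA/TierNull, and the reviewable set (tier1 + tier2 + TierA)."""

import tempfile

from oculovar import parse_panel_file, read_bed
from oculovar.tiering import tier_report
from oculovar.simulate import make_cohort, make_panel
from oculovar.workflow import load_individual

fixture = make_panel(n_genes=10, seed=7)
with tempfile.TemporaryDirectory() as tmp:
    cohort = make_cohort(fixture, n_individuals=10, seed=7, out_dir=tmp)
    panel = parse_panel_file(cohort.panel_csv)
    spans = read_bed(cohort.gene_bed)
    sample = "S03"
    _, calls, annotations = load_individual(cohort.vcf_paths[sample])
    report = tier_report(calls, annotations, panel, spans)

print(f"{sample}: {len(calls)} calls tiered")
print("counts:", {k: v for k, v in report.counts.items() if v})
print(f"reviewable set (tier1 + tier2 + TierA): {len(report.reviewable)} variant(s)")
for a in report.reviewable:
    chrom, pos, ref, alt = a.variant_key
    print(f"  {chrom}:{pos} {ref}>{alt}  {a.tier.value}  ({a.reasons[-1]})")
print(
    "\nTiering triages by impact, rarity and panel membership only; unlike\n"
    "the panel filter it does not test whether the allelic requirement of\n"
    "the gene is actually satisfied."
)
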
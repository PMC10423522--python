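# oculovar

Panel-driven prioritisation of genomic variants for inherited ophthalmic
disease.

Clinical genome analysis for Mendelian eye disease drowns in candidate
variants: a whole genome yields millions of calls, of which at most a
handful belong to the molecular diagnosis. `oculovar` implements the
filtering logic that makes this tractable — a curated gene-panel filter in
the gene2phenotype (G2P) style, a four-phase whole-genome funnel, a
Genomics England-style tiering comparator, and the precision/sensitivity
arithmetic used to evaluate such strategies. It is aimed at clinical
bioinformaticians and methods developers who want the filtering rules as a
reusable, testable library rather than buried in a pipeline.

## The model

A panel entry links a gene *g* to a disease through a **disease
mechanism**: an *allelic requirement* `A(g) ∈ {monoallelic, biallelic,
hemizygous, mitochondrial}` and a *mutation consequence* `M(g) ∈
{loss_of_function, dominant_negative, all_missense_or_inframe, activating,
uncertain}`, plus a curation confidence. A variant *v* with Sequence
Ontology consequence terms `SO(v)` and maximum population frequency
`AF(v)` **qualifies** for the entry iff

```
AF(v) ≤ τ(A(g))   and   SO(v) ∩ C(M(g)) ≠ ∅
```

with `τ(monoallelic) = 0.001`, `τ(biallelic) = 0.05` (hemizygous and
mitochondrial use the stricter monoallelic cut-off), and `C(·)` a
configurable consequence map — **or** if it appears on an inclusion list
(known pathogenic alleles; splice-flagged alleles with delta score
≥ 0.5; hypomorphic alleles), which bypasses both tests. A gene is
**reported** when its allelic requirement is satisfied by qualifying
variants: any hit for monoallelic; a homozygote or ≥ 2 distinct het
alleles (putative compound het, CNV deletions counting as one allele) for
biallelic; a hemizygous/homozygous hit for X-linked genes.

For whole genomes, four funnel phases are applied in order: (1) panel-gene
overlap (CNVs by ≥ 1 bp span overlap), (2) high-quality calls, (3) the
panel filter above, (4) canonical-transcript variants present in fewer
than *k* = 4 of the *n* = 10 cohort individuals.

Evaluation uses precision (PPV) = diagnostic/retained per case (percent,
rounded half up), cohort median/range of unrounded precision, binomial
sensitivity with a Bayesian Beta posterior interval (Jeffreys prior,
highest-posterior-density by default), and a paired Wilcoxon signed-rank
test (exact null distribution for n ≤ 25).

## Worked example

```
python examples/02_prioritise_individual.py
```

prints, for a simulated individual carrying a planted SNV + exonic-deletion
compound heterozygote among noise variants:

```
S03: planted scenario = compound_het_snv_cnv in OCG1
callset size 8; retained 3 variant(s):
  chrS1:20091 T>G  gene=OCG1  zygosity=het  reason=consequence  mode=putative_compound_het
  chrS1:30001 N><DEL>  gene=OCG1  zygosity=het  reason=consequence  mode=putative_compound_het
  chrS8:10051 G>A  gene=OCG8  zygosity=het  reason=consequence  mode=monoallelic_hit
```

Both planted alleles of the biallelic gene survive — one small variant and
one CNV deletion, counted together as a putative compound heterozygote —
while the frequency-stratified noise is removed. The third variant is a
rare allele shared across the cohort; `examples/03_wgs_funnel.py` shows the
funnel's cohort-presence phase removing it. The other examples cover panel
handling (`01`), tiering (`04`) and the evaluation metrics on the published
ten-case whole-genome comparison (`05`).

A command-line interface wraps the same library:

```
oculovar simulate --genes 10 --individuals 10 --seed 7 --out cohort/
oculovar run --vcf cohort/S01.vcf --panel cohort/panel.csv --lists-dir cohort/
oculovar wgs --cohort-dir cohort/ --panel cohort/panel.csv --gene-bed cohort/genes.bed
oculovar tier --vcf cohort/S01.vcf --panel cohort/panel.csv --gene-bed cohort/genes.bed
oculovar metrics --cases examples/data/wgs_comparison_cases.tsv
```

Exit codes: 0 success, 2 validation error, 3 I/O error. A YAML config
(`--config`) can override every threshold: `filter.af_monoallelic`,
`filter.af_biallelic`, `filter.splice_delta_threshold`,
`filter.consequence_map`, `tier_af_limits`, `min_cnv_size`, `funnel_k`.

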
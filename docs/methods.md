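# Methods

## The filtering model

`oculovar` treats variant prioritisation for Mendelian eye disease as a
deterministic decision problem over a curated gene panel. Each panel
entry is a gene–disease thread carrying an **allelic requirement** (the
genotype configuration needed for disease), a **mutation consequence**
(the mechanism class of its pathogenic alleles) and a curation
confidence. Entries declaring both dominant and recessive inheritance
(`monoallelic_and_biallelic`) are expanded into one entry per requirement
before filtering, so every downstream decision handles a single
requirement.

A variant qualifies for an entry through one of two routes:

1. **Standard route** — its maximum population frequency is at or below
   the requirement-specific cut-off *and* at least one of its Sequence
   Ontology consequence terms is accepted by the entry's mechanism.
2. **Inclusion-list override** — the allele is on the known-pathogenic
   list, is splice-flagged with a delta score at or above the threshold,
   or is a listed hypomorphic allele. An override bypasses both the
   frequency and the consequence test: these lists exist precisely to
   rescue alleles (common hypomorphs, deep-intronic splice variants,
   UTR variants) that the standard route would discard.

A gene is reported when qualifying variants satisfy its requirement:
any qualifying variant for monoallelic or mitochondrial entries; a
homozygote or at least two distinct qualifying het alleles for biallelic
entries; a hemizygous or homozygous qualifying variant for X-linked
entries. Two qualifying hets are labelled a *putative* compound
heterozygote — the data are single-sample and unphased, so trans
configuration is assumed rather than demonstrated. A qualifying het CNV
deletion counts as one allele of such a pair. Identical records at the
same normalised allele key are deduplicated before counting, so one
allele can never impersonate two.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| `af_monoallelic` | 0.001 | frequency cut-off for variants in monoallelic genes |
| `af_biallelic` | 0.05 | cut-off for biallelic genes (recessive alleles persist at higher frequency) |
| hemizygous / mitochondrial cut-off | 0.001 | only two cut-offs are defined; the stricter one is the safe choice for dominant-acting classes |
| `splice_delta_threshold` | 0.5 | the widely used high-precision SpliceAI operating point; configurable |
| missing frequency | passes | a novel allele absent from population databases must not be discarded |
| frequency comparison | non-strict (≤) | a boundary choice that must stay consistent with the tests; `af = 0.001` passes monoallelic |
| funnel `k`, `n` | 4, 10 | canonical-cohort phase keeps variants present in fewer than 4 of the 10 individuals (strict `<`) |
| tiering frequency limits | mono 0.001, biallelic 0.01, mito 0.002 | the published scheme names rarity sources but no numbers; these are assumptions, config-exposed, never silently trusted |
| `min_cnv_size` (TierNull) | 2000 bp | CNVs must exceed 2 kb to be TierNull; boundary strict (`>`) |

The default consequence map admits missense and in-frame changes for
loss-of-function entries in addition to canonical LoF terms
(stop/frameshift/splice-site/start-loss/ablation). Curated LoF genes
frequently harbour pathogenic missense alleles, and restricting LoF
entries to truncating classes would silently drop them; UTR and
deep-intronic diagnoses enter via the inclusion lists instead. The map is
config-overridable per mechanism.

## Coordinate and normalisation conventions

Variant calls are VCF 1-based; masks and gene spans are BED 0-based
half-open, with conversion localised to the masking/overlap code.
Multi-allelic records are split per alternate allele before anything
else. Indels are reduced to their parsimonious form by trimming shared
trailing then shared leading bases (keeping one base each side, advancing
`pos` over trimmed leading bases). Reference-based left-shifting across
repeat tracts is deliberately not attempted: the package bundles no
reference genome, and the same normaliser is applied to callsets and
inclusion lists so keys always join exactly. Normalisation is idempotent
(property-tested). CNVs keep symbolic alleles and are keyed on
(chrom, pos, end, alt). A split allele the sample does not carry (e.g.
the untyped side of `0/0` after splitting) contributes nothing to
prioritisation and is dropped by the reader.

Zygosity follows the genotype: all called alleles equal to the alternate
→ homozygous; a single-allele genotype carrying it → hemizygous;
otherwise het. CNV zygosity is taken from the genotype field when
present; depth-based re-estimation is the caller's job, not this
package's.

## Tiering comparator

The tiering module reproduces, in single-sample mode, the triage scheme
used by the NHS Genomic Medicine Service: rare, protein-altering
SNVs/indels go to tier 1 (in-panel high impact, or any impact with a
known-pathogenic assertion — which also rescues alleles excluded on
frequency), tier 2 (in-panel moderate impact) or tier 3 (out-of-panel);
high-quality CNVs go to TierA (panel overlap) or TierNull (> 2 kb, no
overlap). De-novo promotion and family segregation need trio data and are
recorded as skipped in each assignment's reasons. ClinVar matching is by
exact normalised allele; codon-level ("same amino acid change") matching
would require bundled transcript models and is out of scope.

## Evaluation metrics

Percentages are rounded **half away from zero** (12.5 → 13) — a hard
compatibility rule for clinical reporting, witnessed in the tests.
Cohort summaries take the median/min/max of *unrounded* per-case
precision and round once at the end. Sensitivity denominators count
individuals, not variants.

Sensitivity intervals come from the Beta(a + k, b + n − k) posterior
under a Beta(a, b) prior (Jeffreys, (0.5, 0.5), by default). The default
interval is highest-posterior-density, computed by minimising interval
width over the lower tail probability (bounded scalar minimisation,
tolerance 1e−13 on the tail probability); monotone-density posteriors
(a ≤ 1 or b ≤ 1) hug the corresponding boundary, and a U-shaped
posterior falls back to equal-tailed, where a single-interval HPD does
not exist. Equal-tailed intervals use Beta quantiles directly. Both are
verified against an independent quadrature oracle to 1e−6.

The paired comparison is the Wilcoxon **signed-rank** test (the paired
analogue of the rank-sum test), two-sided,
`p = min(1, 2·min(P(W ≤ w), P(W ≥ w)))`. Zero differences are dropped
(all-zero input returns p = 1 with a warning). For n ≤ 25 the null
distribution of the positive rank sum is built exactly by dynamic
programming over sign assignments, with midranks doubled to integers so
ties are handled exactly; larger n uses the normal approximation with
tie correction and no continuity correction.

## The synthetic cohort generator

`oculovar.simulate` emulates the package's study conditions: a toy panel
(every requirement/mechanism/confidence enum covered from 8 genes up,
X-linked genes on a synthetic X contig) and a 10-individual cohort in
which each individual carries one planted diagnostic scenario —
homozygous LoF, compound het, SNV + CNV-deletion compound event,
monoallelic missense, hemizygous, deep-intronic splice-flagged allele,
hypomorphic common allele — plus Poisson(5) noise variants whose
population frequencies straddle the 0.001 and 0.05 cut-offs.
Common-noise individuals receive *damaging* consequences at high
frequency, so only the frequency filter blocks them; other noise is
synonymous/intronic. Five individuals share one rare canonical allele in
a panel gene so the cohort-presence phase has real work to do. The
genome is synthetic (contigs `chrS*`, coordinates < 10⁶) and
consequences are written directly as VEP-style CSQ annotations, so no
reference sequence or annotation database is needed; all randomness
flows through one seeded generator and outputs are byte-identical per
seed.

What passing on these fixtures does **not** show: performance on real
genomes with alignment artefacts, multi-transcript annotation conflicts,
population-stratified frequencies, segmental duplications or phased
trios. The generator plants unambiguous truth; real cohorts do not.
A second, adversarial in-memory generator (`random_engine_inputs`)
exercises every branch of the qualification/satisfaction logic against a
brute-force oracle that enumerates all variant–entry pairs and allele
combinations; the two generators serve different purposes and are both
part of the tested API.

## Problem sizes

The shipped evaluation runs a 10-gene panel over 10 individuals with
Poisson(5) noise per individual (engine, funnel, tiering), 200 random
oracle-comparison cohorts of up to 50 variants, and 50 random
interval-oracle triples — the whole suite completes in seconds, and the
acceptance script likewise.

## Known limitations

- Single-sample only: no phasing, no trio segregation, no de-novo logic.
- Frequency filtering uses the maximum over whatever AF-like fields the
  annotation block exposes; population-specific strategies need a custom
  field list.
- The canonical-transcript test in funnel phase 4 exempts CNVs (which may
  lack transcript annotation); they face only the presence test, and the
  report flags how many passed that way.
- Hypomorphic/splice/known-pathogenic content must be supplied; the
  package curates nothing.
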
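"""Deterministic synthetic fixtures: toy gene panels, per-individual VCFs
with planted causal genotypes plus frequency-stratified noise, inclusion
lists, gene-region BEDs and a truth manifest.

The generator emulates the study conditions the rest of the package is
evaluated under: a small curated panel mixing allelic requirements and
disease mechanisms, and individuals each carrying one planted diagnostic
scenario (homozygous LoF, compound het, SNV+CNV compound event, dominant
het, hemizygous, deep-intronic splice-flagged, hypomorphic common allele)
among noise variants whose population frequencies straddle the 0.001 and
0.05 filter thresholds.  A tiny synthetic genome (contigs chrS0..chrSn and
chrSX, coordinates under 10^6) is used; consequences are supplied directly
as VEP-style CSQ annotations, so no reference sequence is needed.

All randomness flows through a seeded generator; outputs are byte-identical
for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .engine import FilterConfig, QualifyReason, SatisfactionMode
from .panel import (
    AllelicRequirement,
    Confidence,
    MutationConsequence,
    Panel,
    PanelEntry,
    write_panel_file,
)
from .variants import InclusionLists, TranscriptAnnotation, VariantCall, VarClass, Zygosity

CSQ_FIELDS = ("Allele", "Consequence", "IMPACT", "SYMBOL", "Feature", "CANONICAL", "MAX_AF")
CSQ_DESCRIPTOR = "|".join(CSQ_FIELDS)

SCENARIOS = (
    "hom_lof",
    "compound_het_snv",
    "compound_het_snv_cnv",
    "monoallelic_missense",
    "hemizygous",
    "deep_intronic_splice_flagged",
    "hypomorphic_common",
    "common_noise",
    "vus_noise",
)

# requirement / mechanism / confidence mix; cycled over genes so every enum
# member appears at least once when n_genes >= 8
_GENE_COMBOS = (
    (AllelicRequirement.BIALLELIC, MutationConsequence.LOSS_OF_FUNCTION, Confidence.CONFIRMED),
    (AllelicRequirement.MONOALLELIC, MutationConsequence.ALL_MISSENSE_OR_INFRAME, Confidence.CONFIRMED),
    (AllelicRequirement.HEMIZYGOUS, MutationConsequence.LOSS_OF_FUNCTION, Confidence.CONFIRMED),
    (AllelicRequirement.MONOALLELIC, MutationConsequence.DOMINANT_NEGATIVE, Confidence.PROBABLE),
    (AllelicRequirement.BIALLELIC, MutationConsequence.LOSS_OF_FUNCTION, Confidence.CONFIRMED),
    (AllelicRequirement.MONOALLELIC_AND_BIALLELIC, MutationConsequence.LOSS_OF_FUNCTION, Confidence.POSSIBLE),
    (AllelicRequirement.MITOCHONDRIAL, MutationConsequence.UNCERTAIN, Confidence.PROBABLE),
    (AllelicRequirement.MONOALLELIC, MutationConsequence.ACTIVATING, Confidence.CONFIRMED),
)

_BASES = ("A", "C", "G", "T")
_COMPARTMENTS = ("retina", "lens", "cornea", "vitreous", "optic_nerve", "other")


@dataclass(frozen=True)
class GeneRegion:
    gene: str
    chrom: str
    start: int  # 0-based half-open
    end: int


@dataclass
class PanelFixture:
    panel: Panel
    regions: list[GeneRegion]

    def region_for(self, gene: str) -> GeneRegion:
        for r in self.regions:
            if r.gene == gene:
                return r
        raise KeyError(gene)

    def gene_spans(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for r in self.regions:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.gene)
        return trees

    def bed_lines(self) -> list[str]:
        return [f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}" for r in self.regions]


def make_panel(n_genes: int = 8, seed: int = 7) -> PanelFixture:
    """Build a deterministic toy panel with disjoint gene spans.

    Requirements, mechanisms and confidences cycle over a fixed mix that
    covers every enum member once ``n_genes >= 8``.  Hemizygous genes land
    on the synthetic X contig (chrSX); all others get their own autosomal
    contig.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    entries: list[PanelEntry] = []
    regions: list[GeneRegion] = []
    x_count = 0
    for i in range(1, n_genes + 1):
        requirement, mechanism, confidence = _GENE_COMBOS[(i - 1) % len(_GENE_COMBOS)]
        gene = f"OCG{i}"
        if requirement is AllelicRequirement.HEMIZYGOUS:
            chrom = "chrSX"
            start = 10_000 + x_count * 100_000
            x_count += 1
        else:
            chrom = f"chrS{i}"
            start = 10_000
        regions.append(GeneRegion(gene, chrom, start, start + 50_000))
        entries.append(
            PanelEntry(
                gene_symbol=gene,
                gene_id=f"SGENE{i:05d}",
                disease_name=f"Synthetic ocular disorder {i}",
                allelic_requirement=requirement,
                mutation_consequence=mechanism,
                confidence=confidence,
                phenotype_terms=(f"HP:{int(rng.integers(1, 9_999_999)):07d}",),
                publications=(str(int(rng.integers(10_000_000, 40_000_000))),),
                compartment=None,
            )
        )
    panel = Panel(entries=entries, name="synthetic-ocular", version="1")
    return PanelFixture(panel=panel, regions=regions)


@dataclass
class SimVariant:
    """One record to be written to a synthetic VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gt: str
    consequence: str
    impact: str
    gene: str
    transcript: str
    canonical: bool = True
    af: float | None = None
    end: int | None = None
    svtype: str | None = None
    filter_str: str = "PASS"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def csq(self) -> str:
        af = "" if self.af is None else f"{self.af:.6g}"
        return "|".join(
            [
                self.alt if not self.alt.startswith("<") else self.alt.strip("<>"),
                self.consequence,
                self.impact.upper(),
                self.gene,
                self.transcript,
                "YES" if self.canonical else "",
                af,
            ]
        )

    def vcf_line(self) -> str:
        info = [f"CSQ={self.csq()}"]
        if self.end is not None:
            info.insert(0, f"END={self.end}")
        if self.svtype is not None:
            info.insert(0, f"SVTYPE={self.svtype}")
        return "\t".join(
            [
                self.chrom,
                str(self.pos),
                ".",
                self.ref,
                self.alt,
                "100",
                self.filter_str,
                ";".join(info),
                "GT",
                self.gt,
            ]
        )


@dataclass
class PlantedVariant:
    key: tuple  # (chrom, pos, ref, alt)
    zygosity: str
    expected_reason: str


@dataclass
class SampleTruth:
    """Ground truth for one synthetic individual."""

    sample: str
    scenario: str
    gene: str | None
    requirement: str | None
    mechanism: str | None
    planted: list[PlantedVariant] = field(default_factory=list)
    expected_mode: str = SatisfactionMode.NOT_SATISFIED.value

    @property
    def satisfiable(self) -> bool:
        return self.expected_mode != SatisfactionMode.NOT_SATISFIED.value


@dataclass
class TruthManifest:
    samples: list[SampleTruth] = field(default_factory=list)
    recurrent_artifact_key: tuple | None = None
    seed: int = 0
    noise_rate: float = 0.0

    def truth_for(self, sample: str) -> SampleTruth:
        for t in self.samples:
            if t.sample == sample:
                return t
        raise KeyError(sample)


@dataclass
class CohortFixture:
    """Paths of everything make_cohort wrote, plus the in-memory truth."""

    out_dir: Path
    vcf_paths: dict[str, Path]
    panel_csv: Path
    gene_bed: Path
    known_pathogenic: Path
    splice_flagged: Path
    hypomorphic: Path
    manifest_path: Path
    manifest: TruthManifest


class _KeyPool:
    """Draws fresh variant positions so keys never collide within a VCF."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[tuple] = set()

    def snv(self, region: GeneRegion, *, offset: int | None = None) -> tuple[int, str, str]:
        for _ in range(1000):
            if offset is not None:
                pos = region.start + 1 + offset
                offset = None  # fall back to random draws on collision
            else:
                pos = int(self.rng.integers(region.start + 100, region.end - 100)) + 1
            ref, alt = self.rng.choice(_BASES, size=2, replace=False)
            if (region.chrom, pos, str(ref), str(alt)) not in self.used:
                self.used.add((region.chrom, pos, str(ref), str(alt)))
                return pos, str(ref), str(alt)
        raise RuntimeError("could not draw a fresh variant position")


def _rare_af(rng: np.random.Generator) -> float | None:
    if rng.random() < 0.3:
        return None  # novel allele, absent from population databases
    return float(np.round(rng.uniform(1e-5, 5e-4), 7))


def _plant(
    truth: SampleTruth,
    variants: list[SimVariant],
    pool: _KeyPool,
    region: GeneRegion,
    rng: np.random.Generator,
    *,
    gt: str,
    consequence: str,
    impact: str,
    af: float | None,
    reason: str,
    canonical: bool = True,
) -> SimVariant:
    pos, ref, alt = pool.snv(region)
    sv = SimVariant(
        chrom=region.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gt=gt,
        consequence=consequence,
        impact=impact,
        gene=region.gene,
        transcript=f"ENST_{region.gene}_1",
        canonical=canonical,
        af=af,
    )
    variants.append(sv)
    zyg = {"0/1": "het", "1/1": "hom_alt", "1": "hemizygous"}[gt]
    truth.planted.append(PlantedVariant(key=sv.key, zygosity=zyg, expected_reason=reason))
    return sv


def _entries_matching(
    fixture: PanelFixture,
    requirement: AllelicRequirement,
    mechanism: MutationConsequence | None = None,
) -> list[PanelEntry]:
    out = []
    for e in fixture.panel.expand_requirements().entries:
        if e.allelic_requirement is requirement and (
            mechanism is None or e.mutation_consequence is mechanism
        ):
            out.append(e)
    return out


def make_cohort(
    fixture: PanelFixture,
    n_individuals: int = 10,
    scenarios: Sequence[str] | None = None,
    noise_rate: float = 5.0,
    seed: int = 7,
    out_dir: str | Path = ".",
) -> CohortFixture:
    """Write a synthetic cohort: one VCF per individual with a planted
    scenario plus Poisson(noise_rate) noise variants, the panel CSV, the
    gene-region BED, the three inclusion-list files and a JSON truth
    manifest.

    Noise frequencies straddle the monoallelic (0.001) and biallelic
    (0.05) cut-offs; common-noise individuals receive damaging
    consequences at high frequency so only the frequency filter can block
    them.  The first five eligible individuals additionally share one
    rare, canonical 'recurrent artifact' allele in a panel gene, which a
    cohort-presence filter should remove.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenarios = list(scenarios) if scenarios is not None else list(SCENARIOS)
    unknown = set(scenarios) - set(SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenario(s): {sorted(unknown)}")
    if "hemizygous" in scenarios and not _entries_matching(
        fixture, AllelicRequirement.HEMIZYGOUS
    ):
        raise ValueError("scenario 'hemizygous' requires an X-linked gene in the panel")

    rng = np.random.default_rng(seed)
    manifest = TruthManifest(seed=seed, noise_rate=noise_rate)
    splice_rows: list[tuple] = []
    hypomorphic_rows: list[tuple] = []
    per_sample_variants: dict[str, list[SimVariant]] = {}
    contigs: set[str] = {"chrS0"} | {r.chrom for r in fixture.regions}
    decoy = GeneRegion("DECOY1", "chrS0", 10_000, 60_000)

    planner = _ScenarioPlanner(fixture, rng)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_individuals)]
    for idx, sample in enumerate(sample_ids):
        scenario = scenarios[idx % len(scenarios)]
        pool = _KeyPool(rng)
        truth = SampleTruth(
            sample=sample, scenario=scenario, gene=None, requirement=None, mechanism=None
        )
        variants: list[SimVariant] = []
        planner.plant(scenario, truth, variants, pool, splice_rows, hypomorphic_rows)
        _add_noise(
            variants, pool, fixture, decoy, rng,
            noise_rate=noise_rate, common_only=(scenario == "common_noise"),
        )
        manifest.samples.append(truth)
        per_sample_variants[sample] = variants

    # shared rare artifact to exercise a cohort-presence filter
    artifact_carriers = [
        t.sample
        for t in manifest.samples
        if t.scenario not in ("common_noise", "vus_noise")
    ][:5]
    mono = _entries_matching(
        fixture, AllelicRequirement.MONOALLELIC, MutationConsequence.ACTIVATING
    ) or _entries_matching(fixture, AllelicRequirement.MONOALLELIC)
    if len(artifact_carriers) >= 4 and mono:
        region = fixture.region_for(mono[0].gene_symbol)
        pos = region.start + 51  # fixed site shared across carriers
        ref, alt = "G", "A"
        for sample in artifact_carriers:
            per_sample_variants[sample].append(
                SimVariant(
                    chrom=region.chrom, pos=pos, ref=ref, alt=alt, gt="0/1",
                    consequence="missense_variant", impact="MODERATE",
                    gene=region.gene, transcript=f"ENST_{region.gene}_1",
                    canonical=True, af=2e-4,
                )
            )
        manifest.recurrent_artifact_key = (region.chrom, pos, ref, alt)

    vcf_paths: dict[str, Path] = {}
    for sample in sample_ids:
        path = out_dir / f"{sample}.vcf"
        _write_vcf(path, sample, per_sample_variants[sample], sorted(contigs))
        vcf_paths[sample] = path

    panel_csv = out_dir / "panel.csv"
    write_panel_file(fixture.panel, panel_csv)
    gene_bed = out_dir / "genes.bed"
    gene_bed.write_text("\n".join(fixture.bed_lines()) + "\n")

    known_path = out_dir / "known_pathogenic.tsv"
    # a curated pathogenic allele nobody in the cohort carries: the list
    # machinery is exercised without altering any sample's qualify reasons
    r0 = fixture.regions[0]
    known_path.write_text(
        "chrom\tpos\tref\talt\n" + f"{r0.chrom}\t{r0.end + 5000}\tC\tT\n"
    )
    splice_path = out_dir / "splice_flagged.tsv"
    splice_path.write_text(
        "chrom\tpos\tref\talt\tdelta\n"
        + "".join(f"{c}\t{p}\t{r}\t{a}\t{d}\n" for c, p, r, a, d in splice_rows)
    )
    hypo_path = out_dir / "hypomorphic.tsv"
    hypo_path.write_text(
        "chrom\tpos\tref\talt\n"
        + "".join(f"{c}\t{p}\t{r}\t{a}\n" for c, p, r, a in hypomorphic_rows)
    )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True))

    return CohortFixture(
        out_dir=out_dir,
        vcf_paths=vcf_paths,
        panel_csv=panel_csv,
        gene_bed=gene_bed,
        known_pathogenic=known_path,
        splice_flagged=splice_path,
        hypomorphic=hypo_path,
        manifest_path=manifest_path,
        manifest=manifest,
    )


class _ScenarioPlanner:
    """Chooses a suitable panel entry per scenario and plants its
    genotype, rotating across matching genes so a cohort spreads over the
    panel."""

    def __init__(self, fixture: PanelFixture, rng: np.random.Generator):
        self.fixture = fixture
        self.rng = rng
        self.rotation: dict[str, int] = {}

    def _entry(
        self,
        scenario: str,
        requirement: AllelicRequirement,
        mechanism: MutationConsequence | None = None,
    ) -> PanelEntry:
        matches = _entries_matching(self.fixture, requirement, mechanism)
        if not matches:
            raise ValueError(
                f"scenario {scenario!r} needs a {requirement.value} entry"
                + (f" with {mechanism.value}" if mechanism else "")
            )
        i = self.rotation.get(scenario, 0)
        self.rotation[scenario] = i + 1
        return matches[i % len(matches)]

    def plant(
        self,
        scenario: str,
        truth: SampleTruth,
        variants: list[SimVariant],
        pool: _KeyPool,
        splice_rows: list,
        hypomorphic_rows: list,
    ) -> None:
        fixture, rng = self.fixture, self.rng
        if scenario == "common_noise":
            return
        if scenario == "hom_lof":
            entry = self._entry(scenario, AllelicRequirement.BIALLELIC,
                                MutationConsequence.LOSS_OF_FUNCTION)
            region = fixture.region_for(entry.gene_symbol)
            _plant(truth, variants, pool, region, rng, gt="1/1",
                   consequence="stop_gained", impact="HIGH", af=_rare_af(rng),
                   reason=QualifyReason.CONSEQUENCE.value)
            mode = SatisfactionMode.HOMOZYGOUS
        elif scenario == "compound_het_snv":
            entry = self._entry(scenario, AllelicRequirement.BIALLELIC,
                                MutationConsequence.LOSS_OF_FUNCTION)
            region = fixture.region_for(entry.gene_symbol)
            _plant(truth, variants, pool, region, rng, gt="0/1",
                   consequence="frameshift_variant", impact="HIGH", af=_rare_af(rng),
                   reason=QualifyReason.CONSEQUENCE.value)
            _plant(truth, variants, pool, region, rng, gt="0/1",
                   consequence="missense_variant", impact="MODERATE", af=_rare_af(rng),
                   reason=QualifyReason.CONSEQUENCE.value)
            mode = SatisfactionMode.PUTATIVE_COMPOUND_HET
        elif scenario == "compound_het_snv_cnv":
            entry = self._entry(scenario, AllelicRequirement.BIALLELIC,
                                MutationConsequence.LOSS_OF_FUNCTION)
            region = fixture.region_for(entry.gene_symbol)
            _plant(truth, variants, pool, region, rng, gt="0/1",
                   consequence="frameshift_variant", impact="HIGH", af=_rare_af(rng),
                   reason=QualifyReason.CONSEQUENCE.value)
            # heterozygous exonic deletion: the second allele of the pair
            del_start = region.start + 20_000
            cnv = SimVariant(
                chrom=region.chrom, pos=del_start + 1, ref="N", alt="<DEL>",
                gt="0/1", consequence="feature_truncation", impact="HIGH",
                gene=region.gene, transcript=f"ENST_{region.gene}_1",
                canonical=True, af=None, end=del_start + 8_000, svtype="DEL",
            )
            variants.append(cnv)
            truth.planted.append(
                PlantedVariant(key=cnv.key, zygosity="het",
                               expected_reason=QualifyReason.CONSEQUENCE.value)
            )
            mode = SatisfactionMode.PUTATIVE_COMPOUND_HET
        elif scenario == "monoallelic_missense":
            entry = self._entry(scenario, AllelicRequirement.MONOALLELIC,
                                MutationConsequence.ALL_MISSENSE_OR_INFRAME)
            region = fixture.region_for(entry.gene_symbol)
            _plant(truth, variants, pool, region, rng, gt="0/1",
                   consequence="missense_variant", impact="MODERATE", af=_rare_af(rng),
                   reason=QualifyReason.CONSEQUENCE.value)
            mode = SatisfactionMode.MONOALLELIC_HIT
        elif scenario == "hemizygous":
            entry = self._entry(scenario, AllelicRequirement.HEMIZYGOUS)
            region = fixture.region_for(entry.gene_symbol)
            _plant(truth, variants, pool, region, rng, gt="1",
                   consequence="stop_gained", impact="HIGH", af=_rare_af(rng),
                   reason=QualifyReason.CONSEQUENCE.value)
            mode = SatisfactionMode.HEMIZYGOUS
        elif scenario == "deep_intronic_splice_flagged":
            entry = self._entry(scenario, AllelicRequirement.BIALLELIC)
            region = fixture.region_for(entry.gene_symbol)
            sv = _plant(truth, variants, pool, region, rng, gt="0/1",
                        consequence="intron_variant", impact="MODIFIER", af=None,
                        reason=QualifyReason.SPLICE_FLAGGED.value)
            splice_rows.append((*sv.key, round(float(rng.uniform(0.8, 0.99)), 3)))
            _plant(truth, variants, pool, region, rng, gt="0/1",
                   consequence="stop_gained", impact="HIGH", af=_rare_af(rng),
                   reason=QualifyReason.CONSEQUENCE.value)
            mode = SatisfactionMode.PUTATIVE_COMPOUND_HET
        elif scenario == "hypomorphic_common":
            entry = self._entry(scenario, AllelicRequirement.MONOALLELIC)
            region = fixture.region_for(entry.gene_symbol)
            sv = _plant(truth, variants, pool, region, rng, gt="0/1",
                        consequence="missense_variant", impact="MODERATE",
                        af=round(float(rng.uniform(0.005, 0.04)), 4),
                        reason=QualifyReason.HYPOMORPHIC.value)
            hypomorphic_rows.append(sv.key)
            mode = SatisfactionMode.MONOALLELIC_HIT
        elif scenario == "vus_noise":
            # a lone rare het in a biallelic gene: qualifies but cannot
            # satisfy the requirement, so must not be retained
            entry = self._entry(scenario, AllelicRequirement.BIALLELIC)
            region = fixture.region_for(entry.gene_symbol)
            _plant(truth, variants, pool, region, rng, gt="0/1",
                   consequence="missense_variant", impact="MODERATE", af=_rare_af(rng),
                   reason=QualifyReason.CONSEQUENCE.value)
            mode = SatisfactionMode.NOT_SATISFIED
        else:  # pragma: no cover - guarded by make_cohort
            raise ValueError(scenario)
        truth.gene = entry.gene_symbol
        truth.requirement = entry.allelic_requirement.value
        truth.mechanism = entry.mutation_consequence.value
        truth.expected_mode = mode.value


def _add_noise(
    variants: list[SimVariant],
    pool: _KeyPool,
    fixture: PanelFixture,
    decoy: GeneRegion,
    rng: np.random.Generator,
    *,
    noise_rate: float,
    common_only: bool,
) -> None:
    n_noise = int(rng.poisson(noise_rate))
    all_regions = list(fixture.regions) + [decoy]
    for _ in range(n_noise):
        region = all_regions[int(rng.integers(0, len(all_regions)))]
        pos, ref, alt = pool.snv(region)
        gt = "1/1" if rng.random() < 0.15 else "0/1"
        if common_only:
            # damaging consequence at high frequency: only the frequency
            # filter stands between this allele and retention
            af = round(float(rng.uniform(0.06, 0.5)), 4)
            consequence, impact = ("stop_gained", "HIGH") if rng.random() < 0.5 else (
                "missense_variant", "MODERATE")
        else:
            u = rng.random()
            if u < 0.4:
                af = round(float(rng.uniform(0.06, 0.5)), 4)
            elif u < 0.7:
                af = round(float(rng.uniform(0.002, 0.04)), 5)
            else:
                af = round(float(rng.uniform(1e-5, 5e-4)), 7)
            consequence, impact = ("synonymous_variant", "LOW") if rng.random() < 0.6 else (
                "intron_variant", "MODIFIER")
        variants.append(
            SimVariant(
                chrom=region.chrom, pos=pos, ref=ref, alt=alt, gt=gt,
                consequence=consequence, impact=impact, gene=region.gene,
                transcript=f"ENST_{region.gene}_1",
                canonical=bool(rng.random() < 0.7), af=af,
                filter_str="PASS" if rng.random() < 0.9 else "LowQual",
            )
        )


def _write_vcf(path: Path, sample: str, variants: list[SimVariant], contigs: list[str]) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c},length=1000000>" for c in contigs],
        '##FILTER=<ID=LowQual,Description="Low quality">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        f'##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: {CSQ_DESCRIPTOR}">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for sv in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        lines.append(sv.vcf_line())
    path.write_text("\n".join(lines) + "\n")


def random_engine_inputs(
    rng: np.random.Generator, max_variants: int = 50
) -> tuple[
    list[VariantCall],
    dict[tuple, list[TranscriptAnnotation]],
    Panel,
    InclusionLists,
    FilterConfig,
]:
    """Adversarial in-memory cohort for property testing the filter
    engine: random requirements, mechanisms, zygosities, frequencies and
    inclusion-list memberships over a handful of genes.

    Unlike :func:`make_cohort` this generator makes no attempt to plant
    coherent diagnoses — its purpose is to exercise every branch of the
    qualification and satisfaction logic against an independent oracle.
    """
    n_genes = int(rng.integers(1, 6))
    requirements = [
        r for r in AllelicRequirement if r is not AllelicRequirement.MONOALLELIC_AND_BIALLELIC
    ] + [AllelicRequirement.MONOALLELIC_AND_BIALLELIC]
    entries = []
    for g in range(n_genes):
        entries.append(
            PanelEntry(
                gene_symbol=f"G{g}",
                disease_name=f"disease {g}",
                allelic_requirement=requirements[int(rng.integers(0, len(requirements)))],
                mutation_consequence=list(MutationConsequence)[int(rng.integers(0, 5))],
                confidence=list(Confidence)[int(rng.integers(0, 3))],
            )
        )
    panel = Panel(entries=entries, name="random")
    so_pool = [
        "stop_gained", "missense_variant", "synonymous_variant", "intron_variant",
        "frameshift_variant", "inframe_deletion", "splice_region_variant",
        "stop_lost", "5_prime_UTR_variant",
    ]
    zyg_pool = [Zygosity.HET, Zygosity.HET, Zygosity.HOM_ALT, Zygosity.HEMIZYGOUS]
    n_var = int(rng.integers(0, max_variants + 1))
    calls: list[VariantCall] = []
    annotations: dict[tuple, list[TranscriptAnnotation]] = {}
    lists = InclusionLists()
    for v in range(n_var):
        gene = f"G{int(rng.integers(0, n_genes))}"
        is_cnv = rng.random() < 0.1
        chrom, pos = "chrR1", 1000 + v * 10
        if is_cnv:
            ref, alt = "N", "<DEL>" if rng.random() < 0.8 else "<DUP>"
            var_class = VarClass.CNV_DEL if alt == "<DEL>" else VarClass.CNV_DUP
            end = pos + int(rng.integers(100, 5000))
        else:
            ref, alt = "A", "T"
            var_class = VarClass.SNV
            end = None
        zyg = zyg_pool[int(rng.integers(0, len(zyg_pool)))]
        call = VariantCall(
            chrom=chrom, pos=pos, ref=ref, alt=alt, var_class=var_class,
            zygosity=zyg, sample="R1", end=end,
        )
        calls.append(call)
        af_roll = rng.random()
        if af_roll < 0.25:
            af = None
        elif af_roll < 0.5:
            af = float(rng.uniform(0, 0.0015))
        elif af_roll < 0.75:
            af = float(rng.uniform(0.0015, 0.06))
        else:
            af = float(rng.uniform(0.06, 0.6))
        terms = tuple(
            rng.choice(so_pool, size=int(rng.integers(1, 3)), replace=False)
        )
        annotations[call.key] = [
            TranscriptAnnotation(
                variant_key=call.key, gene_symbol=gene,
                transcript_id=f"T{v}", so_terms=tuple(str(t) for t in terms),
                canonical=bool(rng.random() < 0.8), impact="moderate", max_pop_af=af,
            )
        ]
        roll = rng.random()
        if roll < 0.06:
            lists.known_pathogenic.add(call.key)
        elif roll < 0.12:
            lists.splice_flagged[call.key] = float(rng.uniform(0, 1))
        elif roll < 0.18:
            lists.hypomorphic.add(call.key)
    config = FilterConfig(
        af_monoallelic=float(rng.choice([0.001, 0.0005, 0.005])),
        af_biallelic=float(rng.choice([0.05, 0.01, 0.1])),
        splice_delta_threshold=float(rng.choice([0.2, 0.5, 0.8])),
        canonical_only=bool(rng.random() < 0.3),
        retain_carrier_hets_x=bool(rng.random() < 0.3),
    )
    return calls, annotations, panel, lists, config
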
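"""The panel filter engine: qualification, allelic-requirement
satisfaction, oracle equivalence and monotonicity properties."""

from __future__ import annotations

import numpy as np
import pytest

from oculovar.engine import (
    FilterConfig,
    QualifyReason,
    SatisfactionMode,
    assess_gene,
    consequence_pass,
    frequency_pass,
    inclusion_override,
    prioritise_individual,
    retained_keys,
)
from oculovar.panel import AllelicRequirement, MutationConsequence
from oculovar.variants import InclusionLists, VarClass, Zygosity

from helpers import mk_ann, mk_call, mk_entry, mk_panel
from oracle import brute_force_retained

CFG = FilterConfig()


class TestFrequencyPass:
    @pytest.mark.parametrize(
        "af,requirement,expected",
        [
            (0.0005, AllelicRequirement.MONOALLELIC, True),
            (0.001, AllelicRequirement.MONOALLELIC, True),  # non-strict boundary
            (0.002, AllelicRequirement.MONOALLELIC, False),
            (0.002, AllelicRequirement.BIALLELIC, True),
            (0.05, AllelicRequirement.BIALLELIC, True),
            (0.06, AllelicRequirement.BIALLELIC, False),
            (None, AllelicRequirement.MONOALLELIC, True),  # novel allele passes
            (0.002, AllelicRequirement.HEMIZYGOUS, False),  # monoallelic cut-off
            (0.002, AllelicRequirement.MITOCHONDRIAL, False),
        ],
    )
    def test_thresholds(self, af, requirement, expected):
        call = mk_call()
        ann = mk_ann(call, af=af)
        assert frequency_pass(ann, requirement, CFG) is expected


class TestConsequencePass:
    def test_lof_terms(self):
        call = mk_call()
        entry = mk_entry(mechanism=MutationConsequence.LOSS_OF_FUNCTION)
        assert consequence_pass(mk_ann(call, so_terms=("stop_gained",)), entry, CFG)
        assert not consequence_pass(
            mk_ann(call, so_terms=("synonymous_variant",)), entry, CFG
        )

    def test_missense_mechanism(self):
        call = mk_call()
        entry = mk_entry(mechanism=MutationConsequence.ALL_MISSENSE_OR_INFRAME)
        assert consequence_pass(mk_ann(call, so_terms=("missense_variant",)), entry, CFG)
        assert not consequence_pass(mk_ann(call, so_terms=("stop_gained",)), entry, CFG)

    def test_cnv_del_counts_as_lof(self):
        cnv = mk_call(ref="N", alt="<DEL>", var_class=VarClass.CNV_DEL, end=5000)
        entry = mk_entry(mechanism=MutationConsequence.LOSS_OF_FUNCTION)
        ann = mk_ann(cnv, so_terms=("feature_truncation",))
        assert consequence_pass(ann, entry, CFG, call=cnv)
        # but not for a missense-restricted mechanism
        entry2 = mk_entry(mechanism=MutationConsequence.ALL_MISSENSE_OR_INFRAME)
        assert not consequence_pass(ann, entry2, CFG, call=cnv)


class TestInclusionOverride:
    KEY = ("chr1", 100, "A", "T")

    def test_known_pathogenic_fires(self):
        lists = InclusionLists(known_pathogenic={self.KEY})
        assert inclusion_override(self.KEY, lists, CFG) is QualifyReason.KNOWN_PATHOGENIC

    def test_splice_below_threshold_is_none(self):
        lists = InclusionLists(splice_flagged={self.KEY: 0.3})
        assert inclusion_override(self.KEY, lists, CFG) is None
        lists = InclusionLists(splice_flagged={self.KEY: 0.5})
        assert inclusion_override(self.KEY, lists, CFG) is QualifyReason.SPLICE_FLAGGED

    def test_absent_key_is_none(self):
        assert inclusion_override(self.KEY, InclusionLists(), CFG) is None

    def test_override_bypasses_frequency_and_consequence(self):
        """A common synonymous allele is retained once on the pathogenic list."""
        entry = mk_entry(requirement=AllelicRequirement.MONOALLELIC)
        call = mk_call()
        ann = mk_ann(call, so_terms=("synonymous_variant",), af=0.2)
        lists = InclusionLists(known_pathogenic={call.key})
        res = assess_gene(entry, [(call, ann)], lists, CFG)
        assert res.satisfied
        assert res.qualifying[0][2] is QualifyReason.KNOWN_PATHOGENIC


class TestAssessGene:
    def test_single_het_cannot_satisfy_biallelic(self):
        entry = mk_entry(requirement=AllelicRequirement.BIALLELIC)
        call = mk_call(zygosity=Zygosity.HET)
        res = assess_gene(entry, [(call, mk_ann(call, so_terms=("stop_gained",)))], InclusionLists(), CFG)
        assert not res.satisfied
        assert res.satisfaction_mode is SatisfactionMode.NOT_SATISFIED
        assert len(res.qualifying) == 1  # qualifies, but requirement unmet

    def test_hom_alt_satisfies_biallelic(self):
        entry = mk_entry(requirement=AllelicRequirement.BIALLELIC)
        call = mk_call(zygosity=Zygosity.HOM_ALT)
        res = assess_gene(entry, [(call, mk_ann(call, so_terms=("stop_gained",)))], InclusionLists(), CFG)
        assert res.satisfaction_mode is SatisfactionMode.HOMOZYGOUS

    def test_het_snv_plus_het_cnv_del_is_compound_het(self):
        entry = mk_entry(requirement=AllelicRequirement.BIALLELIC)
        snv = mk_call(pos=100, zygosity=Zygosity.HET)
        cnv = mk_call(
            pos=500, ref="N", alt="<DEL>", var_class=VarClass.CNV_DEL,
            end=2000, zygosity=Zygosity.HET,
        )
        pairs = [
            (snv, mk_ann(snv, so_terms=("frameshift_variant",))),
            (cnv, mk_ann(cnv, so_terms=("feature_truncation",))),
        ]
        res = assess_gene(entry, pairs, InclusionLists(), CFG)
        assert res.satisfaction_mode is SatisfactionMode.PUTATIVE_COMPOUND_HET

    def test_monoallelic_single_het(self):
        entry = mk_entry(requirement=AllelicRequirement.MONOALLELIC)
        call = mk_call(zygosity=Zygosity.HET)
        res = assess_gene(entry, [(call, mk_ann(call, so_terms=("stop_gained",)))], InclusionLists(), CFG)
        assert res.satisfaction_mode is SatisfactionMode.MONOALLELIC_HIT

    def test_duplicate_key_never_counts_twice(self):
        """Two identical het records at one site are one allele."""
        entry = mk_entry(requirement=AllelicRequirement.BIALLELIC)
        call = mk_call(zygosity=Zygosity.HET)
        pairs = [
            (call, mk_ann(call, so_terms=("stop_gained",))),
            (call, mk_ann(call, so_terms=("stop_gained",), transcript="T2")),
        ]
        res = assess_gene(entry, pairs, InclusionLists(), CFG)
        assert not res.satisfied
        assert len(res.qualifying) == 1

    def test_hemizygous_requirement(self):
        entry = mk_entry(requirement=AllelicRequirement.HEMIZYGOUS)
        hemi = mk_call(chrom="chrX", zygosity=Zygosity.HEMIZYGOUS)
        res = assess_gene(entry, [(hemi, mk_ann(hemi, so_terms=("stop_gained",)))], InclusionLists(), CFG)
        assert res.satisfaction_mode is SatisfactionMode.HEMIZYGOUS

    def test_carrier_het_on_x_needs_flag(self):
        entry = mk_entry(requirement=AllelicRequirement.HEMIZYGOUS)
        het = mk_call(chrom="chrX", zygosity=Zygosity.HET)
        pairs = [(het, mk_ann(het, so_terms=("stop_gained",)))]
        assert not assess_gene(entry, pairs, InclusionLists(), CFG).satisfied
        cfg = FilterConfig(retain_carrier_hets_x=True)
        assert assess_gene(entry, pairs, InclusionLists(), cfg).satisfied

    def test_wrong_gene_annotation_is_an_error(self):
        entry = mk_entry(gene="GENE1")
        call = mk_call()
        with pytest.raises(ValueError, match="annotated to"):
            assess_gene(entry, [(call, mk_ann(call, gene="OTHER"))], InclusionLists(), CFG)


class TestPrioritiseIndividual:
    def test_empty_panel_is_an_error(self):
        with pytest.raises(ValueError, match="empty panel"):
            prioritise_individual([], {}, mk_panel(), InclusionLists(), CFG)

    def test_empty_callset_gives_empty_report(self):
        panel = mk_panel(mk_entry())
        assessments, retained = prioritise_individual([], {}, panel, InclusionLists(), CFG)
        assert assessments == [] and retained == []

    def test_common_variants_only_zero_retained(self):
        panel = mk_panel(mk_entry(requirement=AllelicRequirement.MONOALLELIC))
        calls = [mk_call(pos=p) for p in (100, 200)]
        annotations = {
            c.key: [mk_ann(c, so_terms=("stop_gained",), af=0.2)] for c in calls
        }
        _, retained = prioritise_individual(calls, annotations, panel, InclusionLists(), CFG)
        assert retained == []

    def test_report_is_deterministically_ordered(self):
        panel = mk_panel(mk_entry(requirement=AllelicRequirement.MONOALLELIC))
        calls = [mk_call(pos=p) for p in (300, 100, 200)]
        annotations = {c.key: [mk_ann(c, so_terms=("stop_gained",))] for c in calls}
        _, retained = prioritise_individual(calls, annotations, panel, InclusionLists(), CFG)
        assert [r.variant_key[1] for r in retained] == [100, 200, 300]

    def test_monoallelic_and_biallelic_diagnoses_coexist(self):
        panel = mk_panel(
            mk_entry("GDOM", requirement=AllelicRequirement.MONOALLELIC),
            mk_entry("GREC", requirement=AllelicRequirement.BIALLELIC),
        )
        dom = mk_call(pos=100, zygosity=Zygosity.HET)
        rec = mk_call(pos=200, zygosity=Zygosity.HOM_ALT)
        annotations = {
            dom.key: [mk_ann(dom, gene="GDOM", so_terms=("missense_variant",))],
            rec.key: [mk_ann(rec, gene="GREC", so_terms=("stop_gained",))],
        }
        assessments, retained = prioritise_individual(
            [dom, rec], annotations, panel, InclusionLists(), CFG
        )
        satisfied = {a.gene_symbol for a in assessments if a.satisfied}
        assert satisfied == {"GDOM", "GREC"}
        assert len(retained) == 2


class TestOracleEquivalence:
    def test_retained_set_matches_brute_force_on_random_cohorts(self):
        """Engine output equals exhaustive enumeration over 200 random
        small cohorts."""
        from oculovar.simulate import random_engine_inputs

        rng = np.random.default_rng(20260928)
        for _ in range(200):
            calls, annotations, panel, lists, config = random_engine_inputs(rng)
            _, retained = prioritise_individual(calls, annotations, panel, lists, config)
            assert retained_keys(retained) == brute_force_retained(
                calls, annotations, panel, lists, config
            )


class TestMonotonicity:
    def _random_case(self, rng):
        from oculovar.simulate import random_engine_inputs

        return random_engine_inputs(rng, max_variants=30)

    def test_lower_af_thresholds_never_grow_retained_set(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            calls, annotations, panel, lists, config = self._random_case(rng)
            tighter = FilterConfig(
                af_monoallelic=config.af_monoallelic / 2,
                af_biallelic=config.af_biallelic / 2,
                splice_delta_threshold=config.splice_delta_threshold,
                canonical_only=config.canonical_only,
                retain_carrier_hets_x=config.retain_carrier_hets_x,
            )
            _, kept = prioritise_individual(calls, annotations, panel, lists, config)
            _, kept_tight = prioritise_individual(calls, annotations, panel, lists, tighter)
            assert retained_keys(kept_tight) <= retained_keys(kept)

    def test_raising_splice_threshold_never_grows_retained_set(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            calls, annotations, panel, lists, config = self._random_case(rng)
            stricter = FilterConfig(
                af_monoallelic=config.af_monoallelic,
                af_biallelic=config.af_biallelic,
                splice_delta_threshold=min(1.0, config.splice_delta_threshold + 0.3),
                canonical_only=config.canonical_only,
                retain_carrier_hets_x=config.retain_carrier_hets_x,
            )
            _, kept = prioritise_individual(calls, annotations, panel, lists, config)
            _, kept_strict = prioritise_individual(calls, annotations, panel, lists, stricter)
            assert retained_keys(kept_strict) <= retained_keys(kept)

    def test_adding_known_pathogenic_never_removes_variants(self):
        rng = np.random.default_rng(44)
        for _ in range(20):
            calls, annotations, panel, lists, config = self._random_case(rng)
            if not calls:
                continue
            _, before = prioritise_individual(calls, annotations, panel, lists, config)
            extra = calls[int(rng.integers(0, len(calls)))].key
            bigger = InclusionLists(
                known_pathogenic=lists.known_pathogenic | {extra},
                splice_flagged=dict(lists.splice_flagged),
                hypomorphic=set(lists.hypomorphic),
            )
            _, after = prioritise_individual(calls, annotations, panel, lists=bigger, config=config)
            assert retained_keys(before) <= retained_keys(after)


class TestFixtureRecall:
    def test_every_planted_satisfiable_genotype_is_retained(self, cohort, cohort_lists, panel_fixture):
        """100% recall of the truth manifest; common-noise individuals
        yield zero retained variants in their planted gene."""
        from oculovar.workflow import load_individual

        for sample, path in cohort.vcf_paths.items():
            truth = cohort.manifest.truth_for(sample)
            _, calls, annotations = load_individual(path)
            assessments, retained = prioritise_individual(
                calls, annotations, panel_fixture.panel, cohort_lists, FilterConfig()
            )
            keys = retained_keys(retained)
            planted = {tuple(p.key) for p in truth.planted}
            if truth.satisfiable:
                assert planted <= keys, (sample, truth.scenario)
                by_key = {r.variant_key: r for r in retained}
                for p in truth.planted:
                    r = by_key[tuple(p.key)]
                    assert r.qualify_reason.value == p.expected_reason
                    assert r.satisfaction_mode.value == truth.expected_mode
            else:
                assert not (planted & keys), (sample, truth.scenario)

    def test_common_noise_individual_retains_nothing(self, cohort, cohort_lists, panel_fixture):
        from oculovar.workflow import load_individual

        noise_samples = [
            t.sample for t in cohort.manifest.samples if t.scenario == "common_noise"
        ]
        assert noise_samples
        for sample in noise_samples:
            _, calls, annotations = load_individual(cohort.vcf_paths[sample])
            _, retained = prioritise_individual(
                calls, annotations, panel_fixture.panel, cohort_lists, FilterConfig()
            )
            assert retained == []
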
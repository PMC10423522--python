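"""Independent brute-force reference implementations used as oracles.

These deliberately share no code path with the package: qualification is
re-derived pair by pair and allelic-requirement satisfaction is decided by
explicit enumeration of allele combinations.
"""

from __future__ import annotations

from itertools import combinations

from oculovar.panel import AllelicRequirement as AR
from oculovar.panel import MutationConsequence as MC
from oculovar.variants import VarClass, Zygosity


def _pair_qualifies(call, ann, entry, lists, config):
    # inclusion-list overrides, checked in list order
    if call.key in lists.known_pathogenic:
        return True
    if call.key in lists.splice_flagged and (
        lists.splice_flagged[call.key] >= config.splice_delta_threshold
    ):
        return True
    if call.key in lists.hypomorphic:
        return True
    # frequency
    threshold = (
        config.af_biallelic
        if entry.allelic_requirement == AR.BIALLELIC
        else config.af_monoallelic
    )
    if ann.max_pop_af is not None and ann.max_pop_af > threshold:
        return False
    # consequence
    if call.var_class == VarClass.CNV_DEL and entry.mutation_consequence == MC.LOSS_OF_FUNCTION:
        return True
    return len(set(ann.so_terms) & set(config.consequence_map[entry.mutation_consequence])) > 0


def brute_force_retained(calls, annotations, panel, lists, config):
    """Retained variant keys by exhaustive enumeration of every
    (variant, entry) pair and every allele combination."""
    entries = []
    for e in panel.entries:
        if e.allelic_requirement == AR.MONOALLELIC_AND_BIALLELIC:
            from dataclasses import replace

            entries.append(replace(e, allelic_requirement=AR.MONOALLELIC))
            entries.append(replace(e, allelic_requirement=AR.BIALLELIC))
        else:
            entries.append(e)

    retained = set()
    for entry in entries:
        qualifying = {}  # key -> call (deduplicated per allele)
        for call in calls:
            for ann in annotations.get(call.key, ()):
                if ann.gene_symbol != entry.gene_symbol:
                    continue
                if config.canonical_only and not ann.canonical:
                    continue
                if _pair_qualifies(call, ann, entry, lists, config):
                    qualifying[call.key] = call
        qcalls = list(qualifying.values())
        satisfied = False
        if entry.allelic_requirement in (AR.MONOALLELIC, AR.MITOCHONDRIAL):
            satisfied = len(qcalls) >= 1
        elif entry.allelic_requirement == AR.BIALLELIC:
            for c in qcalls:
                if c.zygosity == Zygosity.HOM_ALT:
                    satisfied = True
            for c1, c2 in combinations(qcalls, 2):
                if c1.zygosity == Zygosity.HET and c2.zygosity == Zygosity.HET:
                    satisfied = True
        elif entry.allelic_requirement == AR.HEMIZYGOUS:
            for c in qcalls:
                if c.zygosity in (Zygosity.HEMIZYGOUS, Zygosity.HOM_ALT):
                    satisfied = True
                if c.zygosity == Zygosity.HET and config.retain_carrier_hets_x:
                    satisfied = True
        if satisfied:
            retained |= set(qualifying.keys())
    return retained


def brute_force_signed_rank_p(differences):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    import numpy as np
    from scipy.stats import rankdata

    d = np.asarray([x for x in differences if x != 0], dtype=float)
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = []
    for mask in range(2**n):
        w = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
        sums.append(w)
    sums = np.asarray(sums)
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))
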
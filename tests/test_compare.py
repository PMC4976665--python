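from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq

from emsnv.compare import (
    CATEGORY_SAME,
    CATEGORY_TYPE_I,
    CATEGORY_TYPE_II,
    CATEGORY_TYPE_III,
    ComparisonRecord,
    accounting_summary,
    build_comparison,
    pairwise_strain_effects,
    per_gene_snv_histogram,
)
from emsnv.effect import annotate_all, annotate_variant
from emsnv.io_formats import extract_cds_sequence
from emsnv.models import (
    NONSYN_GROUP,
    EffectClass,
    ReferenceSequence,
    TranscriptModel,
    Variant,
    reverse_complement,
)

BASES = "ACGT"


@pytest.fixture
def long_gene():
    """One plus-strand, single-exon gene: 30 codons, no internal stops."""
    cds = "ATG" + "GCTAGTTGGCATCCCGATCTGAAAGGGCGC" * 3 + "TAA"
    cds = cds[:90]  # 30 codons
    residues = "TTTTT" + cds + "AAAAA"
    ref = ReferenceSequence("chrL", residues)
    model = TranscriptModel("gL", "gL.t1", "chrL", "+", ((5, 95),))
    return ref, model


def _variants(ref, model, positions0, strain, alt_shift=1):
    out = []
    for pos0 in positions0:
        old = ref.residues[pos0]
        alt = BASES[(BASES.index(old) + alt_shift) % 4]
        out.append(Variant(model.seq_id, pos0 + 1, old, alt, strain))
    return out


class TestBuildComparison:
    def test_categories_on_hand_fixture(self, long_gene):
        """6 shared + 2 wt-only + 2 mut-only sites; strain totals 8 and 8."""
        ref, model = long_gene
        refs = {"chrL": ref}
        shared0 = [10, 13, 16, 19, 22, 25]
        wt_only0 = [30, 33]
        mut_only0 = [40, 43]
        wt = _variants(ref, model, shared0 + wt_only0, "wt")
        mut = _variants(ref, model, shared0 + mut_only0, "mut")
        wt_calls = annotate_all(wt, [model], refs).calls
        mut_calls = annotate_all(mut, [model], refs).calls
        records = build_comparison(wt_calls, mut_calls, refs)
        cats = Counter(r.category for r in records)
        assert cats == {CATEGORY_SAME: 6, CATEGORY_TYPE_II: 2,
                        CATEGORY_TYPE_III: 2}
        acc = accounting_summary(wt_calls, mut_calls, "wt", "mut")
        assert acc["wt"].total == 8 and acc["mut"].total == 8
        assert acc["wt"].shared_sum == 6 and acc["mut"].shared_sum == 6
        assert acc["wt"].distinct_ss + acc["wt"].distinct_nss == 2
        assert acc["mut"].distinct_ss + acc["mut"].distinct_nss == 2

    def test_divergent_alt_at_same_site_is_type_one(self, long_gene):
        ref, model = long_gene
        refs = {"chrL": ref}
        wt = _variants(ref, model, [10], "wt", alt_shift=1)
        mut = _variants(ref, model, [10], "mut", alt_shift=2)
        records = build_comparison(
            annotate_all(wt, [model], refs).calls,
            annotate_all(mut, [model], refs).calls,
            refs,
        )
        (rec,) = records
        assert rec.category == CATEGORY_TYPE_I
        assert rec.wt_alt != rec.mut_alt

    def test_empty_mutant_set(self, long_gene):
        ref, model = long_gene
        refs = {"chrL": ref}
        wt_calls = annotate_all(
            _variants(ref, model, [10, 13], "wt"), [model], refs
        ).calls
        records = build_comparison(wt_calls, [], refs)
        assert {r.category for r in records} == {CATEGORY_TYPE_II}
        acc = accounting_summary(wt_calls, [], "wt", "mut")
        assert acc["mut"].total == 0 and acc["wt"].total == 2

    def test_swapping_strains_maps_type_two_to_type_three(self, small_sim):
        cfg, refs, models, wt, mut, truth = small_sim
        ref_by_id = {r.seq_id: r for r in refs}
        wt_calls = annotate_all(wt, models, ref_by_id).calls
        mut_calls = annotate_all(mut, models, ref_by_id).calls
        fwd = Counter(
            r.category for r in build_comparison(wt_calls, mut_calls, ref_by_id)
        )
        rev = Counter(
            r.category for r in build_comparison(mut_calls, wt_calls, ref_by_id)
        )
        assert fwd[CATEGORY_SAME] == rev[CATEGORY_SAME]
        assert fwd[CATEGORY_TYPE_I] == rev[CATEGORY_TYPE_I]
        assert fwd[CATEGORY_TYPE_II] == rev[CATEGORY_TYPE_III]
        assert fwd[CATEGORY_TYPE_III] == rev[CATEGORY_TYPE_II]


class TestAccountingInvariants:
    def test_identities_hold_on_simulated_data(self, small_sim):
        cfg, refs, models, wt, mut, truth = small_sim
        ref_by_id = {r.seq_id: r for r in refs}
        wt_calls = annotate_all(wt, models, ref_by_id).calls
        mut_calls = annotate_all(mut, models, ref_by_id).calls
        for acc in accounting_summary(wt_calls, mut_calls).values():
            assert acc.ss + acc.nss == acc.total
            assert acc.same_ss + acc.distinct_ss == acc.ss
            assert acc.same_nss + acc.distinct_nss == acc.nss
            assert 0.0 <= acc.nss_pct <= 100.0


class TestPairwise:
    def test_same_identical_sites_contribute_nothing(self, long_gene):
        ref, model = long_gene
        refs = {"chrL": ref}
        calls = annotate_all(
            _variants(ref, model, [10, 13], "wt"), [model], refs
        ).calls
        calls_m = annotate_all(
            _variants(ref, model, [10, 13], "mut"), [model], refs
        ).calls
        records = build_comparison(calls, calls_m, refs)
        summary = pairwise_strain_effects(records, [model], refs)
        assert summary.syn_snvs == 0 and summary.nonsyn_snvs == 0

    def test_counts_match_retranslation_oracle(self, small_sim):
        """SNV counts per class equal a brute-force full-CDS re-translation
        of the wildtype-allele and mutant-allele consensus sequences."""
        cfg, refs, models, wt, mut, truth = small_sim
        ref_by_id = {r.seq_id: r for r in refs}
        wt_calls = annotate_all(wt, models, ref_by_id).calls
        mut_calls = annotate_all(mut, models, ref_by_id).calls
        records = build_comparison(wt_calls, mut_calls, ref_by_id)
        summary = pairwise_strain_effects(records, models, ref_by_id)

        from emsnv.models import EFFECT_SEVERITY

        def oracle_effect(rec):
            wt_allele = rec.wt_alt or rec.ref
            mut_allele = rec.mut_alt or rec.ref
            best = None
            for m in models:
                if m.seq_id != rec.seq_id or not m.contains(rec.pos - 1):
                    continue
                positions = m.genomic_positions()
                idx = positions.index(rec.pos - 1)
                ref_seq = ref_by_id[m.seq_id]
                spliced = "".join(
                    ref_seq.residues[a:b] for a, b in m.cds_intervals
                )

                def consensus(allele):
                    s = spliced[:idx] + allele + spliced[idx + 1 :]
                    return reverse_complement(s) if m.strand == "-" else s

                prot_a = str(Seq(consensus(wt_allele)).translate())
                prot_b = str(Seq(consensus(mut_allele)).translate())
                diffs = [i for i, (x, y) in enumerate(zip(prot_a, prot_b))
                         if x != y]
                if not diffs:
                    aa = prot_a[
                        (len(positions) - 1 - idx if m.strand == "-" else idx)
                        // 3
                    ]
                    eff = (EffectClass.STOP_STOP if aa == "*"
                           else EffectClass.SYNONYMOUS)
                else:
                    (i,) = diffs
                    a, b = prot_a[i], prot_b[i]
                    if b == "*":
                        eff = EffectClass.STOP_GAIN
                    elif a == "*":
                        eff = EffectClass.STOP_LOSS
                    else:
                        eff = EffectClass.NON_SYNONYMOUS
                if best is None or EFFECT_SEVERITY[eff] > EFFECT_SEVERITY[best]:
                    best = eff
            return best

        exp_syn = exp_nonsyn = 0
        divergent = [r for r in records if r.category != CATEGORY_SAME]
        assert len(divergent) <= 200
        for rec in divergent:
            eff = oracle_effect(rec)
            assert eff is not None
            if eff in NONSYN_GROUP:
                exp_nonsyn += 1
            else:
                exp_syn += 1
        assert summary.nonsyn_snvs == exp_nonsyn
        assert summary.syn_snvs == exp_syn
        # partition invariant over divergent sites
        assert (summary.syn_snvs + summary.nonsyn_snvs
                + summary.n_untranslatable == len(divergent))


class TestHistogram:
    def test_basic_counts(self, long_gene):
        ref, model = long_gene
        refs = {"chrL": ref}
        m2 = TranscriptModel("g2", "g2.t1", "chrL", "+", ((5, 95),))
        m3 = TranscriptModel("g3", "g3.t1", "chrL", "+", ((5, 95),))
        calls = []
        for model_i, pos_list in ((model, [10]), (m2, [13]), (m3, [16, 19])):
            vs = _variants(ref, model_i, pos_list, "wt")
            for v in vs:
                calls.extend(annotate_variant(v, [model_i], refs))
        hist = per_gene_snv_histogram(calls)
        assert hist == {1: 2, 2: 1}

    def test_effect_restriction_drops_synonymous_only_genes(self, long_gene):
        ref, model = long_gene
        refs = {"chrL": ref}
        # CDS offset 8 is codon AGT position 3: T->C is synonymous
        syn_pos0 = 5 + 8
        v = Variant("chrL", syn_pos0 + 1, ref.residues[syn_pos0], "C", "wt")
        calls = annotate_variant(v, [model], refs)
        assert calls[0].effect == EffectClass.SYNONYMOUS
        assert per_gene_snv_histogram(calls, by_effect=True) == {}
        assert per_gene_snv_histogram(calls, by_effect=False) == {1: 1}

    def test_total_equals_mutated_gene_count_in_truth(self, small_sim):
        cfg, refs, models, wt, mut, truth = small_sim
        ref_by_id = {r.seq_id: r for r in refs}
        calls = annotate_all(wt + mut, models, ref_by_id).calls
        hist = per_gene_snv_histogram(calls)
        assert sum(hist.values()) == len(truth.per_gene_mutations)


class TestComparisonRecordInvariants:
    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError):
            ComparisonRecord("s", 1, "C", "T", "G", CATEGORY_SAME,
                             EffectClass.SYNONYMOUS, EffectClass.SYNONYMOUS)
        with pytest.raises(ValueError):
            ComparisonRecord("s", 1, "C", "T", "A", CATEGORY_TYPE_II,
                             EffectClass.SYNONYMOUS, None)
        with pytest.raises(ValueError):
            ComparisonRecord("s", 1, "C", "T", "T", CATEGORY_TYPE_I,
                             EffectClass.SYNONYMOUS, EffectClass.SYNONYMOUS)
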
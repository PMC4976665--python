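"""Joint classification of SNV sites across the wildtype and mutant strains.

Each reference site carrying a variant in either strain is typed:

* ``same_identical`` — both strains carry the same alt allele;
* ``typeI`` — both strains are mutated at the position but to different
  alleles;
* ``typeII`` — only the wildtype diverges from the reference;
* ``typeIII`` — only the mutant diverges (the EMS-specific class).

From the typed records the module builds the strain accounting table
(totals, synonymous vs non-synonymous group counts split into shared vs
strain-distinct positions, multi-SNV counts), the pairwise strain-vs-
strain effect summary, and the per-gene SNV histogram.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from .effect import classify_effect, collect_sites, map_to_cds
from .io_formats import extract_cds_sequence
from .models import (
    COMPLEMENT,
    NONSYN_GROUP,
    EffectCall,
    EffectClass,
    ReferenceSequence,
    SiteAnnotation,
    TranscriptModel,
)

CATEGORY_SAME = "same_identical"
CATEGORY_TYPE_I = "typeI_same_site_divergent_alt"
CATEGORY_TYPE_II = "typeII_wt_only"
CATEGORY_TYPE_III = "typeIII_mut_only"


@dataclass(frozen=True)
class ComparisonRecord:
    """One reference site jointly classified across the two strains."""

    seq_id: str
    pos: int
    ref: str
    wt_alt: str | None
    mut_alt: str | None
    category: str
    wt_effect: EffectClass | None
    mut_effect: EffectClass | None

    def __post_init__(self) -> None:
        if self.category == CATEGORY_TYPE_II and self.mut_alt is not None:
            raise ValueError("typeII record must have no mutant allele")
        if self.category == CATEGORY_TYPE_III and self.wt_alt is not None:
            raise ValueError("typeIII record must have no wildtype allele")
        if self.category == CATEGORY_SAME and self.wt_alt != self.mut_alt:
            raise ValueError("same_identical record must share the alt allele")
        if self.category == CATEGORY_TYPE_I and (
            self.wt_alt is None or self.mut_alt is None or self.wt_alt == self.mut_alt
        ):
            raise ValueError("typeI record needs two divergent alt alleles")


@dataclass(frozen=True)
class StrainAccounting:
    """One strain's row of the SNV accounting table.

    ``ss``/``nss`` split the strain's coding SNVs into the synonymous
    group (synonymous + stop-stop) and the amino-acid-changing group
    (non-synonymous + stop-gain + stop-loss); each is further split into
    sites whose position is shared with the other strain ("same") versus
    strain-distinct. Totals and percentages are derived, never stored.
    """

    strain: str
    ss: int
    nss: int
    same_ss: int
    same_nss: int
    distinct_ss: int
    distinct_nss: int
    multi: int

    @property
    def total(self) -> int:
        return self.ss + self.nss

    @property
    def nss_pct(self) -> float:
        return 100.0 * self.nss / self.total if self.total else 0.0

    @property
    def shared_sum(self) -> int:
        return self.same_ss + self.same_nss

    def validate(self) -> None:
        if self.same_ss + self.distinct_ss != self.ss:
            raise AssertionError("same_ss + distinct_ss != ss")
        if self.same_nss + self.distinct_nss != self.nss:
            raise AssertionError("same_nss + distinct_nss != nss")


@dataclass(frozen=True)
class PairwiseSummary:
    """Mutant-vs-wildtype substitution accounting (SNV and gene counts)."""

    syn_snvs: int
    nonsyn_snvs: int
    syn_genes: int
    nonsyn_genes: int
    genes_both: int
    n_untranslatable: int = 0

    def __post_init__(self) -> None:
        if self.genes_both > min(self.syn_genes, self.nonsyn_genes):
            raise AssertionError("genes_both exceeds a class gene count")


def _sites_by_position(
    sites: list[SiteAnnotation],
) -> dict[tuple[str, int], dict[str, SiteAnnotation]]:
    out: dict[tuple[str, int], dict[str, SiteAnnotation]] = defaultdict(dict)
    for s in sites:
        out[(s.seq_id, s.pos)][s.alt] = s
    return out


def build_comparison(
    wt_calls: list[EffectCall],
    mut_calls: list[EffectCall],
    reference: dict[str, ReferenceSequence],
) -> list[ComparisonRecord]:
    """Type every coding site present in either strain.

    A site with several alt alleles within one strain yields one record
    per allele; divergent leftover alleles of the two strains are paired
    into typeI records.
    """
    wt_pos = _sites_by_position(collect_sites(wt_calls))
    mut_pos = _sites_by_position(collect_sites(mut_calls))
    records = []
    for key in sorted(set(wt_pos) | set(mut_pos)):
        seq_id, pos = key
        ref_base = reference[seq_id].residues[pos - 1]
        wt_alts = wt_pos.get(key, {})
        mut_alts = mut_pos.get(key, {})
        shared = sorted(set(wt_alts) & set(mut_alts))
        wt_only = sorted(set(wt_alts) - set(mut_alts))
        mut_only = sorted(set(mut_alts) - set(wt_alts))
        for alt in shared:
            records.append(
                ComparisonRecord(
                    seq_id=seq_id, pos=pos, ref=ref_base,
                    wt_alt=alt, mut_alt=alt, category=CATEGORY_SAME,
                    wt_effect=wt_alts[alt].primary_effect,
                    mut_effect=mut_alts[alt].primary_effect,
                )
            )
        n_pairs = min(len(wt_only), len(mut_only))
        for wa, ma in zip(wt_only[:n_pairs], mut_only[:n_pairs]):
            records.append(
                ComparisonRecord(
                    seq_id=seq_id, pos=pos, ref=ref_base,
                    wt_alt=wa, mut_alt=ma, category=CATEGORY_TYPE_I,
                    wt_effect=wt_alts[wa].primary_effect,
                    mut_effect=mut_alts[ma].primary_effect,
                )
            )
        for wa in wt_only[n_pairs:]:
            records.append(
                ComparisonRecord(
                    seq_id=seq_id, pos=pos, ref=ref_base,
                    wt_alt=wa, mut_alt=None, category=CATEGORY_TYPE_II,
                    wt_effect=wt_alts[wa].primary_effect, mut_effect=None,
                )
            )
        for ma in mut_only[n_pairs:]:
            records.append(
                ComparisonRecord(
                    seq_id=seq_id, pos=pos, ref=ref_base,
                    wt_alt=None, mut_alt=ma, category=CATEGORY_TYPE_III,
                    wt_effect=None, mut_effect=mut_alts[ma].primary_effect,
                )
            )
    return records


def accounting_summary(
    wt_calls: list[EffectCall],
    mut_calls: list[EffectCall],
    wt_strain: str = "wildtype",
    mut_strain: str = "mutant",
) -> dict[str, StrainAccounting]:
    """Per-strain SNV accounting keyed by strain name.

    Each strain's sites (one per (seq_id, pos, alt)) are labelled by their
    primary effect class and split by whether the *position* also carries
    a variant in the other strain ("same" columns); typeI sites therefore
    count as shared in both strains, each under its own effect.
    """
    out = {}
    wt_sites = collect_sites(wt_calls)
    mut_sites = collect_sites(mut_calls)
    wt_positions = {(s.seq_id, s.pos) for s in wt_sites}
    mut_positions = {(s.seq_id, s.pos) for s in mut_sites}
    for strain, sites, other_positions in (
        (wt_strain, wt_sites, mut_positions),
        (mut_strain, mut_sites, wt_positions),
    ):
        same_ss = same_nss = distinct_ss = distinct_nss = multi = 0
        for s in sites:
            nonsyn = s.primary_effect in NONSYN_GROUP
            shared = (s.seq_id, s.pos) in other_positions
            if nonsyn:
                same_nss += shared
                distinct_nss += not shared
            else:
                same_ss += shared
                distinct_ss += not shared
            multi += s.is_multi
        acc = StrainAccounting(
            strain=strain,
            ss=same_ss + distinct_ss,
            nss=same_nss + distinct_nss,
            same_ss=same_ss,
            same_nss=same_nss,
            distinct_ss=distinct_ss,
            distinct_nss=distinct_nss,
            multi=multi,
        )
        acc.validate()
        out[strain] = acc
    return out


def _pairwise_site_effect(
    seq_id: str,
    pos: int,
    allele_a: str,
    allele_b: str,
    models: list[TranscriptModel],
    reference: dict[str, ReferenceSequence],
    cds_cache: dict[str, str],
) -> tuple[EffectClass, set[str]] | None:
    """Most severe effect of substituting allele_a -> allele_b at a site,
    evaluated in the reference codon context of each containing transcript.
    Returns None when no transcript yields a translatable codon."""
    from .models import EFFECT_SEVERITY

    best: EffectClass | None = None
    genes: set[str] = set()
    for m in models:
        if m.seq_id != seq_id or not m.contains(pos - 1):
            continue
        from .models import Variant

        probe = Variant(seq_id=seq_id, pos=pos, ref=allele_a, alt=allele_b,
                        strain="_pairwise")
        offset = map_to_cds(probe, m)
        if offset is None:
            continue
        if m.transcript_id not in cds_cache:
            cds_cache[m.transcript_id] = extract_cds_sequence(
                m, reference[seq_id]
            )
        coding = cds_cache[m.transcript_id][m.phase :]
        codon_start = (offset // 3) * 3
        if codon_start + 3 > len(coding):
            continue
        ref_codon = coding[codon_start : codon_start + 3]
        if "N" in ref_codon:
            continue
        i = offset % 3
        if m.strand == "-":
            a = allele_a.translate(COMPLEMENT)
            b = allele_b.translate(COMPLEMENT)
        else:
            a, b = allele_a, allele_b
        codon_a = ref_codon[:i] + a + ref_codon[i + 1 :]
        codon_b = ref_codon[:i] + b + ref_codon[i + 1 :]
        eff = classify_effect(codon_a, codon_b)
        genes.add(m.gene_id)
        if best is None or EFFECT_SEVERITY[eff] > EFFECT_SEVERITY[best]:
            best = eff
    if best is None:
        return None
    return best, genes


def pairwise_strain_effects(
    records: list[ComparisonRecord],
    models: list[TranscriptModel],
    reference: dict[str, ReferenceSequence],
) -> PairwiseSummary:
    """Mutant-vs-wildtype substitution summary over divergent sites.

    For every site where the strains' effective alleles differ (typeI,
    typeII, typeIII — the reference allele stands in for an absent call),
    the substitution wildtype-allele -> mutant-allele is classified in the
    reference codon context and tallied as SNV and distinct-gene counts
    per effect group.
    """
    by_seq: dict[str, list[TranscriptModel]] = defaultdict(list)
    for m in models:
        by_seq[m.seq_id].append(m)
    cds_cache: dict[str, str] = {}
    syn_snvs = nonsyn_snvs = untranslatable = 0
    syn_genes: set[str] = set()
    nonsyn_genes: set[str] = set()
    for rec in records:
        if rec.category == CATEGORY_SAME:
            continue
        wt_allele = rec.wt_alt if rec.wt_alt is not None else rec.ref
        mut_allele = rec.mut_alt if rec.mut_alt is not None else rec.ref
        result = _pairwise_site_effect(
            rec.seq_id, rec.pos, wt_allele, mut_allele,
            by_seq.get(rec.seq_id, []), reference, cds_cache,
        )
        if result is None:
            untranslatable += 1
            continue
        effect, genes = result
        if effect in NONSYN_GROUP:
            nonsyn_snvs += 1
            nonsyn_genes |= genes
        else:
            syn_snvs += 1
            syn_genes |= genes
    return PairwiseSummary(
        syn_snvs=syn_snvs,
        nonsyn_snvs=nonsyn_snvs,
        syn_genes=len(syn_genes),
        nonsyn_genes=len(nonsyn_genes),
        genes_both=len(syn_genes & nonsyn_genes),
        n_untranslatable=untranslatable,
    )


def per_gene_snv_histogram(
    calls: list[EffectCall], by_effect: bool = False
) -> dict[int, int]:
    """Histogram mapping (number of SNV sites in a gene) -> (gene count).

    With ``by_effect`` only amino-acid-changing calls are counted, so
    genes carrying purely synonymous variation drop out.
    """
    sites_per_gene: dict[str, set[tuple[str, int, str]]] = defaultdict(set)
    for c in calls:
        if by_effect and c.effect not in NONSYN_GROUP:
            continue
        v = c.variant
        sites_per_gene[c.gene_id].add((v.seq_id, v.pos, v.alt))
    return dict(Counter(len(s) for s in sites_per_gene.values()))


# ---------------------------------------------------------------------------
# report tables


def comparison_to_frame(records: list[ComparisonRecord]) -> pd.DataFrame:
    rows = [
        {
            "seq_id": r.seq_id,
            "pos": r.pos,
            "ref": r.ref,
            "wt_alt": r.wt_alt or ".",
            "mut_alt": r.mut_alt or ".",
            "category": r.category,
            "wt_effect": str(r.wt_effect) if r.wt_effect else ".",
            "mut_effect": str(r.mut_effect) if r.mut_effect else ".",
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["seq_id", "pos", "ref", "wt_alt", "mut_alt", "category",
                 "wt_effect", "mut_effect"],
    )


def accounting_to_frame(summary: dict[str, StrainAccounting]) -> pd.DataFrame:
    rows = []
    for acc in summary.values():
        rows.append(
            {
                "strain": acc.strain,
                "total": acc.total,
                "ss": acc.ss,
                "nss": acc.nss,
                "nss_pct": round(acc.nss_pct, 2),
                "same_ss": acc.same_ss,
                "same_nss": acc.same_nss,
                "distinct_ss": acc.distinct_ss,
                "distinct_nss": acc.distinct_nss,
                "multi_snvs": acc.multi,
            }
        )
    return pd.DataFrame(rows)


def pairwise_to_frame(summary: PairwiseSummary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metric": ["snv_counts", "gene_counts"],
            "synonymous": [summary.syn_snvs, summary.syn_genes],
            "non_synonymous": [summary.nonsyn_snvs, summary.nonsyn_genes],
            "both_classes": [0, summary.genes_both],
        }
    )


def histogram_to_frame(hist: dict[int, int]) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(hist.items()), columns=["n_snvs", "n_genes"]
    )
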
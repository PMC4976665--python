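"""Codon-level effect annotation of SNVs against transcript models.

Each variant falling inside a transcript's CDS is placed into that
transcript's codon frame and classified into one of five effect classes:
synonymous, non-synonymous, stop-gain, stop-loss, stop-stop. A single
reference site can yield several calls when transcripts overlap (e.g.
isoforms in different frames); a site whose calls mix synonymous with an
amino-acid-changing class is flagged as a multi-SNV site.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import extract_cds_sequence
from .models import (
    CODON_TABLE,
    COMPLEMENT,
    EffectCall,
    EffectClass,
    ReferenceSequence,
    SiteAnnotation,
    TranscriptModel,
    Variant,
)

logger = logging.getLogger(__name__)


def classify_effect(ref_codon: str, alt_codon: str) -> EffectClass:
    """Classify a single-base codon substitution.

    Stop categories take precedence over the synonymous / non-synonymous
    split: both stops -> stop_stop, gained stop -> stop_gain, lost stop
    -> stop_loss; otherwise identical amino acids -> synonymous, else
    non_synonymous.
    """
    if ref_codon == alt_codon:
        raise ValueError("codons are identical")
    if sum(a != b for a, b in zip(ref_codon, alt_codon)) != 1:
        raise ValueError(f"codons {ref_codon}/{alt_codon} differ at >1 position")
    ref_aa = CODON_TABLE[ref_codon]
    alt_aa = CODON_TABLE[alt_codon]
    if ref_aa == "*" and alt_aa == "*":
        return EffectClass.STOP_STOP
    if alt_aa == "*":
        return EffectClass.STOP_GAIN
    if ref_aa == "*":
        return EffectClass.STOP_LOSS
    if ref_aa == alt_aa:
        return EffectClass.SYNONYMOUS
    return EffectClass.NON_SYNONYMOUS


def map_to_cds(variant: Variant, model: TranscriptModel) -> int | None:
    """Offset of a variant within a transcript's spliced coding sequence.

    Returns ``None`` when the position is outside every CDS interval.
    Minus-strand offsets count from the 3' genomic end of the spliced
    CDS, so offset 0 is always the first coding-strand base. The
    transcript ``phase`` is then subtracted; positions upstream of the
    first complete codon also return ``None``.
    """
    if variant.seq_id != model.seq_id:
        return None
    pos0 = variant.pos0
    preceding = 0
    for start, end in model.cds_intervals:
        if start <= pos0 < end:
            plus_offset = preceding + (pos0 - start)
            if model.strand == "-":
                offset = model.cds_length - 1 - plus_offset
            else:
                offset = plus_offset
            offset -= model.phase
            return offset if offset >= 0 else None
        preceding += end - start
    return None


@dataclass
class AnnotationResult:
    """Effect calls for one strain plus the exclusion tallies."""

    calls: list[EffectCall] = field(default_factory=list)
    n_outside_cds: int = 0
    n_incomplete_codon: int = 0
    n_ambiguous_context: int = 0  # codon context containing N

    @property
    def sites(self) -> list[SiteAnnotation]:
        return collect_sites(self.calls)


def annotate_variant(
    variant: Variant,
    models: list[TranscriptModel],
    reference: dict[str, ReferenceSequence],
    cds_cache: dict[str, str] | None = None,
) -> list[EffectCall]:
    """Effect calls for one variant across all transcripts containing it.

    ``cds_cache`` maps transcript_id -> extracted coding sequence and is
    filled lazily; pass a shared dict when annotating many variants.
    """
    calls = []
    for model in models:
        offset = map_to_cds(variant, model)
        if offset is None:
            continue
        if cds_cache is not None and model.transcript_id in cds_cache:
            cds = cds_cache[model.transcript_id]
        else:
            cds = extract_cds_sequence(model, reference[model.seq_id])
            if cds_cache is not None:
                cds_cache[model.transcript_id] = cds
        coding = cds[model.phase :]
        codon_index = offset // 3
        codon_start = codon_index * 3
        if codon_start + 3 > len(coding):
            continue  # incomplete terminal codon, tallied by caller
        ref_codon = coding[codon_start : codon_start + 3]
        if "N" in ref_codon:
            continue  # ambiguous context, tallied by caller
        codon_pos = offset % 3 + 1
        if model.strand == "-":
            cref = variant.ref.translate(COMPLEMENT)
            calt = variant.alt.translate(COMPLEMENT)
        else:
            cref, calt = variant.ref, variant.alt
        assert ref_codon[codon_pos - 1] == cref, (
            f"reference base mismatch at {variant.seq_id}:{variant.pos} "
            f"in {model.transcript_id}"
        )
        alt_codon = (
            ref_codon[: codon_pos - 1] + calt + ref_codon[codon_pos:]
        )
        calls.append(
            EffectCall(
                variant=variant,
                gene_id=model.gene_id,
                transcript_id=model.transcript_id,
                cds_offset=offset,
                codon_index=codon_index,
                codon_pos=codon_pos,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                ref_aa=CODON_TABLE[ref_codon],
                alt_aa=CODON_TABLE[alt_codon],
                effect=classify_effect(ref_codon, alt_codon),
                coding_strand_ref=cref,
                coding_strand_alt=calt,
            )
        )
    return calls


def annotate_all(
    variants: list[Variant],
    models: list[TranscriptModel],
    reference: dict[str, ReferenceSequence],
) -> AnnotationResult:
    """Annotate a strain's variant set against all transcript models."""
    by_seq: dict[str, list[TranscriptModel]] = defaultdict(list)
    for m in models:
        by_seq[m.seq_id].append(m)
    cds_cache: dict[str, str] = {}
    result = AnnotationResult()
    for v in variants:
        candidates = by_seq.get(v.seq_id, [])
        containing = [m for m in candidates if m.contains(v.pos0)]
        if not containing:
            result.n_outside_cds += 1
            continue
        calls = annotate_variant(v, containing, reference, cds_cache)
        if calls:
            result.calls.extend(calls)
        else:
            # inside CDS but no call: incomplete codon, N context or phase
            ambiguous = False
            for m in containing:
                cds = cds_cache.get(m.transcript_id) or extract_cds_sequence(
                    m, reference[m.seq_id]
                )
                off = map_to_cds(v, m)
                if off is not None:
                    start = (off // 3) * 3
                    if "N" in cds[m.phase :][start : start + 3]:
                        ambiguous = True
            if ambiguous:
                result.n_ambiguous_context += 1
            else:
                result.n_incomplete_codon += 1
    return result


def collect_sites(calls: list[EffectCall]) -> list[SiteAnnotation]:
    """Group effect calls into per-(seq_id, pos, alt) site annotations."""
    sites: dict[tuple[str, int, str], SiteAnnotation] = {}
    for call in calls:
        v = call.variant
        key = (v.seq_id, v.pos, v.alt)
        if key not in sites:
            sites[key] = SiteAnnotation(seq_id=v.seq_id, pos=v.pos, alt=v.alt)
        sites[key].calls.append(call)
    return list(sites.values())


def detect_multi(site: SiteAnnotation) -> bool:
    """Multi-SNV flag: the site's calls contain a synonymous effect and an
    amino-acid-changing effect in different coding contexts."""
    return site.is_multi


def calls_to_frame(calls: list[EffectCall]) -> pd.DataFrame:
    """Flatten effect calls into the annotated-call report table."""
    sites = {s.site_key: s.is_multi for s in collect_sites(calls)}
    rows = []
    for c in calls:
        v = c.variant
        rows.append(
            {
                "seq_id": v.seq_id,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "strain": v.strain,
                "gene_id": c.gene_id,
                "transcript_id": c.transcript_id,
                "cds_offset": c.cds_offset,
                "codon_index": c.codon_index,
                "codon_pos": c.codon_pos,
                "ref_codon": c.ref_codon,
                "alt_codon": c.alt_codon,
                "ref_aa": c.ref_aa,
                "alt_aa": c.alt_aa,
                "effect": str(c.effect),
                "is_multi": sites[(v.seq_id, v.pos, v.alt)],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id", "pos", "ref", "alt", "strain", "gene_id", "transcript_id",
            "cds_offset", "codon_index", "codon_pos", "ref_codon", "alt_codon",
            "ref_aa", "alt_aa", "effect", "is_multi",
        ],
    )
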
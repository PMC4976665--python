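"""Substitution-spectrum, codon-position, GC-content and positional statistics.

EMS alkylates guanine, so an EMS-derived line is expected to show a
substitution spectrum dominated by C->T and G->A transitions, a consensus
GC content below its progenitor's, and (like any coding variation
surviving in a transcriptome) a characteristic codon-position profile.
This module measures those quantities from annotated effect calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import extract_cds_sequence
from .models import (
    TRANSITIONS,
    VALID_BASES,
    EffectCall,
    ReferenceSequence,
    TranscriptModel,
    Variant,
)

SUBSTITUTIONS = tuple(
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
)  # 12 ordered pairs


@dataclass
class SpectrumTable:
    """Counts of the 12 ordered substitutions plus codon-position tallies."""

    counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {s: 0 for s in SUBSTITUTIONS}
    )
    codon_position: tuple[int, int, int] = (0, 0, 0)
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def transitions(self) -> int:
        return sum(self.counts[s] for s in SUBSTITUTIONS if s in TRANSITIONS)

    @property
    def transversions(self) -> int:
        return self.total - self.transitions

    @property
    def ts_fraction(self) -> float:
        return self.transitions / self.total if self.total else 0.0

    @property
    def ts_tv_ratio(self) -> float:
        return (
            self.transitions / self.transversions
            if self.transversions
            else float("inf")
        )


def substitution_spectrum(
    calls: list[EffectCall], strand_mode: str = "reference"
) -> SpectrumTable:
    """Tally the 12 ordered substitutions over a strain's effect calls.

    ``strand_mode='reference'`` counts the VCF alleles as written;
    ``'coding'`` counts the strand-adjusted alleles, so a reference G->A
    in a minus-strand transcript is tallied as C->T.
    """
    if strand_mode not in ("reference", "coding"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    table = SpectrumTable()
    pos_counts = [0, 0, 0]
    seen: set[tuple] = set()
    for c in calls:
        v = c.variant
        key = (v.seq_id, v.pos, v.alt, c.transcript_id)
        if key in seen:
            continue
        seen.add(key)
        if strand_mode == "coding":
            pair = (c.coding_strand_ref, c.coding_strand_alt)
        else:
            pair = (v.ref, v.alt)
        if pair[0] not in VALID_BASES or pair[1] not in VALID_BASES:
            table.n_excluded += 1
            continue
        table.counts[pair] += 1
        pos_counts[c.codon_pos - 1] += 1
    table.codon_position = tuple(pos_counts)
    return table


def codon_position_counts(calls: list[EffectCall]) -> tuple[int, int, int]:
    """How many calls hit the first, second and third codon position."""
    out = [0, 0, 0]
    for c in calls:
        out[c.codon_pos - 1] += 1
    return tuple(out)


def strain_gc_content(
    models: list[TranscriptModel],
    reference: dict[str, ReferenceSequence],
    variants: list[Variant],
) -> float:
    """GC fraction of a strain's consensus coding sequences.

    The consensus is every transcript's reference CDS with the strain's
    alt alleles substituted at their genomic positions. GC is strand
    symmetric, so substitution happens before any reverse complementing.
    """
    alts: dict[tuple[str, int], str] = {}
    for v in variants:
        alts[(v.seq_id, v.pos0)] = v.alt
    gc = total = 0
    for m in models:
        ref = reference[m.seq_id]
        for start, end in m.cds_intervals:
            for pos0 in range(start, end):
                base = alts.get((m.seq_id, pos0), ref.residues[pos0])
                if base in "GC":
                    gc += 1
                if base != "N":
                    total += 1
    return gc / total if total else 0.0


@dataclass
class PositionalProfile:
    """Per-bin fraction of mutations along gene bodies (5'->3')."""

    n_bins: int
    bin_counts: list[int]

    @property
    def total(self) -> int:
        return sum(self.bin_counts)

    @property
    def fractions(self) -> list[float]:
        t = self.total
        return [c / t for c in self.bin_counts] if t else [0.0] * self.n_bins


def positional_profile(
    calls: list[EffectCall],
    models: dict[str, TranscriptModel] | list[TranscriptModel],
    n_bins: int = 20,
) -> PositionalProfile:
    """Distribution of calls along the coding sequence in ``n_bins`` bins.

    Bin index is ``floor(n_bins * cds_offset / coding_length)``, clamped
    to the final bin, so offset 0 maps to bin 0 and the last coding base
    to bin n_bins-1.
    """
    if not isinstance(models, dict):
        models = {m.transcript_id: m for m in models}
    counts = [0] * n_bins
    for c in calls:
        length = models[c.transcript_id].coding_length
        b = min(n_bins * c.cds_offset // length, n_bins - 1)
        counts[b] += 1
    return PositionalProfile(n_bins=n_bins, bin_counts=counts)


def unpaired_t_test(
    sample_a: list[float] | np.ndarray, sample_b: list[float] | np.ndarray
) -> tuple[float, float, float]:
    """Two-sided Welch unpaired t-test: returns (t, df, p).

    Uses the unequal-variance form with Welch-Satterthwaite degrees of
    freedom. Two zero-variance samples with equal means yield t=0, p=1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return float("inf"), float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    na, nb = a.size, b.size
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def per_gene_transition_fractions(calls: list[EffectCall]) -> dict[str, float]:
    """Fraction of each gene's SNVs that are transitions (reference strand).

    Genes with at least one counted site contribute one fraction; this is
    the per-gene quantity the strain-vs-strain unpaired t-test compares.
    """
    ts: dict[str, int] = {}
    tot: dict[str, int] = {}
    seen: set[tuple] = set()
    for c in calls:
        v = c.variant
        key = (c.gene_id, v.seq_id, v.pos, v.alt)
        if key in seen:
            continue
        seen.add(key)
        tot[c.gene_id] = tot.get(c.gene_id, 0) + 1
        ts[c.gene_id] = ts.get(c.gene_id, 0) + v.is_transition
    return {g: ts.get(g, 0) / n for g, n in tot.items()}


# ---------------------------------------------------------------------------
# report tables


def spectrum_to_frame(tables: dict[str, SpectrumTable]) -> pd.DataFrame:
    rows = []
    for (a, b) in SUBSTITUTIONS:
        row = {"substitution": f"{a}>{b}"}
        for strain, t in tables.items():
            row[strain] = t.counts[(a, b)]
        rows.append(row)
    for label, attr in (
        ("transitions", "transitions"),
        ("transversions", "transversions"),
        ("ts_fraction", "ts_fraction"),
    ):
        row = {"substitution": label}
        for strain, t in tables.items():
            row[strain] = getattr(t, attr)
        rows.append(row)
    for i in range(3):
        row = {"substitution": f"codon_pos_{i + 1}"}
        for strain, t in tables.items():
            row[strain] = t.codon_position[i]
        rows.append(row)
    return pd.DataFrame(rows)


def profile_to_frame(profiles: dict[str, PositionalProfile]) -> pd.DataFrame:
    n_bins = next(iter(profiles.values())).n_bins
    rows = []
    for b in range(n_bins):
        row = {"bin": b + 1}
        for strain, p in profiles.items():
            row[f"{strain}_count"] = p.bin_counts[b]
            row[f"{strain}_fraction"] = p.fractions[b]
        rows.append(row)
    return pd.DataFrame(rows)
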
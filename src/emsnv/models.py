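"""Core domain types for the mutant-vs-wildtype SNV pipeline.

Coordinates are 0-based half-open internally; the VCF/GFF3 surfaces keep
their native 1-based conventions and are converted exactly once, at read
time. All sequence data is uppercase DNA over {A, C, G, T, N}.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGT")
REFERENCE_ALPHABET = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Standard nuclear genetic code, codon -> one-letter amino acid ('*' = stop).
CODON_TABLE: dict[str, str] = {}
_BASES = "TCAG"
_AAS = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AAS[16 * _i + 4 * _j + _k]

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
START_CODON = "ATG"

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})
#: EMS signature on the reference forward strand.
EMS_PAIRS = frozenset({("C", "T"), ("G", "A")})


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a coding-strand DNA string; trailing partial codon ignored."""
    return "".join(
        CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3)
    )


class EffectClass(str, enum.Enum):
    """The five coding-effect categories assigned to a codon substitution."""

    SYNONYMOUS = "synonymous"
    NON_SYNONYMOUS = "non_synonymous"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    STOP_STOP = "stop_stop"

    def __str__(self) -> str:  # keeps TSV serialization terse
        return self.value


#: Severity used to pick one primary call per site (higher = more severe).
EFFECT_SEVERITY = {
    EffectClass.STOP_GAIN: 4,
    EffectClass.STOP_LOSS: 3,
    EffectClass.NON_SYNONYMOUS: 2,
    EffectClass.STOP_STOP: 1,
    EffectClass.SYNONYMOUS: 0,
}

#: Grouping of the five classes into the two-way split used by the
#: strain accounting tables: stop->stop leaves the protein unchanged and
#: is grouped with synonymous; premature/lost stops change it.
NONSYN_GROUP = frozenset(
    {EffectClass.NON_SYNONYMOUS, EffectClass.STOP_GAIN, EffectClass.STOP_LOSS}
)
SYN_GROUP = frozenset({EffectClass.SYNONYMOUS, EffectClass.STOP_STOP})


@dataclass(frozen=True)
class ReferenceSequence:
    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.seq_id!r}")
        bad = set(self.residues) - REFERENCE_ALPHABET
        if bad:
            raise ValueError(
                f"illegal residues {sorted(bad)} in sequence {self.seq_id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's CDS footprint on one reference sequence.

    ``cds_intervals`` are 0-based half-open, non-overlapping, sorted by
    start and stored in genomic order regardless of strand. ``phase`` is
    the offset of the first complete codon within the spliced coding
    sequence (0-2).
    """

    gene_id: str
    transcript_id: str
    seq_id: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.phase <= 2:
            raise ValueError(f"phase must be 0-2, got {self.phase}")
        ivs = tuple(tuple(iv) for iv in self.cds_intervals)
        object.__setattr__(self, "cds_intervals", ivs)
        prev_end = -1
        for start, end in ivs:
            if start >= end:
                raise ValueError(f"{self.transcript_id}: empty interval {start, end}")
            if start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: intervals overlap or are unsorted"
                )
            prev_end = end
        if self.cds_length < 3:
            raise ValueError(f"{self.transcript_id}: spliced CDS shorter than 3")

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)

    @property
    def coding_length(self) -> int:
        """Length of the in-frame coding sequence (phase trimmed)."""
        return self.cds_length - self.phase

    def contains(self, pos0: int) -> bool:
        """True if 0-based reference position falls inside a CDS interval."""
        return any(start <= pos0 < end for start, end in self.cds_intervals)

    def genomic_positions(self) -> list[int]:
        """All CDS reference positions in genomic (ascending) order."""
        out: list[int] = []
        for start, end in self.cds_intervals:
            out.extend(range(start, end))
        return out


@dataclass(frozen=True)
class Variant:
    """A single-base substitution in VCF convention (1-based ``pos``)."""

    seq_id: str
    pos: int
    ref: str
    alt: str
    strain: str

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"non-ACGT allele at {self.seq_id}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.seq_id}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def site(self) -> tuple[str, int]:
        return (self.seq_id, self.pos)

    @property
    def is_transition(self) -> bool:
        return (self.ref, self.alt) in TRANSITIONS


@dataclass(frozen=True)
class EffectCall:
    """One variant interpreted in one transcript's codon frame."""

    variant: Variant
    gene_id: str
    transcript_id: str
    cds_offset: int
    codon_index: int
    codon_pos: int  # 1, 2 or 3 within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: EffectClass
    coding_strand_ref: str
    coding_strand_alt: str

    def __post_init__(self) -> None:
        if self.ref_codon[self.codon_pos - 1] != self.coding_strand_ref:
            raise ValueError("ref codon inconsistent with coding-strand ref allele")
        diffs = [i for i in range(3) if self.ref_codon[i] != self.alt_codon[i]]
        if diffs != [self.codon_pos - 1]:
            raise ValueError("alt codon must differ exactly at codon_pos")
        if CODON_TABLE[self.ref_codon] != self.ref_aa:
            raise ValueError("ref_aa inconsistent with codon table")


@dataclass
class SiteAnnotation:
    """All effect calls at one (seq_id, pos, alt) site for one strain."""

    seq_id: str
    pos: int
    alt: str
    calls: list[EffectCall] = field(default_factory=list)

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.seq_id, self.pos, self.alt)

    @property
    def is_multi(self) -> bool:
        """A multi-SNV site: synonymous in one coding context, amino-acid
        changing (non-synonymous / stop-gain / stop-loss) in another."""
        effects = {c.effect for c in self.calls}
        return EffectClass.SYNONYMOUS in effects and bool(effects & NONSYN_GROUP)

    @property
    def primary_effect(self) -> EffectClass | None:
        if not self.calls:
            return None
        return max((c.effect for c in self.calls), key=EFFECT_SEVERITY.__getitem__)

    @property
    def gene_ids(self) -> set[str]:
        return {c.gene_id for c in self.calls}
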
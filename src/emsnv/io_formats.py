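"""Readers and writers for the standard formats the pipeline touches.

FASTA parsing goes through Biopython, GFF3 through gffutils (in-memory
database), VCF reading through pysam. Counts tables are plain TSV with a
header row, handled by pandas. All conversions between the 1-based file
conventions and the package's 0-based half-open internal coordinates
happen here and nowhere else.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

from .models import (
    REFERENCE_ALPHABET,
    VALID_BASES,
    ReferenceSequence,
    TranscriptModel,
    Variant,
)

logger = logging.getLogger(__name__)

STAGES = ("7", "14", "21", "28", "35", "mature")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a FASTA file into :class:`ReferenceSequence` records.

    Sequences are uppercased (soft-masked bases included); residues
    outside {A,C,G,T,N} raise :class:`FormatError`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - REFERENCE_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: sequence {rec.id!r} contains illegal residues {sorted(bad)}"
            )
        try:
            records.append(ReferenceSequence(seq_id=rec.id, residues=residues))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ReferenceSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_cds_annotation(path: str | Path) -> list[TranscriptModel]:
    """Read gene/mRNA/CDS features from a GFF3 file.

    Returns one :class:`TranscriptModel` per mRNA with at least one CDS.
    GFF 1-based inclusive coordinates become 0-based half-open; CDS of
    minus-strand transcripts stay in genomic order. CDS features whose
    Parent cannot be resolved are skipped with a warning; overlapping CDS
    intervals within one transcript raise :class:`FormatError`.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    mrna_ids = set()
    for mrna in db.features_of_type("mRNA"):
        mrna_ids.add(mrna.id)
        cds_list = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds_list:
            continue
        intervals = tuple((c.start - 1, c.end) for c in cds_list)
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        phase_attr = cds_list[0].frame if mrna.strand == "+" else cds_list[-1].frame
        phase = int(phase_attr) if phase_attr not in (None, ".", "") else 0
        try:
            models.append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=mrna.id,
                    seq_id=mrna.seqid,
                    strand=mrna.strand,
                    cds_intervals=intervals,
                    phase=phase,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: transcript {mrna.id!r}: {exc}") from exc
    # orphan CDS: parent attribute pointing at nothing we loaded
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or not any(p in mrna_ids for p in parents):
            logger.warning("skipping CDS at %s:%s-%s with unresolvable parent",
                           cds.seqid, cds.start, cds.end)
    return models


def write_gff3(models: list[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as gene/mRNA/CDS GFF3 features."""
    by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    for m in models:
        by_gene[m.gene_id].append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, txs in by_gene.items():
            gstart = min(iv[0] for t in txs for iv in t.cds_intervals) + 1
            gend = max(iv[1] for t in txs for iv in t.cds_intervals)
            seq_id, strand = txs[0].seq_id, txs[0].strand
            fh.write(
                f"{seq_id}\temsnv\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for t in txs:
                tstart = t.cds_intervals[0][0] + 1
                tend = t.cds_intervals[-1][1]
                fh.write(
                    f"{seq_id}\temsnv\tmRNA\t{tstart}\t{tend}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene_id}\n"
                )
                # per-interval frame so round-trip preserves phase
                offsets = _interval_phases(t)
                for (start, end), frame in zip(t.cds_intervals, offsets):
                    fh.write(
                        f"{seq_id}\temsnv\tCDS\t{start + 1}\t{end}\t.\t{t.strand}\t"
                        f"{frame}\t"
                        f"ID={t.transcript_id}.cds;Parent={t.transcript_id}\n"
                    )


def _interval_phases(t: TranscriptModel) -> list[int]:
    """GFF phase column for each interval, in genomic order."""
    phases = [0] * len(t.cds_intervals)
    order = range(len(t.cds_intervals))
    if t.strand == "-":
        order = reversed(order)
    consumed = 0
    first = True
    for i in order:
        start, end = t.cds_intervals[i]
        if first:
            phases[i] = t.phase
            consumed = (end - start) - t.phase
            first = False
        else:
            phases[i] = (3 - consumed % 3) % 3
            consumed += end - start
    return phases


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: str | Path,
    strain: str,
    reference: dict[str, ReferenceSequence] | None = None,
) -> list[Variant]:
    """Read SNVs from a VCF 4.x file, labelling each with ``strain``.

    Multi-allelic records are split into one :class:`Variant` per alt;
    indels and symbolic alleles are skipped (count logged). When
    ``reference`` is given, every REF allele is checked against it and a
    mismatch raises.
    """
    variants = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES \
                        or alt not in VALID_BASES:
                    skipped += 1
                    continue
                if reference is not None:
                    refseq = reference.get(rec.chrom)
                    if refseq is None:
                        raise FormatError(
                            f"{path}: unknown sequence {rec.chrom!r} at pos {rec.pos}"
                        )
                    expected = refseq.residues[rec.pos - 1]
                    if expected != ref:
                        raise FormatError(
                            f"{path}: REF {ref!r} at {rec.chrom}:{rec.pos} "
                            f"disagrees with reference base {expected!r}"
                        )
                variants.append(
                    Variant(seq_id=rec.chrom, pos=rec.pos, ref=ref, alt=alt,
                            strain=strain)
                )
    if skipped:
        logger.info("%s: skipped %d non-SNV allele(s)", path, skipped)
    return variants


def write_vcf(
    variants: list[Variant],
    reference: list[ReferenceSequence],
    path: str | Path,
    source: str = "emsnv",
) -> None:
    """Write SNVs as a minimal plain-text VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for rec in reference:
            fh.write(f"##contig=<ID={rec.seq_id},length={len(rec)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.seq_id, v.pos, v.alt)):
            fh.write(f"{v.seq_id}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# CDS extraction


def extract_cds_sequence(model: TranscriptModel, ref: ReferenceSequence) -> str:
    """Spliced coding-strand CDS sequence (5'->3') of one transcript."""
    if model.seq_id != ref.seq_id:
        raise ValueError(
            f"transcript {model.transcript_id} is on {model.seq_id!r}, "
            f"not {ref.seq_id!r}"
        )
    for start, end in model.cds_intervals:
        if start < 0 or end > len(ref):
            raise ValueError(
                f"transcript {model.transcript_id}: interval ({start},{end}) "
                f"outside sequence of length {len(ref)}"
            )
    seq = "".join(ref.residues[s:e] for s, e in model.cds_intervals)
    if model.strand == "-":
        from .models import reverse_complement

        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# Counts tables


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-gene expression counts table.

    Expected TSV layout: first column ``gene_id``, remaining columns named
    ``<strain>_<stage>`` with stage in {7,14,21,28,35,mature}. Returns a
    DataFrame indexed by gene_id with a (strain, stage) column MultiIndex.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = []
    for col in df.columns:
        strain, _, stage = col.rpartition("_")
        if not strain or stage not in STAGES:
            raise FormatError(
                f"{path}: column {col!r} is not of the form <strain>_<stage> "
                f"with stage in {STAGES}"
            )
        cols.append((strain, stage))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["strain", "stage"])
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative counts present")
    strains = df.columns.get_level_values("strain").unique()
    for strain in strains:
        have = set(df[strain].columns)
        used = {s for s in STAGES if any(s in set(df[x].columns) for x in strains)}
        missing = used - have
        if missing:
            raise FormatError(
                f"{path}: strain {strain!r} is missing stage column(s) "
                f"{sorted(missing)}"
            )
    return df


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    flat = table.copy()
    flat.columns = [f"{s}_{t}" for s, t in table.columns]
    flat.to_csv(path, sep="\t", index_label="gene_id")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a report table with fixed 6-significant-digit float format."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
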
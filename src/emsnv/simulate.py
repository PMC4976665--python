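"""Synthetic EMS-mutagenesis datasets with recorded ground truth.

The generator emulates the data the comparison pipeline consumes: a
reference transcriptome (one scaffold per gene, single- or two-exon CDS
on either strand), a wildtype cultivar carrying ancestral divergence
from the reference with an unbiased substitution spectrum, and an
EMS-derived mutant line carrying the wildtype variants plus EMS-specific
variants heavily biased toward C->T / G->A transitions on the reference
strand. A configurable fraction of ancestral sites diverges between the
strains (typeI) or is lost from the mutant (typeII), so all four
comparison categories are exercised. Expression counts over the six
grain developmental stages follow a Poisson model with a designated set
of differentially expressed genes.

Every random draw flows from one :class:`numpy.random.Generator`, so a
fixed seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    STAGES,
    write_counts,
    write_fasta,
    write_gff3,
    write_vcf,
)
from .models import (
    CODON_TABLE,
    STOP_CODONS,
    ReferenceSequence,
    TranscriptModel,
    Variant,
    reverse_complement,
)

_NON_STOP_CODONS = sorted(set(CODON_TABLE) - STOP_CODONS)
_STOP_LIST = sorted(STOP_CODONS)
_FLANK = 30  # untranslated scaffold padding either side of the gene


@dataclass
class SimConfig:
    """Parameters of the synthetic mutagenesis experiment.

    Rates are per CDS base. ``ems_bias`` is the probability that an EMS
    event is a reference-strand C->T or G->A transition (EMS alkylates
    guanine, so real spectra sit near 1); the remainder is a uniform
    non-EMS-type substitution. ``wt_mut_rate`` models the ancestral
    divergence of the wildtype cultivar from the reference assembly.
    """

    n_genes: int = 300
    cds_length: int = 900  # bases, multiple of 3
    cds_length_range: tuple[int, int] | None = None  # optional (min, max)
    gc_target: float = 0.5
    n_isoform_genes: int = 20
    two_exon_fraction: float = 0.4
    intron_length: int = 60
    wt_mut_rate: float = 0.004
    ems_rate: float = 0.002
    ems_bias: float = 0.9
    type1_fraction: float = 0.02  # ancestral sites re-mutated in the mutant
    type2_fraction: float = 0.05  # ancestral sites absent from the mutant
    n_diff_genes: int = 30
    true_logfc: float = 2.0
    count_mean: float = 100.0
    n_terms: int = 20
    wt_name: str = "wildtype"
    mut_name: str = "mutant"
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.wt_mut_rate, self.ems_rate, self.ems_bias,
                  self.type1_fraction, self.type2_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates and fractions must lie in [0, 1]")
        if self.cds_length % 3 or self.cds_length < 30:
            raise ValueError("cds_length must be a multiple of 3, >= 30")
        if self.cds_length_range is not None:
            lo, hi = self.cds_length_range
            if lo % 3 or hi % 3 or lo < 30 or hi < lo:
                raise ValueError("cds_length_range must be multiples of 3, >= 30")


@dataclass
class SimTruth:
    """Ground truth of one simulated lineage pair."""

    variants: pd.DataFrame = field(default_factory=pd.DataFrame)
    category_counts: dict[str, int] = field(default_factory=dict)
    per_gene_mutations: dict[str, int] = field(default_factory=dict)
    diff_genes: dict[str, float] = field(default_factory=dict)

    @property
    def n_ems(self) -> int:
        if self.variants.empty:
            return 0
        return int((self.variants["origin"] == "ems").sum())


# ---------------------------------------------------------------------------
# reference generation


def _codon_probs(gc_target: float) -> np.ndarray:
    pg = gc_target / 2.0
    pa = (1.0 - gc_target) / 2.0
    base_p = {"A": pa, "T": pa, "G": pg, "C": pg}
    w = np.array(
        [base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in _NON_STOP_CODONS]
    )
    return w / w.sum()


def _random_cds(
    rng: np.random.Generator,
    length: int,
    gc_target: float,
    avoid_shifted_stops: bool,
) -> str:
    """Coding sequence: ATG start, stop end, no internal stops in frame 0;
    optionally no stops in the +1 reading frame either (isoform genes)."""
    probs = _codon_probs(gc_target)
    n_codons = length // 3
    idx = rng.choice(len(_NON_STOP_CODONS), size=n_codons - 2, p=probs)
    codons = ["ATG"] + [_NON_STOP_CODONS[i] for i in idx]
    if avoid_shifted_stops:
        # forward pass: resample any codon whose junction with its
        # predecessor forms a stop in the +1 frame
        for k in range(1, len(codons)):
            while codons[k - 1][1:] + codons[k][0] in STOP_CODONS:
                j = rng.choice(len(_NON_STOP_CODONS), p=probs)
                codons[k] = _NON_STOP_CODONS[j]
    # stop codons start with T and the junction codon xyT is never a stop,
    # so any stop is safe for the shifted frame
    codons.append(_STOP_LIST[rng.integers(len(_STOP_LIST))])
    return "".join(codons)


def _random_bases(rng: np.random.Generator, n: int, gc_target: float) -> str:
    pg = gc_target / 2.0
    pa = (1.0 - gc_target) / 2.0
    return "".join(
        rng.choice(np.array(list("ACGT")), size=n, p=[pa, pg, pg, pa])
    )


def generate_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[ReferenceSequence], list[TranscriptModel]]:
    """Build the reference transcriptome: one scaffold per gene.

    Primary transcripts are named ``<gene>.t1``; the first
    ``n_isoform_genes`` genes additionally carry a second, +1-frame-
    shifted isoform ``<gene>.t2`` (single-exon genes only), which is what
    makes multi-SNV sites possible downstream.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    refs: list[ReferenceSequence] = []
    models: list[TranscriptModel] = []
    max_retries = 50
    for i in range(config.n_genes):
        gene_id = f"gene{i + 1:04d}"
        seq_id = f"scaffold{i + 1:04d}"
        has_isoform = i < config.n_isoform_genes
        if config.cds_length_range is not None:
            lo, hi = config.cds_length_range
            length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        else:
            length = config.cds_length
        for attempt in range(max_retries):
            cds = _random_cds(rng, length, config.gc_target, has_isoform)
            gc = (cds.count("G") + cds.count("C")) / len(cds)
            if abs(gc - config.gc_target) <= 0.1:
                break
        else:
            raise RuntimeError(
                f"could not reach GC target {config.gc_target} "
                f"within {max_retries} draws"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        two_exon = (not has_isoform) and rng.random() < config.two_exon_fraction

        genomic_cds = cds if strand == "+" else reverse_complement(cds)
        left = _random_bases(rng, _FLANK, config.gc_target)
        right = _random_bases(rng, _FLANK, config.gc_target)
        if two_exon:
            # split the genomic CDS footprint at a random interior point
            split = int(rng.integers(3, len(genomic_cds) - 3))
            intron = _random_bases(rng, config.intron_length, config.gc_target)
            residues = left + genomic_cds[:split] + intron + genomic_cds[split:] + right
            iv1 = (_FLANK, _FLANK + split)
            iv2 = (
                _FLANK + split + config.intron_length,
                _FLANK + split + config.intron_length + len(genomic_cds) - split,
            )
            intervals: tuple[tuple[int, int], ...] = (iv1, iv2)
        else:
            residues = left + genomic_cds + right
            intervals = ((_FLANK, _FLANK + len(genomic_cds)),)

        refs.append(ReferenceSequence(seq_id=seq_id, residues=residues))
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                seq_id=seq_id,
                strand=strand,
                cds_intervals=intervals,
            )
        )
        if has_isoform:
            start, end = intervals[0]
            if strand == "+":
                iso = ((start + 1, end - 2),)
            else:
                iso = ((start + 2, end - 1),)
            models.append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t2",
                    seq_id=seq_id,
                    strand=strand,
                    cds_intervals=iso,
                )
            )
    return refs, models


# ---------------------------------------------------------------------------
# lineage simulation


def simulate_lineages(
    reference: list[ReferenceSequence],
    models: list[TranscriptModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Variant], list[Variant], SimTruth]:
    """Draw the wildtype and mutant variant sets plus ground truth.

    Ancestral variants (rate ``wt_mut_rate``, uniform spectrum) go to
    both strains; per ancestral site, with probability ``type1_fraction``
    the mutant carries a different alt, or with ``type2_fraction`` the
    site is dropped from the mutant. EMS variants (rate ``ems_rate``,
    C->T/G->A with probability ``ems_bias``) are mutant-only; draws
    colliding with an occupied site are rejected and resampled.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ref_by_id = {r.seq_id: r for r in reference}
    gene_of_seq = {}
    positions: list[tuple[str, int]] = []  # (seq_id, pos0) over primary CDS
    for m in models:
        if not m.transcript_id.endswith(".t1"):
            continue
        gene_of_seq[m.seq_id] = m.gene_id
        positions.extend((m.seq_id, p) for p in m.genomic_positions())
    n_pos = len(positions)

    def base_at(site: tuple[str, int]) -> str:
        return ref_by_id[site[0]].residues[site[1]]

    def uniform_alt(ref_base: str, exclude: set[str] = frozenset()) -> str:
        choices = [b for b in "ACGT" if b != ref_base and b not in exclude]
        return choices[rng.integers(len(choices))]

    # ancestral divergence, shared by construction
    n_anc = rng.binomial(n_pos, config.wt_mut_rate)
    anc_idx = rng.choice(n_pos, size=n_anc, replace=False)
    occupied: set[tuple[str, int]] = set()
    truth_rows = []
    wt_variants: list[Variant] = []
    mut_variants: list[Variant] = []
    n_same = n_t1 = n_t2 = 0
    for idx in sorted(anc_idx):
        site = positions[idx]
        occupied.add(site)
        ref_base = base_at(site)
        wt_alt = uniform_alt(ref_base)
        u = rng.random()
        if u < config.type1_fraction:
            mut_alt: str | None = uniform_alt(ref_base, exclude={wt_alt})
            category = "typeI"
            n_t1 += 1
        elif u < config.type1_fraction + config.type2_fraction:
            mut_alt = None
            category = "typeII"
            n_t2 += 1
        else:
            mut_alt = wt_alt
            category = "same"
            n_same += 1
        wt_variants.append(
            Variant(site[0], site[1] + 1, ref_base, wt_alt, config.wt_name)
        )
        if mut_alt is not None:
            mut_variants.append(
                Variant(site[0], site[1] + 1, ref_base, mut_alt, config.mut_name)
            )
        truth_rows.append(
            {
                "seq_id": site[0], "pos": site[1] + 1, "ref": ref_base,
                "wt_alt": wt_alt, "mut_alt": mut_alt or ".",
                "origin": "ancestral", "category": category,
                "gene_id": gene_of_seq[site[0]],
            }
        )

    # EMS events, mutant-specific
    n_ems = rng.binomial(n_pos, config.ems_rate)
    free = [s for s in positions if s not in occupied]
    free_cg = [s for s in free if base_at(s) in "CG"]
    n_t3 = 0
    for _ in range(n_ems):
        if rng.random() < config.ems_bias:
            pool = free_cg
            if not pool:
                raise RuntimeError("no free C/G sites left for EMS draw")
            while True:
                site = pool[rng.integers(len(pool))]
                if site not in occupied:
                    break
            ref_base = base_at(site)
            mut_alt = "T" if ref_base == "C" else "A"
        else:
            while True:
                site = free[rng.integers(len(free))]
                if site not in occupied:
                    break
            ref_base = base_at(site)
            ems_like = {"C": "T", "G": "A"}.get(ref_base)
            mut_alt = uniform_alt(
                ref_base, exclude={ems_like} if ems_like else set()
            )
        occupied.add(site)
        n_t3 += 1
        mut_variants.append(
            Variant(site[0], site[1] + 1, ref_base, mut_alt, config.mut_name)
        )
        truth_rows.append(
            {
                "seq_id": site[0], "pos": site[1] + 1, "ref": ref_base,
                "wt_alt": ".", "mut_alt": mut_alt,
                "origin": "ems", "category": "typeIII",
                "gene_id": gene_of_seq[site[0]],
            }
        )

    truth_df = pd.DataFrame(
        truth_rows,
        columns=["seq_id", "pos", "ref", "wt_alt", "mut_alt", "origin",
                 "category", "gene_id"],
    )
    per_gene = (
        truth_df.groupby("gene_id").size().to_dict() if len(truth_df) else {}
    )
    truth = SimTruth(
        variants=truth_df,
        category_counts={
            "same": n_same, "typeI": n_t1, "typeII": n_t2, "typeIII": n_t3
        },
        per_gene_mutations=per_gene,
    )
    return wt_variants, mut_variants, truth


# ---------------------------------------------------------------------------
# expression counts


def simulate_counts(
    gene_ids: list[str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Six-stage Poisson expression counts for both strains.

    Per-gene baseline means are Gamma(5, count_mean/5) distributed (mean
    ``count_mean``, moderate spread); the first ``n_diff_genes`` genes
    get their mutant mean scaled by 2**(+-true_logfc) across all stages,
    with a random sign per gene. Returns the counts table and the signed
    true logFC per differential gene.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    means = rng.gamma(shape=5.0, scale=config.count_mean / 5.0, size=len(gene_ids))
    diff: dict[str, float] = {}
    data = {}
    mut_scale = np.ones(len(gene_ids))
    for i in range(min(config.n_diff_genes, len(gene_ids))):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lfc = sign * config.true_logfc
        diff[gene_ids[i]] = lfc
        mut_scale[i] = 2.0 ** lfc
    for stage in STAGES:
        data[(config.wt_name, stage)] = rng.poisson(means)
        data[(config.mut_name, stage)] = rng.poisson(means * mut_scale)
    table = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    table.columns = pd.MultiIndex.from_tuples(
        table.columns, names=["strain", "stage"]
    )
    return table, diff


def simulate_gene2term(
    gene_ids: list[str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Random gene->term annotation map (n_terms terms, ~10% coverage each)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    rows = []
    covered: set[str] = set()
    for t in range(config.n_terms):
        term_id = f"TERM:{t + 1:04d}"
        size = max(2, rng.binomial(len(gene_ids), 0.1))
        for g in rng.choice(len(gene_ids), size=min(size, len(gene_ids)),
                            replace=False):
            rows.append(
                {"gene_id": gene_ids[g], "term_id": term_id,
                 "term_name": f"synthetic term {t + 1}"}
            )
            covered.add(gene_ids[g])
    # every gene carries at least one term so the annotation map can serve
    # as the default enrichment background
    for gene in gene_ids:
        if gene not in covered:
            t = int(rng.integers(config.n_terms))
            rows.append(
                {"gene_id": gene, "term_id": f"TERM:{t + 1:04d}",
                 "term_name": f"synthetic term {t + 1}"}
            )
    return (
        pd.DataFrame(rows)
        .drop_duplicates(["gene_id", "term_id"])
        .sort_values(["term_id", "gene_id"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# dataset orchestration


def simulate_dataset(config: SimConfig, outdir: str | Path) -> SimTruth:
    """Generate and write a complete dataset into ``outdir``.

    Files: reference.fasta, annotation.gff3, wildtype.vcf, mutant.vcf,
    counts.tsv, gene2term.tsv, truth.tsv, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    refs, models = generate_reference(config, rng)
    wt, mut, truth = simulate_lineages(refs, models, config, rng)
    gene_ids = sorted({m.gene_id for m in models})
    counts, diff = simulate_counts(gene_ids, config, rng)
    truth.diff_genes = diff
    g2t = simulate_gene2term(gene_ids, config, rng)

    write_fasta(refs, outdir / "reference.fasta")
    write_gff3(models, outdir / "annotation.gff3")
    write_vcf(wt, refs, outdir / "wildtype.vcf", source="emsnv-simulate")
    write_vcf(mut, refs, outdir / "mutant.vcf", source="emsnv-simulate")
    write_counts(counts, outdir / "counts.tsv")
    g2t.to_csv(outdir / "gene2term.tsv", sep="\t", index=False)
    truth.variants.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest = {
        "config": dataclasses.asdict(config),
        "category_counts": truth.category_counts,
        "n_diff_genes": len(diff),
        "diff_genes": diff,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return truth
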
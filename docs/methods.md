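# Methods

## Problem setting and assumptions

The package compares transcriptome SNV calls from two related plant
lines — a wildtype cultivar and an EMS-mutagenized derivative — both
called against one shared reference. It assumes:

* variants are single-base substitutions, present/absent per strain
  (pooled libraries; no zygosity, phasing or allele-frequency model);
* both strains' VCFs use the same reference sequences, and every REF
  allele is validated against the loaded FASTA at read time;
* coding annotation comes as gene/mRNA/CDS GFF3; transcripts may be
  multi-exon and on either strand, and transcripts of one gene may
  overlap in different frames.

Internal coordinates are 0-based half-open; VCF and GFF3 stay 1-based
on their surfaces and are converted exactly once, in the readers.

## Effect annotation

A variant inside a transcript's CDS is mapped to its offset in the
spliced coding sequence (minus-strand offsets count from the genomic 3'
end, so offset 0 is always the first coding base; the annotated phase
is subtracted). The reference codon is read from the extracted CDS, the
strand-adjusted alternate allele substituted, and the pair classified
with a hard-coded standard nuclear codon table. Stop categories are
decided before the synonymous/non-synonymous split: stop→stop,
stop-gain, stop-loss, then synonymous vs non-synonymous. Variants in an
incomplete terminal codon or with an N in the codon context are
excluded and tallied separately (translation is undefined there).

One variant yields one call per containing transcript. A site whose
calls mix a synonymous effect with an amino-acid-changing effect
(non-synonymous, stop-gain or stop-loss) across coding contexts is a
*multi-SNV* site. The mechanism behind such sites in real data
(isoforms, homeologs of a polyploid, or multi-allelic records) is not
observable from a VCF; this package models them via overlapping
transcript frames, which the simulator creates deliberately.

Where a single label per site is needed (accounting tables), the most
severe call wins: stop-gain > stop-loss > non-synonymous > stop-stop >
synonymous. For two-way summaries, stop-stop is grouped with synonymous
(the protein is unchanged) and stop-gain/stop-loss with non-synonymous.

## Comparative site typing

Sites present in either strain are typed by (seq_id, position):
identical alt in both strains (`same_identical`); both mutated but to
different alleles (`typeI`); wildtype-only (`typeII`); mutant-only
(`typeIII` — the class where EMS-specific mutations accumulate). A
strain with several alts at one position yields one record per allele;
leftover divergent alleles of the two strains are paired into typeI
records. "Shared" in the accounting table means shared *position*, so
typeI sites count as shared in both strains, each under its own
strain's effect class; whether shared columns should count positions or
(position, effect) pairs is ambiguous in the source material, and this
convention is the one the identities `same + distinct = class total`
are enforced under.

The pairwise strain-vs-strain summary classifies, at every divergent
site, the substitution wildtype-allele → mutant-allele in the reference
codon context (the reference allele stands in for an absent call). Only
the focal site is substituted; other strain variants falling in the
same codon are ignored — a documented simplification, exact whenever
variants are sparse relative to codon length.

## Spectrum statistics

The 12 ordered substitutions are tallied either as written in the VCF
(`reference` mode, the default for reporting) or strand-adjusted to the
coding strand (`coding` mode); both are emitted since the convention
used by any given upstream caller varies. Transitions are A↔G and C↔T.
Consensus GC per strain is the GC fraction of all transcripts'
reference CDS with that strain's alleles substituted (N bases excluded
from the denominator; GC is strand-symmetric so substitution precedes
any reverse complementing). The positional profile divides each coding
sequence into 20 equal bins, `bin = floor(20 · offset / length)`
clamped to bin 19, so the 5'-most base is bin 0 and the 3'-most bin 19.

The strain comparison test is a two-sided Welch (unequal-variance)
unpaired t-test on per-gene transition fractions, with
Welch–Satterthwaite degrees of freedom. The Welch form is chosen
because nothing justifies assuming equal variances between strains; the
per-gene transition fraction is chosen as the compared quantity because
it is the per-gene statistic the spectrum analysis produces. Degenerate
inputs: two zero-variance samples with equal means give t = 0, p = 1;
samples smaller than 2 raise.

## Expression and enrichment

logFC is `log2((mut + c)/(wt + c))` with pseudocount c = 1 (keeps all
entries finite and is antisymmetric under strain swap); base 2 and
c = 1 are the field's defaults. No library-size normalization is
applied by default — the counts are treated as preliminary expression
values — but a counts-per-million mode exists. With pooled samples and
no replicates a dispersion-based test is not possible, so "differential"
means |logFC| ≥ 1 in at least one stage; the threshold is a parameter.
The heatmap subset defaults to genes carrying mutant-specific C→T/G→A
variants, matching how such heatmaps are used in EMS studies.

Enrichment is the upper-tail hypergeometric probability per term with
Benjamini–Hochberg correction across tested terms. The population
defaults to all genes in the annotation map (the annotated background);
terms with no population gene are skipped; study genes outside the
population are an error rather than silently dropped.

## The synthetic-data generator

Each gene sits on its own scaffold: 30 bp flanks around a CDS that
starts ATG, ends with a stop, and contains no internal stop in frame.
Genes are single- or two-exon (40% two-exon, intron 60 bp) on a random
strand; a configurable number of genes carry a second, +1-frame-shifted
isoform whose frame is also kept internally stop-free (via local
resampling at codon junctions) so that multi-SNV sites arise from
genuine overlapping reading frames. Codon sampling is weighted to a GC
target of 0.5 with ±0.1 acceptance per gene (bounded retries).

Lineage model: ancestral variants are drawn per CDS base at rate
`wt_mut_rate = 0.004` with a uniform substitution spectrum and written
to both strains; per ancestral site the mutant re-mutates to a
different allele with probability 0.02 (typeI) or loses the variant
with probability 0.05 (typeII). EMS variants are mutant-only, drawn at
`ems_rate = 0.002` per CDS base; each event is a reference-strand C→T
or G→A with probability `ems_bias = 0.9`, otherwise a uniform
non-EMS-type substitution (so the realized EMS-type fraction estimates
the bias directly). Draws colliding with occupied sites are resampled.
The defaults are the conditions of the package's recovery experiment:
300 genes × 900 bp CDS give ≈540 expected EMS events, enough for the
transition-fraction estimate to resolve 0.9 within ±0.05; the ancestral
rate is set so shared sites outnumber strain-specific ones roughly as
in published wildtype-vs-reference tables (order 10³ shared sites at
this genome size). Expression counts are Poisson with per-gene
Gamma(5, mean/5) baselines around `count_mean = 100`; the 30
differential genes have their mutant mean scaled by 2^±2 in all six
stages.

What the generator does *not* emulate: sequencing errors and read-level
artifacts, polyploid homeolog cross-mapping, allele frequencies in
pooled libraries, expression-dependent variant detectability, and any
correlation between mutation load and expression. Passing recovery
tests therefore show the pipeline's statistics are correct for clean
presence/absence calls, not that they are robust to caller noise.

## Numerical and serialization choices

Report TSVs serialize floats to 6 significant digits for reproducible
diffs. All simulator randomness flows from one `numpy` Generator seeded
from `SimConfig.seed`, making every output byte-reproducible. The
per-strain VCF carries the strain as a file-level label, not a sample
column, matching separately sequenced libraries.

## Known limitations

* Codon-context interactions between nearby variants of one strain are
  ignored in both per-strain and pairwise effect calls.
* The presence filter concept "site seen in all per-stage libraries" is
  not applied by default (per-stage VCFs are rarely available); the
  comparison operates on one merged VCF per strain.
* Enrichment treats terms as flat labels; no ontology propagation.
* The t-test target (per-gene transition fractions) is one defensible
  choice among several; the function accepts any pair of per-gene
  fraction samples.
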
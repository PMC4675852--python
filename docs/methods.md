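# Methods

This note records the models, conventions, parameter choices, and known
limitations behind each stage of the pipeline, and what the synthetic
generator does and does not emulate.

## Coordinates and formats

All genomic and protein coordinates are 1-based inclusive (the GFF3
convention) everywhere in the library; conversions happen only inside
readers. FASTA parsing goes through Biopython, GFF3 through gffutils
(in-memory), Newick through Bio.Phylo. The TSV topology dialect
(`protein_id  length  segments  n_terminus_side`) is the canonical
exchange format; TMHMM v2.0 long-format text is supported as a
best-effort importer, with N-terminus sidedness taken from the first
non-TM region label.

## Region model and identification cascade

Regions are assigned by alternating membrane sidedness from the
N-terminus across each TM segment. For a 4-TM protein with the
N-terminus inside, the loops are EC1 (TM1–TM2, extracellular), ICL
(TM2–TM3, intracellular) and EC2 (TM3–TM4, extracellular), and
`orientation_ok` is true. With the N-terminus outside, loops are
labelled by their actual sidedness (EC labels go to extracellular loops
in order) and `orientation_ok` is false. For other TM counts the EC/ICL
labels are withheld (`loopN` keys) because the canonical model is
undefined. Zero-length loops are allowed and recorded.

The cascade's rules are independently switchable, with defaults:

| rule | default | rationale |
|---|---|---|
| four TM helices | required | defining feature of the family |
| EC2 > EC1 | required | the large loop carries the conserved module |
| EC2 cysteines | ≥ 9 | conserved cysteine set of the plant family; `≥` rather than `==` because exact equality is brittle across annotation versions (strict mode available) |
| signature | `GCC[KR]P` core accepted | the longer `SGCC[KR]PP` form is an observation about the rice family, not the screening criterion; strict mode requires it |
| tail length | ≤ 60 aa | "short tails" is otherwise undefined; 60 admits every member of a typical plant family (longest members ~380 aa) while excluding large cytoplasmic domains |
| orientation | required | EC1/EC2 labels are only meaningful with cytoplasmic termini |

Design choice: when the TM count is not 4 (or the orientation is
non-canonical) the EC2-dependent rules are *not evaluated* rather than
trivially failed. A 3-TM protein has no EC2, and reporting "no
signature, too few cysteines, EC2 not longer" for it would conflate one
topological defect with four sequence defects; the failure list then
names the actual defect only. Verdict semantics are unchanged — such
proteins are rejected via the TM-count (or orientation) rule.

Proteins with unknown N-terminus sidedness are scored under both
orientations and the verdict with fewer failed rules is kept, flagged
as `orientation_assumed`.

The glycosylation-sequon scan (N-{P}-[ST] within EC2, overlaps allowed)
and the juxtamembrane-cysteine report (cysteines within 5 residues of a
TM boundary on the cytoplasmic side) are deliberately simple sequence
heuristics, not trained predictors; they are report fields, never
filtering rules.

### Built-in TM predictor

`predict_tm_hydropathy` is a Kyte–Doolittle sliding-window predictor
(window 19, threshold 1.6 mean hydropathy, greedy non-overlapping
maximal windows, merged when within 3 residues). Sidedness follows the
positive-inside heuristic: the terminus flanking the more basic (K/R)
tail is placed inside. It exists so the pipeline is self-contained; it
is a crude approximation of an HMM-based predictor and recovers planted
strongly-hydrophobic helices to within ~3 residues of their true
boundaries, which is sufficient for the cascade but not for real
proteome-scale topology prediction.

## Identity, similarity, and domains

Pairwise alignment is optimal global alignment with affine gaps
(BLOSUM62, gap open 10, extend 0.5, deterministic traceback). Residues
outside the matrix alphabet are mapped to X and scored 0 (neutral) with
a warning. Percent identity counts identical residue columns; percent
similarity additionally counts pairs with a positive substitution
score; columns containing a gap count toward neither. The denominator
is configurable (`alignment_length` default, `shorter_seq`,
`mean_length`) because published identity matrices rarely state which
convention their web tool used; reproductions of published percentages
should expect a ±2 point spread across denominators and aligner
parameter choices.

The progressive multiple aligner builds an NJ guide tree on pairwise
p-distances and merges profiles bottom-up with sum-of-pairs scoring
(expected BLOSUM62 score between column frequency profiles, same affine
penalties). It is deterministic given its inputs and is not intended to
be column-identical to ClustalX.

Per-domain conservation maps each sequence's region intervals through
the alignment to columns, takes the union of columns per region, and
averages pairwise percent identity over that column set; pairs lacking
a region are skipped and counted.

## Phylogeny

`nj_tree` implements Saitou–Nei neighbor joining with the Q-criterion,
deterministic lexicographic tie-breaking (by the smallest leaf id in
each cluster), and negative branch-length clamping that moves the
deficit to the sibling edge so the joined pair's distance is preserved.
On additive (tree-metric) inputs the reconstructed path-length matrix
reproduces the input to machine precision. Distances for tree building
are p-distances with pairwise gap deletion. Bootstrap support resamples
alignment columns with replacement (seeded NumPy generator), rebuilds
the NJ tree per replicate, and reports the percentage of replicates
containing each internal bipartition; 1000 replicates is the default,
and clades are conventionally read at ≥ 50% support.

## Gene architecture

Introns are the gaps between consecutive exons, reported in 5′→3′
transcript order. Phase is the cumulative CDS length 5′ of the intron
mod 3 (phase 0 between codons); introns outside the CDS span are
"undefined" and excluded from the phase census but kept in length
statistics. The interrupted codon's index (⌊cumulative/3⌋ + 1) links an
intron to the protein region containing it.

Tandem duplication: family pairs on one chromosome with at most 10
intervening non-family genes (inclusive boundary — 10 qualifies; the
boundary is a parameter). Intergenic distance is the count of bases
strictly between the two gene extents, 0 when they overlap.

Segmental duplication uses a deliberately simplified colinearity
chainer rather than a full synteny pipeline: anchors (homologous gene
pairs with positions) grouped by chromosome pair, chained under
strictly monotone positions on both chromosomes with consecutive gaps
≤ 500 kb on both; an anchor belongs to a block if some valid chain of
≥ 3 anchors contains it (computed by forward/backward longest-chain
DP, verified against exhaustive enumeration in tests). Pre-computed
block tables from a dedicated synteny tool can be substituted upstream.

## Promoters

Windows are the 1000 bases immediately 5′ of the translation start
(ATG), not the transcription start — matching how such analyses are
anchored when TSS annotation is unreliable; minus-strand windows are
reverse-complemented so offsets read 5′→3′ relative to the gene.
Windows truncated at a contig edge are flagged. Scanning expands IUPAC
codes to character classes and reports every occurrence, overlapping
included, on one or both strands; a leftmost-greedy non-overlapping
mode exists. The bundled dictionary holds PLACE-style consensus strings
for six element classes (ABRE ACGTG, HSE AGAANNTTCT, LTR CCGAC, the
MeJA-response pair CGTCA/TGACG, root motif ATATT, POLLEN1LELAT52
AGAAA); it is data (an editable TSV), not code, because consensus
choices vary between element databases. Note that the HSE consensus is
its own reverse complement as a degenerate pattern, so any HSE instance
is reported on both strands of a two-strand scan.

## Expression (ΔΔCT)

Technical replicates are averaged to one Cq per (gene, condition,
biological replicate). ΔCq = Cq_target − Cq_reference within each
replicate; ΔΔCq subtracts the mean control ΔCq; log₂ fold change is
−ΔΔCq, i.e. amplification efficiency is fixed at 2 (pure comparative-CT;
efficiency-corrected variants are out of scope). The reported standard
error is the propagated SE of a difference of means —
√(s²_treated/n + s²_control/m) over biological replicates — because the
subtracted control mean is itself an estimate; with 3 replicates this
makes the error/SE ratio t₄-distributed rather than heavy-tailed t₂,
which is what a "within 3 SE" coverage statement requires. A condition
compared against itself yields exactly 0.

Regulation is flagged at |log₂FC| ≥ τ with τ = 2 by default
(a 2-unit change on the log₂ axis, i.e. 4-fold linear); τ is
configurable because "two-fold on a log₂ scale" is ambiguous between
that reading and linear 2-fold. Venn overlaps assign a gene to a named
condition group when it is regulated, direction-specifically, in at
least one of the group's conditions, and report all 2^k − 1 exclusive
regions. Hierarchical clustering (scipy; euclidean or correlation
distance, average or complete linkage) imputes missing cells as 0 with
a rendered mask and sorts rows by gene id before linkage so leaf order
is deterministic under ties.

## Synthetic data

One integer seed drives every artifact; per-artifact streams use fixed
offsets, so outputs are byte-identical across runs. The generator
emulates the *structure* of a small plant tetraspanin study, with
defaults chosen as the study conditions:

- **Proteome**: 15 tetraspanins among 500 decoys (100 per class).
  Tetraspanins: four strongly hydrophobic 22-residue TMs, EC1 of 12–18
  aa with exactly one cysteine, ICL 10–15 aa, EC2 of 80–100 aa with an
  embedded `SGCC(K/R)PP` and 9 cysteines, tails ≤ 35 aa from a
  hydrophilic alphabet. Each decoy class violates exactly one rule
  (3 TMs; no signature — enforced by never placing adjacent cysteines;
  EC2 smaller than EC1; a 70–90 aa C-tail; 7 EC2 cysteines), so
  per-rule specificity and failure attribution are measurable.
- **Annotation**: gene plans realize an adjacent tandem pair, a
  10-intervening tandem pair, an 11-intervening non-pair, the intron
  phase multiset {0,0,1,2} in one five-exon gene, an intronless gene, a
  10-intron gene, and intron lengths spanning 95–4200 bp, on both
  strands. Promoter windows carry motifs planted at fixed offsets;
  background bases are then mutated ("scrubbed") until the planted
  occurrences are the only matches on either strand, so recovery is
  exact by construction. Anchor blocks realize one clean 5-anchor
  colinear block (segmental truth) and one chain split by a 600-kb gap
  (negative truth).
- **Cq tables**: Cq = gene baseline − planted log₂FC + a
  condition-wide shift shared with the reference gene + N(0, 0.1)
  noise, in a 3 biological × 2 technical replicate layout over a
  control and five treatment conditions.

What the generator does **not** emulate: realistic codon usage, GC or
repeat structure, homology between family members (planted proteins are
random within their region constraints, so alignment-based identity
percentages on synthetic families reflect alphabet composition, not
evolutionary signal), UTRs and alternative splicing, primer efficiency
variation, or condition-correlated biological noise. Passing tests
therefore demonstrate the correctness of the pipeline's logic and
arithmetic on inputs satisfying its assumptions — not performance on
real proteomes, where topology-prediction error dominates.

## Problem sizes

The test suite and acceptance script run at the sizes the recovery
statements are defined over: 20 proteome seeds of 15+500, 100 additive
matrices of ≤ 8 taxa, 10 bootstrap runs of 1000 replicates on 4-taxon
alignments with 200 columns, 200 random gene models, 20 Cq-table seeds,
100 random promoter windows, and 30 random anchor sets of ≤ 8 anchors
for the brute-force chainer comparison.

## Numerical notes

- NJ ties broken lexicographically; bootstrap RNG is a seeded
  `numpy.random.Generator`; identical seeds give identical supports.
- Alignment traceback prefers substitution, then a gap in the second
  sequence, then the first.
- Negative NJ branch estimates are clamped to 0 with the deficit moved
  to the sibling edge; distances in the agglomeration are floored at 0.
- Degenerate inputs: empty proteomes, single-exon genes, single
  sequences, and empty anchor lists all return empty results rather
  than erroring; truncated promoter windows and incomplete CDS models
  are flagged, not fatal.
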
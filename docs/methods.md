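# Methods

## Segment cache

The simulator works from a library of germline V, J and C segments given as
paired cDNA and peptide FASTA files. For each segment the reading frame of
the cDNA is found by translating the three forward frames and locally
aligning each translation to the peptide (Smith–Waterman via Biopython's
`PairwiseAligner`, BLOSUM62, gap open 10, gap extend 1); the highest-scoring
offset wins, ties going to the smaller offset. The alignment-based search is
robust to 5' UTR/leader sequence ahead of the coding region and to the
occasional cDNA/peptide discrepancy in real references; segments whose best
score falls below a configurable minimum (default 10) are excluded with a
warning rather than poisoning the cache.

CDR3 anchors follow the IMGT junction convention: the V anchor is the
**last** cysteine of the V peptide and the J anchor is the **first**
occurrence of the expected residue — phenylalanine, or tryptophan for
TRAJ33, TRAJ38 and TRAJ55 — within the first five peptide positions.
Searching only the first five J positions prevents a downstream F in the
constant-proximal part of the J segment from being mistaken for the anchor.
Segments without a locatable anchor are excluded and tallied. Subgroups are
obtained by truncating the gene name at the first `-` and at `*`
(TRBV6-1\*01 → TRBV6). All coordinates in the package are 0-based,
half-open.

D genes are not modeled: the generative recipe is V + CDR3 + J + C, with the
D-derived nucleotides absorbed into the sampled CDR3 interior. BCR loci are
out of scope (somatic hypermutation and isotype switching would need a
different generative model).

### Synthetic reference

`make_toy_reference` writes a random in-frame segment library satisfying
every cache invariant, so the whole pipeline runs without any download. Per
chain it emits `n_v` V segments (24-residue core, anchor cysteine, then
`v_tail` cysteine-free residues that are available for junction clipping),
`n_j` J segments (`j_head` clippable residues, the anchor, then a
10-residue tail) and one 30-residue C segment. Defaults are `v_tail=0`,
`j_head=0` (the minimal shape: V peptide ends at the anchor); the test and
acceptance fixtures use `v_tail=4`, `j_head=3` so that junction clipping is
non-degenerate, and name three TRA J genes TRAJ33/38/55 so the tryptophan
exception is exercised. Real references have longer V tails; the synthetic
ones are deliberately short so that exhaustive checks stay cheap.

## Statistical models

Four families of categorical distributions drive sampling — V/J usage per
chain, clip (deleted-residue) counts per chain and junction side, CDR3
length, and interior amino-acid composition pooled into three regions (the
`k=3` positions after the C anchor, the `k` positions before the F/W
anchor, and the middle). Pooling into regions rather than fitting a
per-position-per-length matrix keeps the fit well-conditioned on small
tables while still capturing the strong positional preferences at the
junction edges. All distributions are fitted as empirical frequencies from
an AIRR-style table (`v_call`, `j_call`, `junction_aa`); rows whose genes
are absent from the cache or whose junction violates the anchor rules are
dropped and counted.

Clip lengths are not observable directly from a junction, so they are
inferred by a greedy decomposition: the longest common prefix of the
junction (after the C) with the germline V tail, and the longest common
suffix (before the anchor) with the germline J head; whatever matches
neither is treated as inserted. Insertions are implicit — the CDR3 model
regenerates them — so no separate insertion distribution is fitted. The
greedy rule can over-match when a sampled interior residue happens to equal
the next germline residue (a few percent of events with a 20-letter
alphabet), which is why distribution-recovery checks use a total-variation
tolerance of 0.05 rather than exactness.

The probability that a rearrangement is productive is a configuration
parameter (default 1.0), not a fitted quantity. A built-in default bundle
(uniform usage, truncated-geometric clips with ratio 0.5 bounded by the
shortest clippable germline stretch, a triangular length distribution on
[10, 20] peaked at 14, uniform composition) makes the simulator usable with
zero inputs; bounding the clip support by the germline guarantees every
draw is realizable, so the realized distributions equal the sampled ones.

## Rearrangement and contigs

Sampling retries incompatible draws (clip deeper than the germline, length
shorter than anchors plus retained residues) up to 1,000 times before
failing with a diagnostic — a bounded version of retry-until-success that
terminates on degenerate bundles. Nucleotide realization keeps germline
codons for germline residues; sampled residues get a uniform synonymous
codon (unbiased and seedable; synonymous codons of a residue can never be
stops, so productive contigs are stop-free from the V frame through J by
construction, and the test suite verifies it). Non-productive events are
realized as frameshifts by deleting one random junction nucleotide — the
dominant biological mechanism of failed rearrangements.

Contigs mimic a 5' 10X-style library: a 16-nt random unique cell barcode
(optional minimum pairwise Hamming distance; optional UMI block, off by
default), the clipped V (including any sequence 5' of the coding region),
the junction, the clipped J and the first 50 bp of the chain's C segment
(C-specific priming); the stored template is the reverse complement of that
mRNA-sense sequence. The barcode lives in the contig rather than in a
separate index read; per-cell FASTQ output makes demultiplexed layouts
trivial and the `barcoded-merged` layout covers the single-file case.

## Sequencing simulation

**Clonal expansion.** Clone sizes follow a rank-size power law: the r-th
largest clone is proportional to r^(−s), discretized deterministically so
sizes are positive integers summing to the cell count (the clone count is
chosen self-consistently; rounding residue is folded into the largest
clones). s = 0 gives equal clones, large s a single dominant clone; the
default s = 1.5 produces a realistically heavy-tailed repertoire. Clone
membership is a random partition; members share both rearrangements but
keep their own barcodes. The exponent is recovered by a log-log rank-size
regression restricted to clones of size ≥ 5 (below that, integer rounding
flattens the tail).

**Depth.** Per-contig depth is either fixed or uniform on [low, high]
(defaults 2–100; simulation presets of 400× mirror TCR-amplified
single-cell libraries, 2–100× the range where reconstruction methods start
to differ).

**Reads.** Amplicon semantics: single-end reads start at the template 5'
end; mate 2 of a pair is reverse-complemented from the 3' end. The read
count per template is `round(depth · template_len / (read_len · mates))`
(round half away from zero, minimum one read for positive depth — low
depths on short contigs must still emit reads), which makes the realized
depth exact to within one read-equivalent. Substitution errors are i.i.d.
per base at the configured rate with a flat quality string Q =
−10·log10(rate) capped to [2, 41]; indels are not simulated (substitutions
dominate short-read error). Every read records its provenance — template
id, start, strand and the injected error positions — so the error-free read
is reconstructible, and read ids resolve against the run manifest. An
amplicon FASTA export lets users run an external read simulator instead.

**Background.** Non-TCR transcripts come from a pluggable expression model:
gene means drawn log-normally (or taken from a user count table, TSV or
MatrixMarket) with gamma-Poisson (negative binomial) per-cell sampling,
then each gene rescaled so its mean depth across cells is exactly 1× —
that rescaling is the contract the TCR signal-to-background ratio depends
on, and it is enforced to 1e-6. Transcripts are stored
reverse-complemented like the contigs. The model reproduces overdispersion
but not gene-gene correlation structure or dropout patterns of real
droplet data; passing tests therefore bound the TCR-read bookkeeping, not
the realism of the background transcriptome.

**Pseudo-bulk.** A uniform random subset of per-cell FASTQs is concatenated
at byte level (valid for gzip members too); the selection list is written
alongside.

## Evaluation

Ground truth loads from the simulator's own table or from a CellRanger-style
`filtered_contig_annotations.csv`; cells are filtered to full-length and
productive, and when a cell carries several productive contigs of one chain
the one with the highest read support is kept (ties broken by lexicographic
CDR3) — a deterministic reduction where the convention is otherwise
unspecified. A cell is *true* for a feature when at least one predicted
chain matches: CDR3 at exact amino-acid identity, V/J at subgroup level,
AsTCR requiring all three, the paired scope requiring both chains.
Sensitivity is true/all, accuracy true/result; with zero result cells
accuracy is reported as missing rather than 0 so averages stay meaningful.
A prediction carrying only a bare locus ("TRBJ" with no subgroup number)
never matches. Predictions for barcodes outside the truth universe count
toward result cells unless `--strict-universe` is set. Candidate-read
TPR/TNR are plain set arithmetic against read-level labels, and contig
depth is total candidate-read nucleotides over contig length.

## Scoring

Accuracy and sensitivity aspects are per-sample weighted means of the
(CDR3, V, J) proportions with weights (0.5, 0.3, 0.2), averaged over
samples; time and memory enter as log2(1/seconds) and log2(1/kB);
adaptability and usability (output-file points 0–4 plus subjective
user-friendliness 0–5, supplied as inputs, never computed) are point
scores. Each aspect is min-max scaled to [1, 10] across methods — with all
values equal mapping to the midpoint 5.5, a symmetric choice for the
degenerate case — and combined with weights 0.2/0.2/0.1/0.1/0.1/0.1. The
weights sum to 0.8 by design and are not renormalized, so the attainable
range of the overall score is [0.8, 8.0]; ranking is descending with ties
sharing the smaller rank. The composite is monotone in every aspect and
invariant to affine rescaling of any aspect's raw values.

## Problem sizes and numerical choices

The validation suite runs the generative checks at 10,000 rearrangements,
distribution recovery at 5,000 events per chain (total-variation < 0.05
per distribution, which leaves headroom over the ~2% multinomial noise
floor and the few-percent greedy clip-inference bias), a 500-cell 400×
150 bp paired-end error-free run for read/template conservation and depth
(~560k reads), error calibration over 1.2 million bases (0.01 ± 0.0005),
and exponent recovery at 10,000 cells (±0.15). All randomness flows
through explicitly passed numpy generators; identical seeds give
byte-identical FASTQ, ground truth and manifests (gzip output uses a fixed
mtime for the same reason). Categorical supports are kept in sorted order
so iteration order never depends on dict history.

## Known limitations

- No D-segment bookkeeping, nucleotide-level N/P insertion model, dual-TRA
  cells, γδ chains or allelic inclusion.
- The error model is substitution-only with flat quality; no PCR
  duplicates, position-dependent error profiles or indels.
- The background expression model preserves marginal overdispersion and the
  1× scaling contract only; it is not a copula model of real scRNA-seq
  covariance.
- Clip-length inference is greedy and can under-count deletions when
  sampled residues coincide with germline ones; statistics fitted from very
  short junctions inherit that bias.
- The scoreboard consumes externally measured time/memory and subjective
  usability points; it does not execute or meter the methods themselves.
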
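# tcrforge

Simulation of 5' single-cell TCR-seq reads with exact ground truth, and a
benchmark harness for methods that reconstruct T cell receptors from
(single-cell) RNA-seq data.

## The problem

T cell receptors (TCRs) are heterodimers of an α and a β chain produced by
V(D)J recombination. The hypervariable CDR3 loop — spanning the conserved
cysteine at the 3' end of the V gene to the conserved phenylalanine (or
tryptophan, for TRAJ33/TRAJ38/TRAJ55) near the 5' end of the J gene — has no
reliable germline reference, which makes TCR reconstruction from RNA-seq
reads a specialized assembly problem. Evaluating reconstruction methods
fairly requires data where the answer is known exactly. `tcrforge` generates
such data: paired TRA/TRB rearrangements sampled from empirical repertoire
statistics, assembled into barcoded full-length 5'-library contigs, expanded
into clones, and sequenced *in silico* at a chosen depth, read length and
error rate — together with the metrics used to compare reconstruction
methods against that ground truth.

## What it computes

**Simulation.** For each cell and chain, a rearrangement is drawn as

- V, J genes ~ categorical usage distributions per chain;
- deleted residue counts at the V–CDR3 and CDR3–J junctions ~ categorical
  clip distributions;
- CDR3 length L ~ categorical length distribution; the CDR3 is then
  `C + (germline V tail after the anchor, clipped) + sampled interior +
  (germline J head before the anchor, clipped) + F/W`, with interior
  residues drawn from positional composition tables;
- incompatible draws are retried until success (bounded budget).

Germline residues keep germline codons; sampled residues get uniform
synonymous codons, so productive junctions translate back exactly. The
contig is `barcode + clipped V + CDR3 + clipped J + ~50 bp of C`, stored
reverse-complemented (5' amplification). Clone sizes follow a rank-size
power law (size of the r-th clone ∝ r^(−s), default s = 1.5); per-contig
depth is fixed or uniform; reads follow amplicon semantics (mate 1 anchored
at the template 5' end, mate 2 at the 3' end) with i.i.d. substitution
errors. An optional background of non-TCR transcripts is scaled to a mean
depth of exactly 1× per gene per cell.

**Evaluation.** Per sample, with "all cells" the ground-truth universe and
"result cells" those a method reports on,
`sensitivity = true cells / all cells` and `accuracy = true cells / result
cells`, for features CDR3 (exact amino acid), V and J (subgroup level,
TRBV6-1\*01 → TRBV6) and AsTCR (all three correct), per chain and paired.
Candidate-read selections are scored by TPR/TNR against read-level truth,
and contig depth is estimated as total candidate-read nucleotides divided by
contig length.

**Scoring.** Six aspects (accuracy, sensitivity, adaptability, usability,
log2(1/time s), log2(1/memory kB)) are min-max scaled to [1, 10] across
methods and combined with weights 0.2, 0.2, 0.1, 0.1, 0.1, 0.1 (deliberately
summing to 0.8, so a method dominating every aspect scores 8.0).

## Worked example

No downloads are needed — a synthetic paired cDNA/peptide reference
generator is built in:

```
tcrforge toy-ref -o ref --seed 3
tcrforge cache --cdna ref/toy_cdna.fasta --pep ref/toy_pep.fasta -o cache.json
# -> cached 18 segments (0 excluded) -> cache.json
tcrforge rearrange --cache cache.json -n 50 --seed 5 -o truth/
tcrforge fit --airr truth/ground_truth.tsv --cache cache.json -o bundle.json
# -> fitted bundle (fitted from 100 rows (0 dropped)) -> bundle.json
tcrforge simulate --cache cache.json --bundle bundle.json -n 20 \
    --depth uniform:2:100 --read-len 100 --mode PE --zipf 1.5 --seed 11 -o run1/
# -> wrote 3372 reads for 20 cells -> run1/
tcrforge pseudobulk --cells run1 --pattern "cell_*_R1.fastq" -k 5 --seed 2 -o pb.fastq
```

The cache holds 18 segments: 6 V + 6 J + 1 C per chain, each with its
detected reading frame and anchor position. `run1/` contains per-cell FASTQ
pairs, the amplicon FASTA, the ground-truth table and a manifest; 3372 reads
is the analytic count — each contig gets round(depth·len/(2·100)) read
pairs for its drawn depth.

Evaluating the simulator's own truth table against itself gives the
expected identity (every cell correct):

```
tcrforge eval --truth truth/ground_truth.tsv --pred pred.tsv -o metrics.tsv
# chain feature  n_all  n_result  n_true  sensitivity  accuracy
#   TRA    CDR3     50        50      50          1.0       1.0
#   TRA       V     50        50      50          1.0       1.0
#   ...
```

and scoring a two-method comparison where one method dominates every aspect
reproduces the 8.0 ceiling:

```
tcrforge score --metrics m.tsv --points p.tsv -o scorecard.tsv
#     accuracy  sensitivity  adaptability  usability  time  memory  overall  rank
# T4      10.0         10.0          10.0       10.0  10.0    10.0      8.0     1
# MX       1.0          1.0           1.0        1.0   1.0     1.0      0.8     2
```

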
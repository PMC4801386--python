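# Methods

## Overview

The package quantifies per-CDS transcript abundance in four libraries (FSG,
MSG, FWB, MWB), tests each CDS for salivary-gland enrichment, classifies
enriched CDS by sex, and cross-validates fold changes against qPCR. The
chain is deliberately simple — counting, within-library normalization,
2×2-table tests — because the underlying study design has one library per
condition and no biological replication at the sequencing level; the qPCR
module exists precisely because replication enters only there.

## Read assignment

Reads are first trimmed from the 3′ end: the trailing run of bases with
Phred quality below 13 is removed, and reads shorter than 25 nt (the seed
word size) afterwards are dropped. An alternative whole-read discard mode
is available, since base-trimming versus read-discarding is a genuine
design fork; base-trimming is the default because it preserves usable
5′ sequence.

Mapping is seed-and-extend in the blastn idiom. Candidate CDS are any that
share an exact 25-mer with the read on either strand. Each candidate is
scored by banded extension around the seed diagonals with match +2,
mismatch −3, gap open −5, gap extension −2 (megablast-like values; the
scheme is configurable because only the word size, the one-gap allowance
and the identity floor are fixed by the method definition). "One gap
allowed" is read as at most one gap opening of length ≤ 3 nt on either
sequence — in a 101-nt read context a longer gap is indistinguishable from
a mismapping. The read must be fully contained within the CDS; identity is
matches divided by alignment columns (gap columns included) and alignments
below 95 % are discarded. Among survivors only assignments tied at the
maximal score are retained, at most five per read; when more than five tie,
the five lexicographically smallest CDS ids are kept for determinism.
Multi-mapped reads contribute a whole count to each tied CDS (the retention
rule caps the inflation at 5×); a fractional 1/k policy is available behind
a flag. Library totals R are therefore column sums of the count matrix.

The test suite checks the mapper against an exhaustive aligner that
enumerates every start diagonal of every CDS on both strands with no
seeding or pruning; retained (read, CDS) pairs and scores must agree
exactly on randomized instances that include duplicated CDS, indel reads
and unmappable reads.

## Quantification

RPKM uses each library's own mapped-read total; TPM is the standard
length-rate normalization and sums to 10⁶ per library whenever any read
mapped. The Expression Index is anchored to the FSG library by default (the
most abundant FSG transcript defines EI = 100); the reference library is
configurable. Two pseudocounted ratio families are emitted for the six
directed library pairs (FSG/MSG, FSG/FWB, FSG/MWB, FWB/MWB, MSG/MWB,
MSG/FWB): the normalized read ratio r₁R₂/[R₁(r₂+1)] on raw counts, and
TPM ratios with +0.1 added to the denominator. Both pseudocounts are part
of the method definition, not tunables.

## Enrichment testing and classification

Each CDS is tested with a Pearson χ² (1 df) on [[r₁, R₁−r₁], [r₂, R₂−r₂]],
pooling FSG+MSG against FWB+MWB. No Yates correction is applied by default:
the intended regime has large counts, and a flag enables it for desk-scale
data. A zero row marginal returns statistic 0, p 1. Bonferroni and BH
adjustments run over all CDS in the reference.

The salivary filter requires a pseudocounted TPM fold
(TPM_FSG+TPM_MSG)/(TPM_FWB+TPM_MWB+0.1) ≥ 10 **and** BH q ≤ α (default
0.05). The fold metric is TPM-based rather than count-ratio-based for
consistency with the downstream TPM-ratio screens; the pooled normalized
read ratio is emitted alongside for comparison. At realistic depths the
significance gate is never binding — it matters only for shallow data.
Thresholds follow the stated wording: "at least" boundaries are inclusive
(≥ 10, ≥ 5), the extreme screen's "above 1,000" is strict (>). Enriched CDS
are partitioned by the fivefold TPM-ratio boundary into female-enriched,
male-enriched and shared; with the +0.1 pseudocount the two directions
cannot both reach fivefold, but the larger ratio would win if a custom
threshold made that possible. The extreme screen flags
FSG/(MWB+0.1) > 1,000 (female direction) and MSG/(FWB+0.1) > 1,000 (male
direction) — the cross-sex whole-body denominator matches how extreme
salivary specificity is tabulated in practice; the same-sex SG ratios are
present in the output for inspection. Heatmap input is the row-wise Z score
of the TPM matrix (sample SD, ddof 1); constant rows map to all-zero so
heatmaps stay well-defined.

The category summary table reports, per class, both the mean of per-CDS
pseudocounted ratios and the ratio of mean TPMs. These genuinely differ
under heterogeneous per-CDS ratios — published class-level "average ratio"
columns are ambiguous between the two — so both are emitted with explicit
labels rather than guessing.

## ORF bookkeeping

The longest ORF is sought per contig over all six frames, where an ORF is a
maximal stop-free codon run optionally bounded by a stop. A methionine
start is recorded as a flag, never required (assembled CDS sets legitimately
contain N-terminally truncated proteins). Runs are ranked by total codon
span counting a bounding stop, with complete (stop-bounded) runs preferred
on span ties — a complete ORF is more trustworthy than one truncated by the
contig edge — then by frame order +1, +2, +3, −1, −2, −3 and leftmost
start. Codons containing N translate to X and do not terminate a run.
Coordinates are 0-based half-open on the forward strand and include the
terminal stop codon when present. The extension rule (new length ≥ 1.25 ×
reference length) and the outgroup-validation thresholds operate on
externally supplied alignment summaries; the 10 % size window is taken
relative to the subject (reference) length, which is the conservative
reading of an ambiguous rule.

## qPCR model

Technical duplicates are averaged per biological replicate before any
statistics (they measure instrument noise, not biology; a flag treats them
as replicates instead). ΔCt = Ct_target − Ct_reference per replicate;
ΔΔCt is the difference of group means; its SE combines the two group
standard errors in quadrature, the standard propagation for a difference of
independent means. Fold change is 2^−ΔΔCt with the interval
(2^−(ΔΔCt+SE), 2^−(ΔΔCt−SE)). No amplification-efficiency correction is
applied (pure 2^−ΔΔCt model). Concordance between log₂ qPCR and log₂
RNA-seq folds is Pearson R with a two-sided p and an OLS line; the returned
residual SD, slope/intercept SEs and band helper reproduce a 95 %
mean-response confidence band.

## Synthetic data generator

The generator emulates the study conditions: 101-nt single-end reads, a
3:1 FSG:MSG depth imbalance mirroring the molar pooling of the original
libraries, uniform base composition, strand-symmetric sampling, independent
per-base substitution errors (default 0.005, low enough that most reads
pass the 95 % identity floor while a tail exercises it), and optional
injected low-quality 3′ tails (default probability 0.02) to exercise
trimming.

Composition is planted in expected-TPM space. Planting raw per-library
abundance multipliers cannot realise TPM-scale folds when enriched CDS are
a sizeable fraction of a closed reference: TPM renormalization deflates
every ratio by the library-composition factor. Instead, each SG-associated
CDS (female-, male- or shared-enriched) receives a fixed molar level in
both whole-body libraries (`enriched_wb_tpm`, default 150 ppm — salivary
transcripts are rare in whole bodies), its pooled salivary level is that
level times the planted SG/WB fold, split between FSG and MSG by the
planted sex fold, and background CDS absorb the remaining molar mass of
each library. Planted folds then hold exactly in expected TPM, and the
realised (sub-unity) SG/WB fold of background CDS is recorded in the truth
table. Read counts are multinomial per library with sampling weight molar
fraction × CDS length (longer templates yield more reads); CDS shorter than
the read length are excluded from sampling with a warning. Default scale is
500 CDS of 150–400 nt with depths FSG 90,000 / MSG 30,000 / FWB 25,000 /
MWB 25,000 and planted folds drawn U(25, 40): large enough that every
enriched CDS has expected salivary counts ≥ ~200, the regime in which the
classification-recovery guarantees are stated.

What the generator does **not** emulate: transcript isoforms and shared
subsequences (apart from explicit exact duplicates for multi-mapping
tests), paired-end structure, PCR duplicates, positional coverage bias,
quality-score decay and indel sequencing errors, and realistic whole-body
transcriptome complexity (background CDS stand in for it as a uniform
pool). Passing recovery tests therefore demonstrates correctness of the
counting, testing and classification machinery under the planted model, not
robustness to assembly artifacts or mapping ambiguity in real libraries.

## Numerical choices and degenerate inputs

- χ² is computed in closed form (N(ad−bc)²/row·column products) and checked
  against scipy's contingency test; zero marginals short-circuit to (0, 1).
- RPKM with R = 0 returns 0 with a warning; EI with a zero reference
  maximum is an error (the index is undefined, not zero).
- An all-zero count library yields an all-zero TPM vector rather than NaN.
- Score ties inside one CDS prefer higher identity, then fewer gaps; ties
  across CDS beyond the 5-hit cap resolve lexicographically.
- All randomness flows from numpy `default_rng` seeded per stage from the
  run seed, so fixed seeds give byte-identical FASTQ and TSV outputs.

## Known limitations

- The mapper is not a general aligner: no spliced alignment, no paired-end
  rescue, no SAM emission; reads must fit inside a CDS.
- Between-sample normalization is limited to TPM/RPKM by design (no TMM or
  quantile normalization), matching the method being implemented.
- The χ² on pooled single libraries tests read-count proportions, not
  biological variability; its p-values carry the usual caveat of
  unreplicated RNA-seq and are why the qPCR concordance module exists.
- The test suite and defaults run at desk scale (tens of thousands of
  reads, hundreds of CDS), chosen so the statistical guarantees (binomial
  tolerances, ≥ 95 % recovery) are meaningful while the suite stays fast;
  the implementation itself streams reads and holds only the count matrix,
  so it scales to larger inputs linearly.
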
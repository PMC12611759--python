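# Methods

This note documents the models and procedures implemented in `editscope`,
the parameters that matter, what the simulators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Long-read deletion profiling

**Model.** A long PCR amplicon spanning a Cas9 cut site reads out
large on-target deletions as a length deficit: a molecule that lost *d*
bases between the primers yields a read of trimmed length *L\** − *d*,
where *L\** is the primer-trimmed unedited length. The pipeline therefore
needs no reference alignment — only a strict guarantee that every
surviving read is a complete, on-locus amplicon.

**Filtering.** Three consecutive rounds:

1. *End-to-end*: the forward primer must match at the 5′ end and the
   reverse-complemented reverse primer at the 3′ end. Each read is tried
   in forward orientation first, then reverse-complemented; matching is
   prefix/suffix-anchored edit distance (substitutions + indels) with
   budget ⌈rate·len⌉, rate 0.1 by default (a config knob; typical
   error-tolerant adapter-trimming defaults). Retained reads are emitted
   forward-strand with both primers trimmed. Palindromic primers are
   rejected at spec validation, so strand assignment cannot tie.
2. *Locus identity*: the trimmed read must begin with the 30-nt genomic
   anchor following the forward primer and end with the reverse
   complement of the 30-nt anchor preceding the reverse primer site,
   same matching budget (3 edits for 30-nt anchors at rate 0.1). Anchors
   are genomic sequence and are not trimmed.
3. *Size cap*: reads longer than cap + buffer are discarded, buffer
   +20 bp for sequencing-error length jitter. The cap is *L\** for an
   ordinary locus; when the locus carries a known HDR template insertion
   (e.g. 228 bp) the cap is *L\** + insertion size, otherwise every
   knock-in allele would be discarded by the rule that removes
   over-length artifacts. This reconciliation is a deliberate design
   choice: the size filter's purpose is to remove concatemers and
   chimeras, not expected knock-in alleles.

**Quantification.** Deletion size per read: max(0, *L\** − length).
The survival curve maps each observed size *s* to the fraction of reads
with deletion > *s* (non-increasing by construction). The headline
statistic is the fraction of reads with deletion > 1 kb. HDR-insertion
alleles are called by length: |length − (*L\** + insertion)| ≤ 20 bp.
Length-based calling deliberately ignores base-level alignment —
substitution noise cannot move a read across a kilobase threshold, and
indel noise shifts lengths by only tens of bases (see simulator).

**QC.** The surviving reads' global identity to the unedited amplicon
core (Needleman–Wunsch edit distance / max length) stands in for
genome-wide mapping QC: in an unedited sample, >95% of surviving reads
should match at ≥80% identity. This check is meaningful for unedited
samples only; genuine kilobase-deletion reads score low by construction.

**Known bias.** Under asymmetric survival of noisy molecules (round 3
discards net-insertion noise outliers but keeps net-deletion ones), the
>1-kb frequency is inflated by roughly one to two percentage points at
3% indel noise; this is inherent to any length-capped workflow and is
visible in the recovery tests (estimates ≈0.31–0.32 for truth 0.30).

## Short-read HDR classification

Reads with both 20-nt anchors at exactly 32 bp spacing are genotyped by
the Hamming distance between the 15-mer at the configured offset in the
gap and the wild-type reference 15-mer: ≥ 11 → HDR (the full barcode
substitutes 12 nt), else WT. Anchor matching is exact by default (a
mismatch budget is configurable); with multiple placements the leftmost
pair wins (deterministic tie-break). The reference 15-mer's offset inside
the gap is derived at spec load by exact search in the wild-type
amplicon, making the packaged spec reproducible without guessing.

Reads without a valid anchor pair are aligned globally to the wild-type
amplicon (affine gaps: match 2, mismatch −1, open −5, extend −1 —
standard disclosed parameters) and called *indel* when any inserted or
deleted base overlaps the 30-bp window centered on the cut site;
substitution-only discrepancies leave the read unclassified.

Identical sequences form alleles; alleles below 0.2% of total reads are
excluded (this removes the sequencing-error singleton cloud), and class
fractions are computed over retained reads. *Partial HDR* is defined
operationally as an HDR-called allele whose edited window differs from
the configured full-HDR window; it is tabulated separately and merged
into the reported HDR fraction. The 0.2% exclusion is applied at the
allele level (grouped identical sequences), the natural unit for a
frequency filter.

## Single-cell segment-loss calling

**Procedure.** Genes ordered by (chromosome, position); mitochondrial
genes excluded from dosage inference (they are used only by QC). Per
cell: library-size normalization to 10,000 counts, log1p. Per gene: the
mean log-expression over unedited cells is subtracted from each edited
cell. The residual is smoothed along each chromosome with a centered
51-gene moving average (shrinking windows at chromosome edges), then
each cell is median-centered (removing global depth/size shifts that
would otherwise masquerade as whole-genome dosage changes).

**Denoising.** The unedited cells are passed through the identical
residual computation against their own mean, giving a per-gene empirical
null of smoothed residuals. Edited-cell values inside the central
[q, 1−q] band of that null (q = 0.005) are set to 0 (neutral). Quantile
bands rather than ±k·sd because the single-cell residual null is
left-skewed (dropout tail): a symmetric standard-deviation band
under-covers exactly the loss direction and inflates false loss calls
several-fold. Without denoising, ordinary sampling noise pushes ~30% of
perfectly diploid cells below the call threshold at realistic depths;
with it, the null call rate is ≤3% in the packaged simulations. The band
parameter is exposed (`denoise_quantile`, None disables).

**Calling.** Residuals are exponentiated so neutral = 1.0 and a one-copy
loss trends toward 0.5. Per cell, the mean residual over the telomeric
segment (genes with start < target site on the target chromosome) is
compared against the strict threshold 0.95; the comparison segment is
the following 7 Mb ([target, target + 7 Mb), half-open on both
boundaries, so the gene exactly at the target site belongs to the
comparison side). Loss frequency = flagged cells / cells. Segment means
are taken on the denoised (smoothed) residuals — the same quantity the
heatmap displays. Cells are also Ward-clustered (Euclidean, via scipy)
on their telomeric-gene residuals; the dendrogram leaf order drives the
heatmap export. Ward on fixed input is deterministic.

**QC.** Cells outside [500, 50,000] total counts or above 20%
mitochondrial fraction are removed. These defaults are ordinary 10x-style
bounds and are configurable; no doublet modeling is attempted.

## ddPCR Poisson statistics

λ = −ln(1 − n⁺/n) copies per droplet (saturated wells raise; zero
positives give λ = 0 validly). All reported quantities are λ ratios, so
droplet volume cancels and is never parameterized. Replicate wells are
combined ratio-first (per-well ratio, then mean ± s.d., matching per-well
instrument practice); a pooled-count mode is available. Optional
confidence intervals use the delta method on ln λ
(se = √(p/(n(1−p)))/λ), normal approximation. Normalized CNV divides a
condition's ratio by the unedited control's ratio — the control against
itself is exactly 1 by construction — and fractional change is that
minus 1. VCN multiplies the λ ratio by 2 for a diploid reference gene.

## Synthetic data generators

All generators are deterministic per config + seed (single PCG64 stream;
FASTQ output is byte-stable) and return truth tables that exactly
partition the generated records. Class fractions are realized as exact
counts (round(n·f)) by default so recovery tests have exact
expectations; a `sampling` switch enables multinomial draws instead.

*Long reads*: each on-locus molecule is primer + anchor + core + anchor +
rc(primer); deletions sample a size (uniform 1,000 to core−200 bp by
default) and are placed to span the cut site, clamped to the
inter-anchor interior (sizes too large to fit are clamped, recorded in
the truth table); HDR molecules insert one fixed random template of the
configured size at the cut. Noise: i.i.d. per-base substitutions plus
1–2-bp indels (geometric, capped), defaults in the packaged study
conditions 2% and 3% — coarse ONT-like error without homopolymer
structure. Contaminants are primer-free random sequences at 0.8–1.2× the
core length, so round 1 rejects them unambiguously. Half of reads are
emitted reverse-complemented. Constant Q20 qualities (the analyses are
length/sequence based and never read qualities).

*Short reads*: four allele classes on the classifier's amplicon — WT;
HDR (full 12-substitution barcode window); partial HDR (exactly the
threshold number, 11, of those substitutions, so it crosses the HDR call
but differs from the full barcode); indel (drawn from a small recurrent
repertoire of 8 concrete deletion/insertion alleles at the cut site,
generated once per config — mirroring the strongly peaked allele spectra
of real end-joining outcomes, and necessary for the 0.2% allele filter
to behave as it does on real data). Substitution noise only.

*Single cells*: per-gene baseline means log-uniform in [0.5, 20] counts
(typical 10x 3′ per-gene depths), negative binomial with dispersion 0.3
(var = μ + 0.3μ²), i.i.d. across cells. The default panel spans 220
genes over 25 Mb of the target chromosome (≈57 telomeric to the default
target site), 80 genes elsewhere, 13 mitochondrial genes. Loss cells
(exact count) scale every in-segment gene's mean by `loss_effect`
(default 0.5 = monoallelic loss).

*Droplets*: each droplet draws Poisson(λ) copies and is positive iff ≥1,
independently per channel.

**What the simulators do not emulate** — and hence what passing tests do
not show about real data: ONT homopolymer/strand-specific error and
chimeric/concatemeric PCR artifacts; paired-end structure, quality-score
variation and UMI structure in short reads; cell-to-cell library-quality
correlation, doublets, cell-type heterogeneity and mappability variation
in the single-cell matrices (the unedited reference here is distributed
identically to the edited cells, which real organoid/HSPC comparisons
only approximate); droplet volume variation and rain (intermediate
fluorescence) in ddPCR. Recovery accuracies measured here are therefore
upper bounds on real-data performance.

## Problem sizes in the packaged checks

The packaged recovery checks use 5,000 long reads, 10,000 short reads,
500 + 500 cells and 20,000 droplets × 200 seeds — the scales at which
the corresponding statistics stabilize well inside their tolerance
bands on a single CPU.

## Known limitations

- Deletion sizing is length-based; balanced events (inversion,
  substitution of equal length) and deletions paired with co-located
  insertions are invisible or mis-sized. Translocations are out of scope.
- The long-read HDR call is a ±20-bp length window; an unrelated
  insertion of similar size would be miscalled HDR.
- The indel caller reports a binary window-overlap verdict, not allele
  structure, and one best alignment; micro-equivalent gap placements
  are resolved by the aligner's internal tie-break.
- Segment-loss calling assumes the unedited cohort is a faithful
  expression reference for the edited cells; composition shifts between
  cohorts would bias residuals genome-wide (partially absorbed by
  per-cell median centering).
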
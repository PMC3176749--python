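# Methods

This note documents the models implemented in `pairfuse`, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the numerical/design decisions that were genuinely open.

## Read alignment

A deterministic seeded aligner stands in for a production short-read mapper,
sized for the tens-of-kilobase references this package targets. Placements
are gapless with at most `max_mismatch` (default 2) substitutions; the
ambiguity base N never matches anything, including another N, and reads with
more than 10% N are rejected at load. Seeds are exact 12-mers placed by
pigeonhole: `max_mismatch + 1` disjoint seeds per read, so every placement
within the mismatch budget is guaranteed to be found for reads of length at
least 36 nt (both 38 nt and 76/80 nt reads qualify). The test suite verifies
exact agreement with a brute-force all-positions scan. A placement is
*unique* only when exactly one placement attains the minimal mismatch count;
ties are conservatively non-unique, which is what the unique-mapping
requirements downstream rely on. Indels, spliced alignment and quality-aware
scoring are deliberately out of scope; substitution-only sequencing errors in
the simulator keep the generator consistent with this contract.

Coordinates are 0-based half-open internally; only human-readable report text
uses 1-based inclusive coordinates.

## Synthetic locus and libraries

`build_locus` constructs a ~48 kb contig carrying a 5-exon gene (C11LIKE,
genomically upstream; the 3′ fusion partner) and a 3-exon gene (ERRLIKE,
downstream; the 5′ partner) on the + strand with a ~1 kb intergenic gap, plus
a 95%-identity paralog of the downstream gene on a second contig as a
homology decoy. Fusion isoforms join ERRLIKE exon 2 to C11LIKE exon 3, 4 or
5; the default tandem-duplication interval runs from the upstream gene's
intron 2 to the downstream gene's intron 2 (~8.3 kb), the configuration in
which transcription from the downstream gene's promoter in the first copy
reads through into the second copy's 3′ exons and produces exactly those
fusion transcripts. Everything — breakpoints, junction strings, junction
transcript coordinates — is recorded as truth at build time, and all outputs
are reproducible from (config, seed).

**RNA libraries.** Fragments of truncated-normal length (mean 350 bp, sd 30)
yield FR read pairs of 76 or 38 nt (long fraction 0.27, reflecting a sequencing
mix dominated by short reads), with per-base substitution errors (default
0.5%) and a configurable fraction of ligation chimeras (default 1%) built
from two independent fragments. A fragment's isoform is drawn proportionally
to weight × (length − fragment length + 1) — the number of valid placements —
which makes the generator exactly the sampling model assumed by the
quantification EM; sampling proportional to raw length instead would bias
the estimand by L/(L−μ+1) per isoform and turn abundance recovery into a
property of transcript lengths rather than of the method. The default
abundance scenario is 40:10:1:0 over {downstream wild type, fusion isoform 1,
fusion isoform 2, upstream wild type}.

**DNA libraries.** Each cell carries two haplotypes; a heterozygous
duplication sits on one. Fragment starts are drawn from a smooth positive
capture-bias function (mixture of Gaussian bumps over the locus) that is a
deterministic function of the locus, hence *shared* between tumor and normal
— emulating capture-probe inhomogeneity that is consistent between samples
and cancels in the tumor:normal ratio. Fragments are 160–780 bp
(truncated-normal, mean 400), reads 80 nt, so genuine pairs never exceed the
1 kb anomaly threshold. PCR duplicates are appended geometrically with
probability 0.1 per copy, giving a duplicate fraction of exactly 10%. A small
ligation-chimera rate (0.5%) provides the scattered anomalous-pair background
that any real library contains and that the pile-up null is calibrated
against. Tumor purity is a knob (default 1.0) that mixes haplotype sampling.

What the generator does **not** emulate: quality-score structure, GC bias,
indels, germline SNPs, alignment at genome scale against repeat families.
Passing tests therefore demonstrate correctness of the inference under the
stated sampling assumptions, not robustness to every artifact of real data.

## RNA arm

Junction records use flank `F = 66 = 76 − O_min` nt of *cumulative spliced*
sequence per side (so any informative 76-mer fits on a record; 38-mers are
scanned against the same records), with `O_min = 10` bp required on both
sides of the junction. Within-gene junctions are enumerated for every ordered
exon pair i<j, skips included — cheap at this scale and useful as uniqueness
competitors that absorb ambiguous reads. Junction-read uniqueness is enforced
across the *whole* database (the stricter reading). Only cross-gene
categories contribute to candidate counts.

Polarity: a junction read aligned in the fusion-transcript sense requires a
reverse-oriented mate uniquely placed in the 3′ gene downstream of the
junction; a reverse junction read requires a forward mate in the 5′ gene
upstream; the implied fragment must not exceed the insert bound (600 bp).
Mates that are unaligned or multi-mapping count as inconsistent. Homology-
and chimera-driven junction hits systematically fail this test.

False discovery: the published analysis's exact false-discovery model was not
available, so the per-candidate null mean is reconstructed as
(inconsistent-polarity hits) + (estimated chimeric-pair rate × junction reads
scanned × the candidate's share of junction-database length); the chimera
rate defaults to the observed discordant-leftover fraction. One-sided Poisson
tail p-values are BH-corrected across candidates. Candidates with at least
one consistent junction read are reported with q-values; a read-through flag
marks gene pairs whose junction canonical transcription could explain
(5′ gene transcriptionally upstream of the 3′ gene within 100 kb on the same
strand).

## Quantification

Expression rank is by unique-read density per kb per million. The isoform EM
uses binary pair–isoform compatibility (both mates placed on the isoform in
FR orientation with implied fragment inside the truncated-normal support,
mean ± 4 sd) and effective lengths `l_i = max(1, L_i − μ + 1)`. The EM
likelihood is asserted non-decreasing at every iteration; convergence is a
relative log-likelihood change below 1e-8 or 1000 iterations. The fitted
mixture weights α are read-generating fractions; reported abundances are
molar, `θ_i ∝ α_i / l_i`. Isoforms with no uniquely supporting pair are
flagged "no direct evidence" alongside their estimate, which is the honest
statement for an isoform whose abundance is only bounded, not observed.

## DNA arm

**Anomaly definition.** Both mates uniquely placed; anomalous iff
cross-contig, not FR-inward (same strand, or everted with the (−) end left of
the (+) end), or separation > 1 kb.

**Pile-up null.** Anomalous pairs with one (+) and one (−) end are binned
(default 500 bp per axis) into a 2-D histogram. The null mean for cell (i,j)
is `T · p_i · q_j`, where T is the anomalous total and p, q are the
per-strand coverage marginals estimated from *all* uniquely aligned read
starts — the position-specific capture bias. Estimating the marginals from
the anomalous pairs themselves was considered and rejected: a genuine
junction cluster then dominates its own marginals (null mean ≈ T at the
cluster, destroying power), and under a uniform null every occupied cell has
p ≈ c/T so BH over occupied cells rejects everything. BH runs over every
cell with positive bias on both axes; significant cells merge with
8-connectivity. Clusters additionally require ≥ 3 supporting pairs: with
cell means of order 1e-2 the Poisson tail otherwise declares any chance
two-pair coincidence significant, and a support floor is the standard remedy
in discordant-pair structural-variant calling.

**Copy number.** After collapsing pairs with identical
(start, strand) × (start, strand) coordinates (PCR duplicates), unique read
starts are counted in 100 bp bins. The estimate is `ρ = 2·(t/T)/(n/N)`
(diploid-scaled), with the 95% CI computed exactly (Clopper–Pearson) on the
conditional proportion π = t/(t+n) and transformed monotonically to the ρ
scale, `ρ = 2·(π/(1−π))·(N/T)`. Bins with zero normal reads (or total depth
below a knob, default 1) are masked. Interior/exterior summaries exclude
bins within 200 bp of the breakpoints, where junction-crossing reads are
unalignable and depth dips for reasons unrelated to copy number.

**Rearrangement call.** A tandem duplication requires an everted cluster
((+) end downstream joined to (−) end upstream — reference join interval end
→ interval start) *and* a significant interior-vs-exterior step (two-sided
chi-square on pooled deduplicated counts, α = 0.01) with ratio > 1. The
expected heterozygous signature is 3/2. Copy-number variation (a run of ≥ 3
bins whose CI excludes diploid) without a usable cluster yields "unresolved"
— the case of a rearrangement whose junction the method cannot pin down.

**Orphan-end assembly.** Pairs with one unique mate within 20 kb of the
anchor and one unalignable mate contribute the unaligned mate, windowed by
the anchored mate's start (200 bp windows, (+) and (−) anchor classes
separate). The assembler builds a de Bruijn graph on k = 31 k-mers (both
orientations counted canonically), prunes k-mers below coverage 2, and emits
maximal unbranched paths in canonical orientation — deterministic and
independent of read order. Contigs are tiled into 80-mers (step 80, final
tile end-anchored) and classified against the reference by exact matching;
a contig with any reference-absent tile is scrutinized. Sample specificity
requires reads that are themselves reference-absent, match the contig
exactly, and overlap an absent tile by ≥ 20 nt, in exactly one sample.
Split alignment anchors the contig's first and last 31-mers uniquely in the
reference, extends both matches maximally, and reports the junction
left-aligned through any micro-homology; the simulator records truth in the
same canonical form, so recovered breakpoints are comparable base-exactly.
For the genome-wide blind-spot scan, 80-mers step by 1 and a tile with more
than 10 exact genome matches (both strands) is "blind". Exact matching (no
mismatches) is used for both screens.

## Cohort statistics

A sample is positive only when a strict majority of its technical replicates
(up to 6; variable n allowed) detect a product — ties are negative, accepting
false negatives rather than false positives. Prevalence pools per-site counts
and reports a Clopper–Pearson interval; report text rounds to the nearest
percent.

## Problem sizes

The test suite and reproduction script run everything at desk scale: a
~48 kb locus; RNA pools of 2×10^4–10^5 pairs; DNA libraries of 1.6×10^4
pairs (~40× deduplicated depth) with 20 simulation seeds for the
copy-number and breakpoint-recovery summaries and 100 rearrangement-free
replicates for the cluster-FDR check. These sizes give the statistical
resolution the checks need (binomial/Poisson error well inside the stated
tolerance bands) while keeping a full run in a couple of minutes on one CPU.

## Known limitations

- Gapless alignment: small indels near junctions would defeat both the
  transcriptome filter and the junction scan.
- The false-discovery null for RNA candidates is a declared reconstruction;
  its absolute q-values are tunable, though the ranking is not.
- The pile-up model assumes the two ends' positions are independent under
  the null given the bias; structured artifacts (e.g. segmental duplications)
  would violate this.
- Exact-match tiling and mappability ignore sequencing errors and SNPs; on
  real genomes a mismatch-tolerant mapper would be substituted.
- Copy-number CIs are per-bin and conditional; no segmentation or
  multi-sample smoothing is attempted.
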
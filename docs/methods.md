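# Methods

`ltrperturb` re-creates, at desk scale and on fully synthetic data, the
computational arc of a family-wide CRISPR perturbation study of a young
LTR (long terminal repeat) family: design a small multiplexed guide set
that reaches most copies of a divergent repeat family, verify that
short-read pairs can be assigned to individual copies, confirm targeting
with three-antibody consensus ChIP peaks, and measure the reciprocal,
distance-dependent consequences of activating or silencing the whole
family at once on host gene expression.  This note records the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## The synthetic study system

`simulate.SimConfig` holds every study condition.  The default system is
a scaled-down analogue of the human LTR5HS landscape:

| parameter | default | meaning |
|---|---|---|
| `consensus_length` | 968 bp | length of the family consensus (a solo-LTR scale) |
| `family_sizes` | LTR5HS 60, LTR5A 25, LTR5B 25, LTR5 10, LTR2 15 | one targeted family, two related decoys, a parental family, one unrelated family (the real family has ~700 copies; 60 preserves the structure at tractable cost) |
| `divergence` | 0.05 /bp | per-copy substitution rate from the consensus; a young family is a few percent diverged |
| `subfamily_identity` | 0.88 | identity of the decoy consensus to the target consensus |
| `chrom_lengths` | chr1 1.6 Mb, chr2 0.4 Mb | two chromosomes; repeats confined to segments so that large TSS distances exist |
| `nb_dispersion` | 0.02 | NB dispersion of counts; typical for clonal cell-line RNA-seq replicates |
| `replicates` | 2 | biological replicates per condition, as in the emulated experiments |
| `chip_fold` | 10 | fragment-midpoint enrichment at bound copies |
| `chip_background_rate` | 0.025 /bp | background fragments per bp per sample (~50k fragments per 2 Mb) |
| `bound_fraction` | 0.85 / 0.53 / 0.41 / 0.19 | planted bound fraction per family (target, decoys, parent) |
| `effect_max_activation` / `repression` | 3.0 / 3.5 (log2) | peak planted effect sizes, in the range reported for strongly responding host genes |

**Sequence model.**  Backgrounds are i.i.d. uniform ACGT, which makes
off-target probabilities analytically checkable.  Divergence is
substitution-only (uniform choice among the three other bases); an
analytic consequence used as a test oracle is that two copies at rate
*d* share identity `(1-d)^2 + d^2/3`.  Indels are deliberately absent so
the Hamming guide-match model is exact.  Real repeat families carry
indels, CpG-biased mutation and non-uniform base composition; passing
tests therefore certify the algorithms, not the biology of any real
genome.

**Gene placement.**  `gene_strata` requests `(n, d_min, d_max)` blocks
of genes by absolute TSS-to-nearest-copy distance.  The planted distance
is drawn first and the TSS is then sampled uniformly among all genome
positions that realise exactly that nearest-copy distance; this keeps
the planted distance distribution uniform over each stratum instead of
collapsing onto whichever copy happens to be closest.  The truth table
is always re-derivable from the emitted BED/GTF.

**Effect model.**  An enhancer-dependent gene responds with +e under
family-wide activation and -e' under repression.  The published analyses
show significant effects out to roughly 200 kb with no stated functional
form, so the simulator uses a transparent stand-in: full effect within
40 kb, linear decay to zero at `effect_range` (200 kb), zero beyond.
Conclusions that depend on the exact decay shape should not be read off
this simulator.

**Determinism.**  Every artifact draws from
`SeedSequence([master_seed, stream_offset])` with fixed per-artifact
offsets, so outputs are byte-reproducible given `(config, seed)` and any
single stage can be re-run without disturbing the others.

## Guide design

A candidate is every distinct 16-nt seed immediately 5' of an NGG PAM
(first base unconstrained, including N) on either strand, with the whole
19-bp window inside a targeted copy.  Genomic hits are Hamming matches
of the seed (no bulges) at 0-3 mismatches followed by a valid PAM; N in
the genome never matches.  Hits whose protospacer overlaps a masked
family (target + related decoys, mirroring the deliberate tolerance of
subfamily binding) are not counted as off-targets.  A
`require_pam=False` variant reproduces off-target counting without the
PAM constraint, since plain `-v`-style alignment would not check it.

"Lowest off-target rate" is operationalised as ascending lexicographic
order over the mismatch-stratified count vector `(m0, m1, m2, m3)` —
this dominates any monotone weighting — with ties broken by descending
zero-mismatch on-target copy count and then by sequence, making the
selection deterministic and permutation-invariant.  Whether the original
selection also rewarded coverage is unknowable from the text, so
coverage enters only as the tie-break by default (`prefer_coverage`
flips it).

The matcher uses a 4-mer pigeonhole index (any 16-mer within 3
mismatches of a window shares at least one exact aligned 4-mer chunk),
then verifies candidates exactly.  It is required — and tested — to be
bit-identical to a naive dense scan; the dense scanner lives only in the
test suite.

Coverage of a copy at level m means >= 1 PAM-valid hit with <= m
mismatches lying **within** the copy's interval (containment, matching
the per-insertion counting of alignments to extracted repeat
sequences), whereas off-target masking uses overlap.

## Paired-end mappability

For each copy, all fragments of 150-400 bp fully inside the copy
+/- 400 bp are enumerated; mate 1 is the first 150 bp, mate 2 the
reverse complement of the last 150 bp.  A pair is uniquely mappable when
its best concordant placement (both mates, correct orientation, fragment
size in range, minimal total mismatches) is unique and the runner-up
needs >= `min_margin` (default 2) more mismatches.  This replaces an
aligner-specific MAPQ > 20 rule with an aligner-independent, exhaustively
checkable criterion; the margin is configurable because the
correspondence to any particular MAPQ scale is approximate.  The search
is exact up to 4 total mismatches per pair; more distant placements are
ignored, which only matters for families diverged enough that 150-mers
collide at 5+ mismatches.

## ChIP peaks and consensus

Fragments are binned by midpoint (200 bp bins).  Per bin, the caller
computes a Poisson upper-tail p-value of the treatment count at
`lambda = max(genome-wide treatment mean, depth-scaled local control
mean over +/- 5 kb)`, applies Benjamini-Hochberg over all bins, and
merges significant bins bridging gaps of one bin.  This is a documented
functional stand-in for a full peak caller, whose exact parameters in
the emulated study are unknown; it is validated by calibration (null
simulations yield essentially zero three-antibody consensus peaks) and
recovery (planted bound copies found, bound fractions within +/- 5
points) rather than by output identity.

Consensus requires one mutually overlapping peak from each of the three
antibody sets; the consensus interval is the triple intersection and
each supporting peak is consumed at most once.  Peaks are assigned to
repeat families by a priority list (target first), contexts are
classified promoter > intragenic > intergenic with a strand-aware
-1000/+100 promoter window (a common default; the original annotation
tool does not print its definition), and unassigned peaks are split into
sequence-legitimate (overlapping a <= 3-mismatch PAM-valid guide hit) vs
nonspecific.

In the demo pipeline the planted per-copy enrichment scales with the
number of covering guides, emulating the observed coverage-to-binding
relationship, and the coverage/signal Spearman correlation is reported.

## Differential expression and distance analysis

The DE engine is a deliberately simple NB Wald test: median-of-ratios
size factors over all-positive genes; per-gene method-of-moments
dispersion from within-condition residual variance, floored at the
median of the gene's expression-decile stratum (moment estimates from
two replicates understate variance for about half the genes; the floor
keeps the test conservative without hurting strong effects); Wald z for
the log2 fold change of recruitment vs the two pooled control conditions
(pooling follows the emulated contrast definition; per-control contrasts
remain available by passing a single control label); BH across genes
with normalised mean >= 1.  It is validated by planted-effect recovery
and empirical FDR, not by agreement with any particular DE package.

A gene is *reciprocal* when significantly up under activation and down
under repression (FDR < 0.05 in both) — the operational enhancer
signature.  Distances are signed by gene orientation (negative =
promoter-upstream) from the TSS to the nearest targeted copy's centre,
ties toward the smaller coordinate.  Genes on chromosomes without any
targeted copy get infinite distance (a cross-chromosome distance has no
regulatory meaning); the decile universe is all expression-filtered
genes, the simplest defensible choice where the original universe is
unstated.

Distance-bin tests assign genes to 40-kb bins centred at
`round(signed/40k)*40k` (half away from zero) out to 400 kb; each bin's
log2 fold changes are compared with the pooled beyond-400 kb genes by a
two-sided Wilcoxon-Mann-Whitney test — exact subset enumeration with
average-rank ties for n <= 20, otherwise the tie-corrected normal
approximation with continuity correction.  The reference set (far pool
vs all other genes) is configurable; far pool is the default.  One
calibration remark: a truly null far bin is significant at the nominal
5% rate by construction, so profile checks aggregate over bins and
replicate runs rather than demanding every null bin be quiet in every
run.

Fisher's exact test (two-sided, sum of tables no more probable than the
observed) and Spearman's rho are delegated to scipy; the test suite
checks both against independent full-enumeration/rank-then-Pearson
oracles so the delegation is never load-bearing.

## Chimeric transcripts

TPM is count/exonic-length rates normalised to one million.  A
transcript is chimeric when its strand-aware 5' end lies in
`[copy.start - 100, copy.end + 100)` — the symmetric reading of "within
100 bp", with an `upstream_only` flag for the asymmetric reading — and
by default must be spliced (>= 2 exons); calls above 1 TPM are
"appreciable".  The rule is deterministic, so planted chimeras are
recovered with precision = recall = 1.

## Problem sizes and runtime

Default demo: 2 Mb genome, 135 repeat copies, ~4,100 seed candidates,
2,000 genes, three antibodies, two effectors; the full pipeline runs in
a few minutes on one core.  Mappability enumerates ~375k pairs per copy
and is run on an 8-copy subset in the demo (the per-copy fractions at
default divergence are all 1.0, so the subset is representative).  The
acceptance checks use 100 null ChIP simulations, a 2,000-gene recovery
experiment, and 50 replicate count simulations for the distance-bin
profile.

## Known limitations

- No indels, bulges, or realistic base composition; guide efficacy,
  chromatin accessibility and cutting efficiency are out of scope.
- The peak caller and DE test are transparent simplifications; numbers
  from real data will differ from dedicated tools even when the
  qualitative conclusions agree.
- The distance-decay form of the planted effect is a stand-in; only its
  range (200 kb) is anchored to the emulated study.
- Published headline figures (e.g. 635/697 copies covered, rho = 0.57,
  275 reciprocal genes) depend on the real genome, annotation and
  deposited sequencing data and are not reproduced numerically here;
  the pipeline reproduces the *procedures* and demonstrates them on
  synthetic data with known truth.
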
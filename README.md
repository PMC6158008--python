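# ltrperturb

Family-wide CRISPR perturbation analysis for repetitive elements.

Young LTR (long terminal repeat) retrotransposon families — hundreds of
diverged copies of a retroviral promoter/enhancer scattered through a
genome — are prime candidates for co-opted host enhancers, but they
cannot be studied one copy at a time.  The strategy this package
implements targets an entire family at once: design a minimal multiplex
of SpCas9 guide RNAs whose 16-nt PAM-proximal seeds collectively match
most copies of the family, recruit dCas9 activator (CRISPRa) or
repressor (CRISPRi) fusions to all of them, verify binding per copy by
three-antibody consensus ChIP peaks, and read out the host-gene
consequences as *reciprocal* expression changes (up under activation and
down under repression) resolved by the signed distance from each gene's
TSS to the nearest family copy.

`ltrperturb` is a tested re-implementation of that computational
pipeline, exercised end-to-end on seeded synthetic genomes with planted
ground truth:

- `ltrperturb.simulate` — seeded generator of genomes with a targeted
  repeat family plus ~88%-identical decoy subfamilies, genes at
  controlled TSS distances, three-antibody ChIP fragment sets, negative
  binomial count matrices with distance-decaying reciprocal effects, and
  spliced transcripts with planted LTR-origin chimeras;
- `ltrperturb.guides` — seed enumeration (16-mer + NGG), mismatch-
  stratified off-target scoring with family masking (exact-equivalent to
  a naive Hamming+PAM scan), deterministic top-k selection, per-copy
  coverage, and coverage/ChIP-signal Spearman correlation;
- `ltrperturb.mappability` — exhaustive paired-end read enumeration and
  a unique-best-with-margin placement rule standing in for MAPQ > 20;
- `ltrperturb.peaks` — binned Poisson window peak calling vs pooled
  controls, three-antibody consensus intersection, peak-to-repeat-family
  assignment, context classification, and anchor-centred signal
  matrices;
- `ltrperturb.expression` — NB Wald differential expression
  (recruitment vs pooled controls), reciprocal classification, signed
  nearest-copy distance annotation, distance deciles, 40-kb-bin
  rank-sum profiles, orientation summaries, and Fisher overlap
  enrichment;
- `ltrperturb.chimeric` — TPM and detection of transcripts whose
  strand-aware 5' end originates within 100 bp of a family copy.

The statistical core of the readout, per gene *g* with log2 fold
changes under the two effectors:

    reciprocal(g)  <=>  padj_a(g) < 0.05  and  lfc_a(g) > 0
                   and  padj_i(g) < 0.05  and  lfc_i(g) < 0

with BH-adjusted Wald p-values from a negative binomial model
(Var = mu + alpha*mu^2), and per 40-kb distance bin a two-sided
Wilcoxon–Mann–Whitney test of the bin's fold changes against genes more
than 400 kb from any copy.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
default synthetic system (2 Mb genome, 60 targeted copies, 2,000 genes,
seed 17) and narrate what they find:

```sh
python analysis/01_simulate_genome.py     # genome + repeats + genes + truth
python analysis/02_design_guides.py       # 12-guide multiplex design
python analysis/03_mappability.py         # per-copy paired-end mappability
python analysis/04_chip_peaks.py          # consensus peaks + bound fractions
python analysis/05_expression.py          # reciprocal DE + distance profile
python analysis/06_chimeric.py            # LTR-origin transcripts
```

Output of the design step:

```
4108 unique seed candidates; 12 selected (all with zero off-targets at 0-1 mismatches: True)
targeted-family coverage at 0 mm: >=1 guide 96.7%, >=2 guides 95.0%, >=4 guides 70.0%
decoy LTR5A: 4.0% of copies hit by >=1 guide at 0 mm (tolerated by design)
decoy LTR5B: 60.0% of copies hit by >=1 guide at 0 mm (tolerated by design)
```

Twelve guides suffice to cover nearly all 60 copies of the synthetic
family, most copies by several guides — the multiplexing premise.  The
expression step then reports:

```
2000 genes tested; 205 significant in both contrasts, 205 reciprocal
recovery vs planted truth: sensitivity 0.97, FDR 0.049
195/205 reciprocal genes fall in the nearest distance decile (95%)
activation bins significant vs far genes: centers [-160000, ..., 160000] (expected: within +/-200 kb)
nearest copy upstream/downstream of promoter: 115/90
```

The classifier recovers 97% of the planted enhancer targets at an
empirical FDR below 5%, the recovered genes concentrate in the nearest
distance decile, the distance-bin profile is significant out to the
planted 200 kb range and flat beyond, and the effects are split across
upstream/downstream placements and both orientations — the synthetic
analogue of long-range, orientation-independent enhancer action.  The
chimeric step finds only the four planted LTR-origin transcripts above
1 TPM, ruling out promoter read-through as the explanation.

Each stage is also exposed as a CLI over the same text formats
(FASTA/BED6/GTF-lite/TSV): `ltrperturb simulate|design|coverage|
mappability|peaks|consensus|annotate-peaks|matrix|de|classify|distance|
bins|chimeric|run-all`.

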
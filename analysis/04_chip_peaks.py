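#!/usr/bin/env python
"""Call recruitment binding sites from simulated three-antibody ChIP.

Simulates Poisson fragment pileups with planted 10x enrichment at the
bound copies (binding strength scaled with guide coverage), calls Poisson
window peaks for each antibody against the two matched controls, keeps
only intervals supported by all three antibodies, assigns them to repeat
families by priority, classifies the genomic context of each peak, and
correlates per-copy ChIP signal with the number of matching guides.
"""
import argparse
from pathlib import Path

import pandas as pd

from ltrperturb.guides import (
    GuideCandidate,
    correlate_coverage_with_signal,
    map_guides_to_instances,
)
from ltrperturb.io import read_bed_repeats, read_fasta, read_gtf_lite
from ltrperturb.peaks import (
    SignalTrack,
    assign_peaks_to_repeats,
    call_peaks,
    classify_offtarget_peaks,
    classify_peak_context,
    consensus_peaks,
)
from ltrperturb.simulate import SimConfig, choose_bound_instances, simulate_chip

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=17)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--guides", type=Path, default=Path("results/guides"))
parser.add_argument("--out", type=Path, default=Path("results/peaks"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

genome = read_fasta(args.data / "genome.fa")
instances = read_bed_repeats(args.data / "repeats.bed")
_tx, genes = read_gtf_lite(args.data / "genes.gtf")
seeds = pd.read_csv(args.guides / "selected_guides.tsv", sep="\t")["seed"].tolist()

cfg = SimConfig(seed=args.seed)
records, hits = map_guides_to_instances(
    [GuideCandidate(s) for s in seeds], genome, instances,
    ["LTR5HS", "LTR5A", "LTR5B"],
)
bound = choose_bound_instances(cfg, instances)
cov0 = {r.instance_id: r.guides_matching[0] for r in records}
max_cov = max(cov0.values()) or 1
fold = {i: 1.0 + (cfg.chip_fold - 1.0) * (0.25 + 0.75 * cov0.get(i, 0) / max_cov)
        for i in bound}

chip = simulate_chip(cfg, instances, bound, per_instance_fold=fold)
calls, track0 = [], None
for ab, d in chip.items():
    t = SignalTrack.from_fragments(d["treatment"], cfg.chrom_lengths, 200)
    track0 = track0 or t
    ctrls = [SignalTrack.from_fragments(c, cfg.chrom_lengths, 200)
             for c in d["controls"]]
    calls.append(call_peaks(t, ctrls, source=ab))
cons = consensus_peaks(*calls)
assign, fractions = assign_peaks_to_repeats(
    cons, instances, ["LTR5HS", "LTR5A", "LTR5B", "LTR5"]
)
context = classify_peak_context(cons, genes)
offtarget = [pk for pk, lab in zip(cons, assign["assigned_family"])
             if lab == "off-target"]
off_split = classify_offtarget_peaks(offtarget, hits)

signal = {}
for r in instances:
    if r.family != "LTR5HS":
        continue
    b0, b1 = r.start // 200, (r.end - 1) // 200
    signal[r.instance_id] = float(track0.counts[r.chrom][b0:b1 + 1].mean())
rho, n_rho = correlate_coverage_with_signal(
    [r for r in records if r.family == "LTR5HS"], signal, m=0
)

assign.to_csv(args.out / "peak_assignment.tsv", sep="\t", index=False)
fractions.to_csv(args.out / "bound_fractions.tsv", sep="\t", index=False)
context.to_csv(args.out / "peak_context.tsv", sep="\t", index=False)

print(f"peaks per antibody: {[len(c) for c in calls]}; "
      f"three-antibody consensus: {len(cons)}")
print(fractions.to_string(index=False))
print("peak context:", context["context"].value_counts().to_dict())
print(f"off-target peaks: {len(off_split['legitimate'])} sequence-legitimate, "
      f"{len(off_split['nonspecific'])} nonspecific")
print(f"Spearman rho (guide coverage vs ChIP signal, 0 mm): {rho:.2f} over "
      f"{n_rho} copies")
print(f"wrote peak tables -> {args.out}")
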
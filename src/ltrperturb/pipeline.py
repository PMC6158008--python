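"""End-to-end orchestration of the simulated perturbation study.

Stages run in dependency order: simulate -> guide design -> coverage ->
mappability -> ChIP peaks -> differential expression / distance analysis
-> chimeric transcripts.  Every stage is also invocable standalone (see
the CLI); the pipeline is composition, not a monolith.  All outputs are
deterministic given the config.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from .chimeric import compute_tpm, detect_chimeric
from .expression import (
    annotate_distance,
    classify_reciprocal,
    de_table,
    de_test,
    decile_analysis,
    distance_bin_tests,
    orientation_summary,
)
from .guides import (
    GenomeIndex,
    coverage_summary,
    correlate_coverage_with_signal,
    enumerate_seed_candidates,
    map_guides_to_instances,
    score_offtargets,
    select_guides,
)
from .io import (
    write_bed_repeats,
    write_counts_tsv,
    write_fasta,
    write_fragments_bed,
    write_gtf_lite,
)
from .mappability import mappability_for_instances
from .peaks import (
    SignalTrack,
    assign_peaks_to_repeats,
    call_peaks,
    classify_offtarget_peaks,
    classify_peak_context,
    consensus_peaks,
)
from .simulate import (
    SimConfig,
    choose_bound_instances,
    simulate_chip,
    simulate_counts,
    simulate_genes,
    simulate_repeat_genome,
    simulate_transcripts,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "results/run"
    k_guides: int = 12
    max_mm: int = 3
    coverage_thresholds: tuple[int, ...] = (1, 2, 4)
    peak_bin_width: int = 200
    peak_alpha: float = 0.05
    promoter_window: tuple[int, int] = (-1000, 100)
    mappability_instances: int = 8
    de_alpha: float = 0.05
    bin_test_width: int = 40_000
    bin_test_max: int = 400_000
    chimeric_window: int = 100
    tpm_min: float = 1.0

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sim_data = data.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim_data) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
        return cls(sim=SimConfig(**sim_data), **data)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                log.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_all(config: PipelineConfig, seed: Optional[int] = None) -> dict[str, Any]:
    """Run every stage; write per-stage outputs plus a summary under out_dir."""
    if seed is not None:
        config.sim.seed = int(seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    (out / "run_log.txt").write_text(
        f"ltrperturb {__version__}\n"
        f"config_sha256 {hashlib.sha256(cfg_json.encode()).hexdigest()}\n"
        f"master_seed {config.sim.seed}\n"
        f"config {cfg_json}\n"
    )
    summary: dict[str, Any] = {"seed": config.sim.seed}

    genome, instances, truth = _stage("simulate")(_simulate)(config, out)
    genes, truth = _stage("genes")(_genes)(config, instances, truth, out)
    gidx = GenomeIndex(genome)
    design = _stage("design")(_design)(config, genome, gidx, instances, out)
    summary.update(design["summary"])
    mapp = _stage("mappability")(_mappability)(config, genome, instances, out)
    summary.update(mapp)
    chip = _stage("peaks")(_chip)(config, genome, instances, genes, design, out)
    summary.update(chip)
    expr = _stage("expression")(_expression)(config, genes, instances, truth, out)
    summary.update(expr)
    chim = _stage("chimeric")(_chimeric)(config, genes, instances, truth, out)
    summary.update(chim)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    _write_summary_md(summary, out / "summary.md")
    return summary


def _simulate(config: PipelineConfig, out: Path):
    genome, instances, truth = simulate_repeat_genome(config.sim)
    write_fasta(genome, out / "genome.fa")
    write_bed_repeats(instances, out / "repeats.bed")
    return genome, instances, truth


def _genes(config: PipelineConfig, instances, truth, out: Path):
    genes, truth = simulate_genes(config.sim, instances, truth)
    truth.gene_effects.to_csv(out / "gene_truth.tsv", sep="\t")
    return genes, truth


def _design(config: PipelineConfig, genome, gidx, instances, out: Path):
    sim = config.sim
    candidates = enumerate_seed_candidates(genome, instances, sim.target_family)
    masked = [sim.target_family, *[f for f in sim.related_families if f != "LTR5"]]
    scored = score_offtargets(
        candidates, genome, masked, instances, config.max_mm,
        target_family=sim.target_family, index=gidx,
    )
    selected = select_guides(scored, config.k_guides)
    fams = [sim.target_family, *sim.related_families]
    records, hits = map_guides_to_instances(
        selected, genome, instances, fams, config.max_mm, index=gidx
    )
    summ = coverage_summary(records, config.coverage_thresholds)
    summ.to_csv(out / "coverage_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "seed": [c.seed_seq for c in scored],
            **{f"offtarget_mm{m}": [c.offtarget_counts[m] for c in scored] for m in range(4)},
            **{f"ontarget_le_mm{m}": [c.ontarget_instances[m] for c in scored] for m in range(4)},
        }
    ).to_csv(out / "guide_candidates.tsv", sep="\t", index=False)
    with open(out / "guides.fa", "w") as fh:
        for i, g in enumerate(selected):
            fh.write(f">guide_{i:02d}\n{g.seed_seq}\n")
    with open(out / "guide_hits.bed", "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.guide}\t{h.mismatches}\t"
                f"{h.strand}\t{int(h.pam_valid)}\n"
            )
    target_cov = summ[summ["family"] == sim.target_family]
    pick = lambda m, t: float(
        target_cov[(target_cov["mismatches"] == m) & (target_cov["threshold"] == t)][
            "fraction"
        ].iloc[0]
    )
    return {
        "selected": selected,
        "records": records,
        "hits": hits,
        "summary": {
            "n_candidates": len(candidates),
            "n_selected": len(selected),
            "target_cov_ge1_mm0": pick(0, 1),
            "target_cov_ge2_mm0": pick(0, 2),
            "target_cov_ge4_mm0": pick(0, 4),
        },
    }


def _mappability(config: PipelineConfig, genome, instances, out: Path):
    targets = [r for r in instances if r.family == config.sim.target_family]
    subset = targets[: config.mappability_instances]
    results = mappability_for_instances(genome, subset)
    pd.DataFrame(
        {
            "instance_id": [r.instance_id for r in results],
            "n_pairs": [r.n_pairs_enumerated for r in results],
            "n_unique": [r.n_unique for r in results],
            "fraction": [r.fraction_unique for r in results],
        }
    ).to_csv(out / "mappability.tsv", sep="\t", index=False)
    return {
        "mappability_mean_fraction": float(
            np.mean([r.fraction_unique for r in results])
        ),
        "mappability_n_instances": len(results),
    }


def _chip(config: PipelineConfig, genome, instances, genes, design, out: Path):
    sim = config.sim
    bound = choose_bound_instances(sim, instances)
    # enrichment scales with how many selected guides cover the instance,
    # emulating the observed coverage/binding relationship
    cov0 = {r.instance_id: r.guides_matching[0] for r in design["records"]}
    max_cov = max(cov0.values()) if cov0 else 1
    fold = {
        iid: 1.0 + (sim.chip_fold - 1.0) * (0.25 + 0.75 * cov0.get(iid, 0) / max(1, max_cov))
        for iid in bound
    }
    chip = simulate_chip(sim, instances, bound, per_instance_fold=fold)
    calls_by_ab = []
    tracks = {}
    for ab, data in chip.items():
        t = SignalTrack.from_fragments(data["treatment"], sim.chrom_lengths, config.peak_bin_width)
        ctrls = [
            SignalTrack.from_fragments(c, sim.chrom_lengths, config.peak_bin_width)
            for c in data["controls"]
        ]
        tracks[ab] = t
        calls_by_ab.append(call_peaks(t, ctrls, config.peak_alpha, source=ab))
        write_fragments_bed(data["treatment"], out / f"chip_{ab}_treatment.bed")
    cons = consensus_peaks(*calls_by_ab)
    with open(out / "consensus_peaks.bed", "w") as fh:
        for pk in cons:
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\tconsensus\t{pk.max_score:.3f}\t.\n")
    priority = [sim.target_family, *sim.related_families]
    assign, fractions = assign_peaks_to_repeats(cons, instances, priority)
    assign.to_csv(out / "peak_assignment.tsv", sep="\t", index=False)
    fractions.to_csv(out / "bound_fractions.tsv", sep="\t", index=False)
    offtarget = [
        pk for pk, lab in zip(cons, assign["assigned_family"]) if lab == "off-target"
    ]
    off_split = classify_offtarget_peaks(offtarget, design["hits"], config.max_mm)
    context = classify_peak_context(cons, genes, config.promoter_window)
    context.to_csv(out / "peak_context.tsv", sep="\t", index=False)

    # per-instance ChIP signal = mean treatment coverage over the instance
    ab0 = list(tracks)[0]
    t0 = tracks[ab0]
    signal = {}
    for r in instances:
        if r.family != sim.target_family:
            continue
        b0, b1 = r.start // t0.bin_width, (r.end - 1) // t0.bin_width
        signal[r.instance_id] = float(t0.counts[r.chrom][b0 : b1 + 1].mean())
    rho, n_rho = correlate_coverage_with_signal(design["records"], signal, m=0)

    target_frac = float(
        fractions.loc[fractions["family"] == sim.target_family, "bound_fraction"].iloc[0]
    )
    planted_frac = len(
        [i for i in bound if i.startswith(sim.target_family)]
    ) / max(1, len([r for r in instances if r.family == sim.target_family]))
    ctx_counts = context["context"].value_counts()
    return {
        "n_consensus_peaks": len(cons),
        "bound_fraction_target": target_frac,
        "planted_bound_fraction_target": planted_frac,
        "offtarget_peaks_legitimate": len(off_split["legitimate"]),
        "offtarget_peaks_nonspecific": len(off_split["nonspecific"]),
        "peak_context_counts": {k: int(v) for k, v in ctx_counts.items()},
        "spearman_rho_mm0": rho,
        "spearman_n": n_rho,
    }


def _expression(config: PipelineConfig, genes, instances, truth, out: Path):
    sim = config.sim
    act = simulate_counts(sim, genes, truth, "activation")
    rep = simulate_counts(sim, genes, truth, "repression")
    write_counts_tsv(act, out / "counts_activation.tsv", out / "samples_activation.tsv")
    write_counts_tsv(rep, out / "counts_repression.tsv", out / "samples_repression.tsv")
    de_a = de_test(act)
    de_i = de_test(rep)
    de = de_table(de_a, de_i)
    de.to_csv(out / "de_table.tsv", sep="\t")
    labels = classify_reciprocal(de, config.de_alpha)
    distances = annotate_distance(genes, instances, sim.target_family)
    distances.to_csv(out / "distance_annotation.tsv", sep="\t")
    tested = labels[de["tested"]]
    deciles = decile_analysis(tested, distances)
    deciles.to_csv(out / "decile_table.tsv", sep="\t")
    bins = distance_bin_tests(
        de[de["tested"]], distances, "lfc_a", config.bin_test_width, config.bin_test_max
    )
    pd.DataFrame(
        {
            "center": [b.center for b in bins],
            "n_genes": [b.n_genes for b in bins],
            "median_lfc": [b.median_lfc for b in bins],
            "pvalue": [b.pvalue for b in bins],
        }
    ).to_csv(out / "distance_bin_tests.tsv", sep="\t", index=False)
    recip = labels[labels == "reciprocal"].index.tolist()
    orient = orientation_summary(recip, distances)
    orient.to_csv(out / "orientation_summary.tsv", sep="\t")

    n_recip = len(recip)
    first_decile = 0
    if n_recip and "reciprocal" in deciles.columns:
        first_decile = int(deciles.loc[1, "reciprocal"])
    labels.to_frame().to_csv(out / "reciprocal_labels.tsv", sep="\t")
    return {
        "n_genes_tested": int(de["tested"].sum()),
        "n_both_significant": int(
            ((de["padj_a"] < config.de_alpha) & (de["padj_i"] < config.de_alpha)).sum()
        ),
        "n_reciprocal": n_recip,
        "reciprocal_in_first_decile": first_decile,
        "upstream_count": int(orient.loc["upstream"].sum()),
        "downstream_count": int(orient.loc["downstream"].sum()),
    }


def _chimeric(config: PipelineConfig, genes, instances, truth, out: Path):
    transcripts, truth = simulate_transcripts(config.sim, genes, instances, truth)
    write_gtf_lite(transcripts, out / "transcripts.gtf")
    compute_tpm(transcripts)
    calls = detect_chimeric(
        transcripts, instances, config.sim.target_family,
        window=config.chimeric_window, tpm_min=config.tpm_min,
    )
    pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "instance_id": [c.instance_id for c in calls],
            "offset": [c.offset for c in calls],
            "tpm": [c.tpm for c in calls],
            "appreciable": [c.appreciable for c in calls],
        }
    ).to_csv(out / "chimeric_calls.tsv", sep="\t", index=False)
    return {
        "n_chimeric_calls": len(calls),
        "n_chimeric_appreciable": sum(1 for c in calls if c.appreciable),
    }


def _write_summary_md(summary: dict[str, Any], path: Path) -> None:
    lines = ["# Pipeline summary", ""]
    for k in sorted(summary):
        lines.append(f"- {k}: {summary[k]}")
    path.write_text("\n".join(lines) + "\n")
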
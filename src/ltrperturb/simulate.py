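"""Seeded simulator for every downstream stage.

Emulates the study system at desk scale: one young, targeted LTR family
plus related decoy subfamilies at ~88% identity and an unrelated repeat
family, inserted into an i.i.d. uniform ACGT background; genes with TSS
placed at controlled distances from the targeted family; three-antibody
ChIP fragment sets with planted enrichment at bound instances; negative
binomial count matrices for recruitment vs two control conditions with
planted, distance-decaying reciprocal enhancer effects; and spliced
transcript models, a few of which originate inside or next to an instance.

All outputs are fully determined by (config, seed): each artifact draws
from its own RNG stream derived from the master seed by a fixed offset.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneModel,
    GenomeSequence,
    RepeatInstance,
    TranscriptModel,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed per-artifact stream offsets (master seed + offset -> independent RNG)
_STREAMS = {
    "genome": 1,
    "genes": 2,
    "chip": 3,
    "counts_activation": 4,
    "counts_repression": 5,
    "transcripts": 6,
}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), _STREAMS[stream], int(extra)])
    )


# Default gene strata: (n_genes, min |distance| bp, max |distance| bp) from
# the TSS to the center of the nearest targeted instance.  Covers <2 kb out
# to >1 Mb on both sides/strands, mirroring the published distance spread.
DEFAULT_GENE_STRATA: tuple[tuple[int, int, int], ...] = (
    (40, 500, 2_000),
    (160, 2_000, 140_000),
    (100, 150_000, 220_000),
    (200, 220_000, 420_000),
    (500, 420_000, 700_000),
    (1000, 700_000, 1_150_000),
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic system.

    The defaults are the scaled-down analogue of the published setting:
    60 copies of the targeted family (vs 697 genome-wide), two related
    decoy subfamilies at the 0.88 identity target plus a small parental
    family and one unrelated LTR family, 5% within-family divergence,
    2,000 genes, two replicates per condition, and 10x ChIP enrichment at
    bound copies.
    """

    seed: int = 17
    consensus_length: int = 968
    family_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "LTR5HS": 60, "LTR5A": 25, "LTR5B": 25, "LTR5": 10, "LTR2": 15,
        }
    )
    target_family: str = "LTR5HS"
    related_families: tuple[str, ...] = ("LTR5A", "LTR5B", "LTR5")
    divergence: float = 0.05
    subfamily_identity: float = 0.88
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_600_000, "chr2": 400_000}
    )
    repeat_segments: dict[str, list[tuple[int, int]]] = field(
        default_factory=lambda: {
            "chr1": [(60_000, 400_000)],
            "chr2": [(100_000, 300_000)],
        }
    )
    gene_strata: tuple[tuple[int, int, int], ...] = DEFAULT_GENE_STRATA
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    # enhancer effect model: full effect inside effect_full_range, linear
    # decay to zero at effect_range, zero beyond
    effect_max_activation: float = 3.0
    effect_max_repression: float = 3.5
    effect_full_range: int = 40_000
    effect_range: int = 200_000
    baseline_log_mean: float = 4.6  # ln scale; exp(4.6) ~ 100 counts
    baseline_log_sd: float = 1.0
    baseline_min: float = 5.0
    nb_dispersion: float = 0.02
    replicates: int = 2
    library_factor_range: tuple[float, float] = (0.7, 1.3)
    # ChIP model
    frag_min: int = 150
    frag_max: int = 400
    chip_background_rate: float = 0.025  # fragments per bp per sample
    chip_fold: float = 10.0
    bound_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "LTR5HS": 0.85, "LTR5A": 0.53, "LTR5B": 0.41, "LTR5": 0.19, "LTR2": 0.0,
        }
    )
    antibodies: tuple[str, ...] = ("Cas9", "GFP_a", "GFP_b")
    # transcript model
    n_transcribed_genes: int = 300
    n_chimeric: int = 4

    def validate(self) -> None:
        for name, rate in (
            ("divergence", self.divergence),
            ("subfamily_identity", self.subfamily_identity),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        for fam, frac in self.bound_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"bound_fraction[{fam}] outside [0, 1]")
        if self.chip_fold < 1.0:
            raise ValueError("chip_fold must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.target_family not in self.family_sizes:
            raise ValueError("target_family missing from family_sizes")
        if self.frag_min > self.frag_max:
            raise ValueError("frag_min > frag_max")


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests downstream."""

    bound_instances: set[str] = field(default_factory=set)
    gene_effects: Optional[pd.DataFrame] = None  # indexed by gene_id
    chimeric_transcripts: set[str] = field(default_factory=set)
    guide_plan: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# genome + repeat landscape (all sequence work in 0..3 code space)

def _mutate(rng: np.random.Generator, enc: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base with probability `rate` to a uniform other base."""
    out = enc.copy()
    hit = rng.random(len(enc)) < rate
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


def _revcomp_codes(enc: np.ndarray) -> np.ndarray:
    return (3 - enc)[::-1].astype(np.uint8)


def _decode(enc: np.ndarray) -> str:
    return _BASES[enc].tobytes().decode()


def expected_pairwise_identity(divergence: float) -> float:
    """Closed-form mean identity between two copies mutated independently
    from the same consensus at the given per-bp substitution rate (uniform
    choice among the three other bases)."""
    d = divergence
    return (1 - d) ** 2 + d * d / 3.0


def simulate_repeat_genome(
    config: SimConfig,
) -> tuple[GenomeSequence, list[RepeatInstance], SimTruth]:
    """Random background genome with mutated-consensus repeat copies planted.

    Related subfamilies share a consensus diverged to the subfamily identity
    target; unrelated families get an independent consensus.  Instances are
    placed without overlap inside the configured repeat segments, on random
    strands.  Deterministic given (config, seed).
    """
    config.validate()
    rng = _rng(config.seed, "genome")
    L = config.consensus_length

    target_cons = rng.integers(0, 4, size=L).astype(np.uint8)
    consensi: dict[str, np.ndarray] = {config.target_family: target_cons}
    for fam in sorted(config.family_sizes):
        if fam == config.target_family:
            continue
        if fam in config.related_families:
            consensi[fam] = _mutate(rng, target_cons, 1.0 - config.subfamily_identity)
        else:
            consensi[fam] = rng.integers(0, 4, size=L).astype(np.uint8)

    chrom_enc = {
        c: rng.integers(0, 4, size=n).astype(np.uint8)
        for c, n in config.chrom_lengths.items()
    }

    segments = [
        (chrom, s, e)
        for chrom in sorted(config.repeat_segments)
        for s, e in config.repeat_segments[chrom]
        if chrom in chrom_enc
    ]
    if not segments:
        raise ValueError("no repeat segments on any configured chromosome")
    seg_weights = np.array([e - s for _, s, e in segments], dtype=float)
    seg_weights /= seg_weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_enc}

    jobs = [
        (fam, i)
        for fam in sorted(config.family_sizes)
        for i in range(config.family_sizes[fam])
    ]
    rng.shuffle(jobs)

    instances: list[RepeatInstance] = []
    for fam, i in jobs:
        placed = False
        for _ in range(2000):
            si = int(rng.choice(len(segments), p=seg_weights))
            chrom, s0, e0 = segments[si]
            if e0 - s0 < L:
                continue
            start = int(rng.integers(s0, e0 - L))
            end = start + L
            if any(start < oe and os_ < end for os_, oe in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            inst_enc = _mutate(rng, consensi[fam], config.divergence)
            if strand == "-":
                inst_enc = _revcomp_codes(inst_enc)
            chrom_enc[chrom][start:end] = inst_enc
            instances.append(
                RepeatInstance(chrom, start, end, strand, fam, f"{fam}_{i:04d}")
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place {fam} instance without overlap; "
                "increase the genome length or the repeat segments"
            )

    genome = GenomeSequence({c: _decode(enc) for c, enc in chrom_enc.items()})
    instances.sort(key=lambda r: (r.chrom, r.start, r.end, r.instance_id))
    return genome, instances, SimTruth()


# ---------------------------------------------------------------------------
# genes at controlled distances

def _effect_at(config: SimConfig, dist: float) -> float:
    """Distance decay of the planted enhancer effect in [0, 1].

    Full effect inside effect_full_range, linear decay to zero at
    effect_range, zero beyond.  The published work does not state a
    functional form; this shape is a stand-in (see docs/methods.md).
    """
    d = abs(dist)
    if d <= config.effect_full_range:
        return 1.0
    if d >= config.effect_range:
        return 0.0
    return (config.effect_range - d) / (config.effect_range - config.effect_full_range)


def simulate_genes(
    config: SimConfig,
    instances: list[RepeatInstance],
    truth: Optional[SimTruth] = None,
) -> tuple[list[GeneModel], SimTruth]:
    """Place gene TSS so planted |distance| strata are hit exactly.

    The realised nearest-instance distance (over all targeted-family copies
    on the gene's chromosome) is recomputed after placement and must fall in
    the requested stratum, so the emitted truth table is always consistent
    with the emitted annotation.  Planted enhancer effects follow the
    distance-decay model; the truth table stores signed distance, nearest
    instance, and the activation/repression effects (log2 units).
    """
    config.validate()
    rng = _rng(config.seed, "genes")
    targets = [r for r in instances if r.family == config.target_family]
    if not targets:
        raise ValueError(f"no instances of target family {config.target_family}")
    centers_by_chrom: dict[str, np.ndarray] = {}
    strands_by_chrom: dict[str, list[str]] = {}
    ids_by_chrom: dict[str, list[str]] = {}
    for chrom in sorted({r.chrom for r in targets}):
        rows = [r for r in targets if r.chrom == chrom]
        rows.sort(key=lambda r: r.center)
        centers_by_chrom[chrom] = np.array([r.center for r in rows])
        strands_by_chrom[chrom] = [r.strand for r in rows]
        ids_by_chrom[chrom] = [r.instance_id for r in rows]
    chroms = sorted(centers_by_chrom)

    genes: list[GeneModel] = []
    rows = []
    gidx = 0
    for n, dmin, dmax in config.gene_strata:
        for _ in range(n):
            placed = False
            for _try in range(200):
                # draw the planted distance first, then enumerate every TSS
                # position realising exactly that nearest-instance distance;
                # this keeps the planted distances uniform over the stratum
                # instead of piling up near whichever instance is closest
                d_req = int(rng.integers(dmin, dmax + 1))
                cand: list[tuple[str, int, int]] = []  # (chrom, tss, instance idx)
                for chrom in chroms:
                    centers = centers_by_chrom[chrom]
                    clen = config.chrom_lengths[chrom]
                    for side in (-1, 1):
                        tss_arr = centers + side * d_req
                        ok = (tss_arr >= 0) & (tss_arr < clen)
                        for k in np.flatnonzero(ok):
                            tss_c = int(tss_arr[k])
                            j = int(np.searchsorted(centers, tss_c))
                            near = min(
                                abs(tss_c - int(centers[kk]))
                                for kk in (j - 1, j)
                                if 0 <= kk < len(centers)
                            )
                            if near == d_req:
                                cand.append((chrom, tss_c, int(k)))
                if not cand:
                    continue
                chrom, tss, best_k = cand[int(rng.integers(len(cand)))]
                centers = centers_by_chrom[chrom]
                clen = config.chrom_lengths[chrom]
                # tie-break the nearest instance toward smaller coordinate
                j = int(np.searchsorted(centers, tss))
                best_d = None
                for k in (j - 1, j):
                    if 0 <= k < len(centers):
                        d = abs(tss - int(centers[k]))
                        if best_d is None or d < best_d:
                            best_k, best_d = k, d
                strand = "+" if rng.random() < 0.5 else "-"
                glen = int(rng.integers(*config.gene_length_range))
                if strand == "+":
                    span = (tss, min(clen, tss + glen))
                else:
                    span = (max(0, tss - glen + 1), tss + 1)
                gene_id = f"g{gidx:04d}"
                genes.append(GeneModel(gene_id, chrom, strand, tss, span))
                nearest = ids_by_chrom[chrom][best_k]
                inst_strand = strands_by_chrom[chrom][best_k]
                signed = (int(centers[best_k]) - tss) * (1 if strand == "+" else -1)
                scale = _effect_at(config, best_d)
                rows.append(
                    {
                        "gene_id": gene_id,
                        "chrom": chrom,
                        "strand": strand,
                        "tss": tss,
                        "nearest_instance": nearest,
                        "instance_strand": inst_strand,
                        "signed_distance": signed,
                        "abs_distance": best_d,
                        "act_effect": scale * config.effect_max_activation,
                        "rep_effect": -scale * config.effect_max_repression,
                    }
                )
                gidx += 1
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"cannot satisfy distance stratum [{dmin}, {dmax}] on this genome"
                )

    table = pd.DataFrame(rows).set_index("gene_id")
    # baseline expression drawn here so counts share it across effectors
    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(table)))
    table["baseline"] = np.maximum(base, config.baseline_min)
    truth = truth or SimTruth()
    truth.gene_effects = table
    return genes, truth


# ---------------------------------------------------------------------------
# ChIP fragments

Fragments = dict[str, np.ndarray]  # chrom -> (n, 2) start/end


def _draw_fragments(
    rng: np.random.Generator, config: SimConfig, chrom: str, n: int, lo: int, hi: int
) -> np.ndarray:
    """n fragments with midpoints uniform in [lo, hi) and uniform lengths."""
    if n <= 0:
        return np.empty((0, 2), dtype=np.int64)
    mids = rng.integers(lo, max(lo + 1, hi), size=n)
    lens = rng.integers(config.frag_min, config.frag_max + 1, size=n)
    clen = config.chrom_lengths[chrom]
    starts = np.clip(mids - lens // 2, 0, clen - 1)
    ends = np.clip(starts + lens, starts + 1, clen)
    return np.stack([starts, ends], axis=1).astype(np.int64)


def choose_bound_instances(
    config: SimConfig, instances: list[RepeatInstance]
) -> set[str]:
    """Sample the planted bound set per family at the configured fractions."""
    rng = _rng(config.seed, "chip", extra=999)
    bound: set[str] = set()
    for fam in sorted(config.bound_fraction):
        frac = config.bound_fraction[fam]
        members = sorted(
            (r.instance_id for r in instances if r.family == fam)
        )
        k = int(round(frac * len(members)))
        if k:
            bound.update(rng.choice(members, size=k, replace=False).tolist())
    return bound


def simulate_chip(
    config: SimConfig,
    instances: list[RepeatInstance],
    bound_instances: set[str],
    per_instance_fold: Optional[dict[str, float]] = None,
) -> dict[str, dict[str, object]]:
    """Three pseudo-antibody ChIP experiments sharing one bound set.

    Each antibody gets a treatment fragment set (Poisson background plus
    planted enrichment centred on bound instances, midpoint rate fold x
    background inside the instance) and two matched background-only control
    sets.  Independent noise per antibody; fold < 1 is an error.
    """
    config.validate()
    by_id = {r.instance_id: r for r in instances}
    unknown = bound_instances - set(by_id)
    if unknown:
        raise ValueError(f"bound ids not in annotation: {sorted(unknown)[:3]}...")
    folds = {iid: config.chip_fold for iid in bound_instances}
    if per_instance_fold:
        folds.update({k: float(v) for k, v in per_instance_fold.items() if k in folds})
    if any(f < 1.0 for f in folds.values()):
        raise ValueError("per-instance fold must be >= 1")

    out: dict[str, dict[str, object]] = {}
    for ai, antibody in enumerate(config.antibodies):
        rng = _rng(config.seed, "chip", extra=ai)
        sets: list[Fragments] = []
        for _rep in range(3):  # treatment + 2 controls
            frags: Fragments = {}
            for chrom in sorted(config.chrom_lengths):
                clen = config.chrom_lengths[chrom]
                n_bg = rng.poisson(config.chip_background_rate * clen)
                frags[chrom] = _draw_fragments(rng, config, chrom, n_bg, 0, clen)
            sets.append(frags)
        # enrichment only on the treatment set
        treatment = sets[0]
        for iid in sorted(bound_instances):
            inst = by_id[iid]
            extra_rate = (folds[iid] - 1.0) * config.chip_background_rate
            n_extra = rng.poisson(extra_rate * inst.length)
            extra = _draw_fragments(rng, config, inst.chrom, n_extra, inst.start, inst.end)
            treatment[inst.chrom] = np.concatenate([treatment[inst.chrom], extra])
        out[antibody] = {"treatment": sets[0], "controls": [sets[1], sets[2]]}
    return out


# ---------------------------------------------------------------------------
# count matrices

def simulate_counts(
    config: SimConfig,
    genes: list[GeneModel],
    truth: SimTruth,
    effector: str,
) -> CountMatrix:
    """NB count matrix for one effector (activation or repression).

    Recruitment samples get mean baseline * 2^effect; both control
    conditions get the baseline.  Per-sample library factors exercise the
    size-factor estimation downstream.  Deterministic given (config, seed).
    """
    if effector not in ("activation", "repression"):
        raise ValueError("effector must be 'activation' or 'repression'")
    if truth.gene_effects is None:
        raise ValueError("truth has no gene effects; run simulate_genes first")
    table = truth.gene_effects
    gene_ids = [g.gene_id for g in genes]
    baseline = table.loc[gene_ids, "baseline"].to_numpy(float)
    if (baseline <= 0).any():
        raise ValueError("non-positive baseline expression")
    effect = table.loc[
        gene_ids, "act_effect" if effector == "activation" else "rep_effect"
    ].to_numpy(float)

    rng = _rng(config.seed, f"counts_{effector}")
    conditions = ["recruitment", "control_a", "control_b"]
    sample_ids, cond_map, cols = [], {}, []
    lo, hi = config.library_factor_range
    for cond in conditions:
        for r in range(config.replicates):
            sid = f"{effector}_{cond}_r{r + 1}"
            sample_ids.append(sid)
            cond_map[sid] = cond
            lib = rng.uniform(lo, hi)
            mu = baseline * (2.0 ** effect if cond == "recruitment" else 1.0) * lib
            if config.nb_dispersion > 0:
                size = 1.0 / config.nb_dispersion
                counts = rng.negative_binomial(size, size / (size + mu))
            else:
                counts = rng.poisson(mu)
            cols.append(counts.astype(int))
    df = pd.DataFrame(
        np.stack(cols, axis=1), index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )
    return CountMatrix(df, cond_map)


# ---------------------------------------------------------------------------
# transcripts (for the chimeric stage)

def simulate_transcripts(
    config: SimConfig,
    genes: list[GeneModel],
    instances: list[RepeatInstance],
    truth: SimTruth,
) -> tuple[list[TranscriptModel], SimTruth]:
    """Spliced transcript models with a few planted LTR-origin chimeras.

    Most transcripts sit inside gene spans.  n_chimeric transcripts have
    their strand-aware 5' end inside a targeted instance, and two decoys
    start just beyond the 100 bp detection window to exercise the boundary.
    Counts are drawn so planted chimeras exceed TPM 1 after normalisation.
    """
    rng = _rng(config.seed, "transcripts")
    targets = [r for r in instances if r.family == config.target_family]
    transcripts: list[TranscriptModel] = []

    n_tr = min(config.n_transcribed_genes, len(genes))
    chosen = rng.choice(len(genes), size=n_tr, replace=False)
    for k in sorted(chosen.tolist()):
        g = genes[k]
        s, e = g.span
        n_ex = int(rng.integers(1, 4))
        # exon skeleton laid 5'->3' from the TSS
        cuts = np.sort(rng.integers(s, e, size=2 * n_ex))
        exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1]) + 1) for i in range(n_ex)]
        exons = [(a, b) for a, b in exons if a < b]
        if not exons:
            exons = [(s, e)]
        # anchor 5' end to the TSS
        if g.strand == "+":
            exons[0] = (g.tss, max(exons[0][1], g.tss + 1))
        else:
            exons[-1] = (min(exons[-1][0], g.tss), g.tss + 1)
        try:
            t = TranscriptModel(
                f"t_{g.gene_id}", g.gene_id, g.chrom, g.strand, exons,
                count=float(rng.integers(10, 2000)),
            )
        except ValueError:
            t = TranscriptModel(
                f"t_{g.gene_id}", g.gene_id, g.chrom, g.strand, [(s, e)],
                count=float(rng.integers(10, 2000)),
            )
        transcripts.append(t)

    chimeric_ids: set[str] = set()
    n_chim = min(config.n_chimeric, len(targets))
    picked = rng.choice(len(targets), size=n_chim + 2, replace=False)
    clen_by = dict(config.chrom_lengths)
    for j, pi in enumerate(picked.tolist()):
        inst = targets[pi]
        clen = clen_by[inst.chrom]
        decoy = j >= n_chim
        # 5' end inside the instance (chimeric) or 150 bp upstream (decoy,
        # outside the 100 bp window)
        if decoy:
            start5 = max(0, inst.start - 150)
        else:
            start5 = int(rng.integers(inst.start, inst.end))
        exon1 = (start5, min(clen, start5 + int(rng.integers(200, 600))))
        gap = int(rng.integers(200, 2000))
        e2s = min(clen - 2, exon1[1] + gap)
        exon2 = (e2s, min(clen, e2s + int(rng.integers(200, 600))))
        tid = f"chim_{j}" if not decoy else f"near_{j}"
        t = TranscriptModel(
            tid, f"gene_{tid}", inst.chrom, "+", [exon1, exon2],
            count=float(rng.integers(500, 5000)),
        )
        transcripts.append(t)
        if not decoy:
            chimeric_ids.add(tid)

    truth.chimeric_transcripts = chimeric_ids
    return transcripts, truth
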
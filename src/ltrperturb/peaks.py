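"""Simplified enrichment peak calling, three-antibody consensus, and peak
annotation to repeat families and genomic context.

The caller is a binned Poisson window test: per bin, the upper-tail
probability of the treatment count given a local background rate taken as
the larger of the genome-wide treatment mean and the depth-scaled local
control mean (+/- 5 kb window), with Benjamini-Hochberg correction over
bins and merging of significant bins.  It is a documented functional
stand-in for a full peak caller, validated by calibration and recovery
properties rather than output identity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .guides import GuideHit, _IntervalLookup
from .io import GeneModel, RepeatInstance

log = logging.getLogger(__name__)

Fragments = Mapping[str, np.ndarray]


@dataclass
class SignalTrack:
    """Per-chromosome fragment counts in fixed-width bins (midpoint binned)."""

    counts: dict[str, np.ndarray]
    bin_width: int

    def __post_init__(self) -> None:
        for chrom, v in self.counts.items():
            if (v < 0).any():
                raise ValueError(f"negative counts on {chrom}")

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    @classmethod
    def from_fragments(
        cls, fragments: Fragments, chrom_lengths: Mapping[str, int], bin_width: int = 200
    ) -> "SignalTrack":
        counts = {}
        for chrom, clen in chrom_lengths.items():
            nbins = int(np.ceil(clen / bin_width))
            arr = np.zeros(nbins, dtype=np.int64)
            frags = fragments.get(chrom)
            if frags is not None and len(frags):
                mids = (frags[:, 0] + frags[:, 1]) // 2
                np.add.at(arr, np.clip(mids // bin_width, 0, nbins - 1), 1)
            counts[chrom] = arr
        return cls(counts, bin_width)


@dataclass
class PeakCall:
    chrom: str
    start: int
    end: int
    score: float  # -log10 adjusted p (max over bins)
    fold_enrichment: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("peak start >= end")
        if self.score < 0:
            raise ValueError("negative peak score")


@dataclass
class ConsensusPeak:
    chrom: str
    start: int
    end: int
    supporting: tuple[int, int, int]  # indices into the three input peak lists
    max_score: float


def call_peaks(
    treatment: SignalTrack,
    controls: Sequence[SignalTrack],
    alpha: float = 0.05,
    local_window: int = 5_000,
    merge_gap_bins: int = 1,
    source: str = "",
) -> list[PeakCall]:
    """Poisson window peak calls of treatment vs pooled scaled controls."""
    if treatment.total == 0:
        raise ValueError("zero-depth treatment track")
    for c in controls:
        if c.bin_width != treatment.bin_width:
            raise ValueError("bin width mismatch between tracks")
        if set(c.counts) != set(treatment.counts):
            raise ValueError("chromosome mismatch between tracks")
    bw = treatment.bin_width
    half = max(1, int(round(local_window / bw)))

    n_bins_total = sum(len(v) for v in treatment.counts.values())
    genome_mean = treatment.total / n_bins_total
    ctrl_total = sum(c.total for c in controls)
    scale = treatment.total / ctrl_total if ctrl_total > 0 else 0.0

    pvals, index = [], []
    lam_by_chrom: dict[str, np.ndarray] = {}
    for chrom, t in treatment.counts.items():
        pooled = np.zeros(len(t), dtype=float)
        for c in controls:
            pooled += c.counts[chrom]
        # local control mean over +/- local_window, depth scaled
        kernel = np.ones(2 * half + 1)
        local = np.convolve(pooled, kernel, mode="same") / np.convolve(
            np.ones(len(t)), kernel, mode="same"
        )
        lam = np.maximum(genome_mean, scale * local)
        lam_by_chrom[chrom] = lam
        p = stats.poisson.sf(t - 1, lam)  # P(X >= t)
        pvals.append(p)
        index.extend((chrom, i) for i in range(len(t)))
    pall = np.concatenate(pvals)
    reject, padj, _, _ = multipletests(pall, alpha=alpha, method="fdr_bh")

    padj_by_chrom: dict[str, np.ndarray] = {}
    rej_by_chrom: dict[str, np.ndarray] = {}
    off = 0
    for chrom, t in treatment.counts.items():
        n = len(t)
        padj_by_chrom[chrom] = padj[off : off + n]
        rej_by_chrom[chrom] = reject[off : off + n]
        off += n

    peaks: list[PeakCall] = []
    for chrom, t in treatment.counts.items():
        sig = np.flatnonzero(rej_by_chrom[chrom])
        if len(sig) == 0:
            continue
        # merge significant bins with gaps <= merge_gap_bins
        runs: list[list[int]] = [[int(sig[0]), int(sig[0])]]
        for b in sig[1:].tolist():
            if b - runs[-1][1] <= merge_gap_bins + 1:
                runs[-1][1] = b
            else:
                runs.append([b, b])
        lam = lam_by_chrom[chrom]
        pa = padj_by_chrom[chrom]
        for b0, b1 in runs:
            bins = np.arange(b0, b1 + 1)
            score = float(-np.log10(max(pa[bins].min(), 1e-300)))
            fold = float((t[bins] / np.maximum(lam[bins], 1e-12)).max())
            peaks.append(
                PeakCall(chrom, b0 * bw, (b1 + 1) * bw, score, fold, source)
            )
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def consensus_peaks(
    peaks_a: Sequence[PeakCall],
    peaks_b: Sequence[PeakCall],
    peaks_c: Sequence[PeakCall],
) -> list[ConsensusPeak]:
    """Intervals supported by one mutually overlapping peak from each set.

    Consensus interval = intersection of the three supporting peaks; each
    supporting peak is used at most once (greedy along the genome).
    """
    used_b: set[int] = set()
    used_c: set[int] = set()
    out: list[ConsensusPeak] = []
    order_a = sorted(range(len(peaks_a)), key=lambda i: (peaks_a[i].chrom, peaks_a[i].start))
    for ia in order_a:
        a = peaks_a[ia]
        match = None
        for ib, b in enumerate(peaks_b):
            if ib in used_b or b.chrom != a.chrom:
                continue
            if b.start >= a.end or a.start >= b.end:
                continue
            for ic, c in enumerate(peaks_c):
                if ic in used_c or c.chrom != a.chrom:
                    continue
                # pairwise overlap among all three
                lo = max(a.start, b.start, c.start)
                hi = min(a.end, b.end, c.end)
                if lo < hi and not (c.start >= b.end or b.start >= c.end):
                    match = (ib, ic, lo, hi)
                    break
            if match:
                break
        if match:
            ib, ic, lo, hi = match
            used_b.add(ib)
            used_c.add(ic)
            score = max(a.score, peaks_b[ib].score, peaks_c[ic].score)
            out.append(ConsensusPeak(a.chrom, lo, hi, (ia, ib, ic), score))
    out.sort(key=lambda p: (p.chrom, p.start))
    return out


def assign_peaks_to_repeats(
    consensus: Sequence[ConsensusPeak],
    instances: Sequence[RepeatInstance],
    priority: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each peak to the highest-priority overlapping family.

    Returns (per-peak assignment table, per-family bound-fraction table).
    Peaks overlapping no instance are labelled 'off-target'.
    """
    lookups = {
        fam: _IntervalLookup(
            (r.chrom, r.start, r.end) for r in instances if r.family == fam
        )
        for fam in priority
    }
    rows = []
    bound: dict[str, set[str]] = {fam: set() for fam in priority}
    per_fam_instances: dict[str, list[RepeatInstance]] = {fam: [] for fam in priority}
    for r in instances:
        if r.family in per_fam_instances:
            per_fam_instances[r.family].append(r)

    for pk in consensus:
        label = "off-target"
        for fam in priority:
            if lookups[fam].overlaps(pk.chrom, pk.start, pk.end):
                label = fam
                break
        rows.append(
            {"chrom": pk.chrom, "start": pk.start, "end": pk.end,
             "assigned_family": label, "max_score": pk.max_score}
        )
        # any-family instance overlap for bound fractions
        for fam in priority:
            for r in per_fam_instances[fam]:
                if r.chrom == pk.chrom and pk.start < r.end and r.start < pk.end:
                    bound[fam].add(r.instance_id)

    frac_rows = []
    for fam in priority:
        n = len(per_fam_instances[fam])
        frac_rows.append(
            {"family": fam, "n_instances": n, "n_bound": len(bound[fam]),
             "bound_fraction": len(bound[fam]) / n if n else np.nan}
        )
    return pd.DataFrame(rows), pd.DataFrame(frac_rows)


def classify_offtarget_peaks(
    offtarget_peaks: Sequence[ConsensusPeak],
    guide_hits: Sequence[GuideHit],
    max_mm: int = 3,
) -> dict[str, list[ConsensusPeak]]:
    """Split off-target peaks into sequence-legitimate vs nonspecific.

    A peak is 'legitimate' iff it overlaps at least one PAM-valid guide hit
    with <= max_mm mismatches (Watson-Crick pairing explains it)."""
    hit_lookup = _IntervalLookup(
        (h.chrom, h.start, h.end)
        for h in guide_hits
        if h.pam_valid and h.mismatches <= max_mm
    )
    out: dict[str, list[ConsensusPeak]] = {"legitimate": [], "nonspecific": []}
    for pk in offtarget_peaks:
        key = "legitimate" if hit_lookup.overlaps(pk.chrom, pk.start, pk.end) else "nonspecific"
        out[key].append(pk)
    return out


def classify_peak_context(
    consensus: Sequence[ConsensusPeak],
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (-1000, 100),
) -> pd.DataFrame:
    """Mutually exclusive promoter > intragenic > intergenic classification.

    The promoter window is strand-aware around the TSS: (-1000, +100) means
    1 kb upstream to 100 bp downstream in the gene's orientation.
    """
    up, down = promoter_window
    prom_iv, body_iv = [], []
    for g in genes:
        if g.strand == "+":
            prom_iv.append((g.chrom, g.tss + up, g.tss + down))
        else:
            prom_iv.append((g.chrom, g.tss - down + 1, g.tss - up + 1))
        body_iv.append((g.chrom, g.span[0], g.span[1]))
    prom = _IntervalLookup((c, max(0, s), e) for c, s, e in prom_iv if max(0, s) < e)
    body = _IntervalLookup(body_iv)
    rows = []
    for pk in consensus:
        if prom.overlaps(pk.chrom, pk.start, pk.end):
            label = "promoter"
        elif body.overlaps(pk.chrom, pk.start, pk.end):
            label = "intragenic"
        else:
            label = "intergenic"
        rows.append({"chrom": pk.chrom, "start": pk.start, "end": pk.end, "context": label})
    return pd.DataFrame(rows)


def signal_matrix(
    track: SignalTrack,
    anchors: Sequence[RepeatInstance] | Sequence[GeneModel],
    window: int = 4000,
    bin_width: int = 50,
    sort_by_sum: bool = False,
    flip_minus: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """n_anchors x (window / bin_width) depth-normalised signal matrix.

    Row i covers [midpoint - window/2, midpoint + window/2) of anchor i in
    bins of bin_width; signal is fragments-per-million.  Anchors whose
    window leaves the chromosome get zero padding (with a warning).
    """
    nb = window // bin_width
    half = window // 2
    depth = track.total
    norm = 1e6 / depth if depth > 0 else 0.0
    mat = np.zeros((len(anchors), nb))
    ids = []
    for i, a in enumerate(anchors):
        if isinstance(a, RepeatInstance):
            mid, chrom, strand, aid = a.center, a.chrom, a.strand, a.instance_id
        else:
            mid, chrom, strand, aid = a.tss, a.chrom, a.strand, a.gene_id
        ids.append(aid)
        counts = track.counts[chrom]
        clen = len(counts) * track.bin_width
        lo, hi = mid - half, mid + half
        if lo < 0 or hi > clen:
            log.warning("anchor %s window off chromosome; zero padded", aid)
        # resample track bins onto the matrix bins by midpoint position
        for j in range(nb):
            s = lo + j * bin_width
            e = s + bin_width
            if e <= 0 or s >= clen:
                continue
            b0, b1 = max(0, s) // track.bin_width, (min(clen, e) - 1) // track.bin_width
            frac = 0.0
            for b in range(b0, b1 + 1):
                bs, be = b * track.bin_width, (b + 1) * track.bin_width
                ov = min(be, e) - max(bs, s)
                if ov > 0:
                    frac += counts[b] * ov / track.bin_width
            mat[i, j] = frac * norm
        if flip_minus and strand == "-":
            mat[i] = mat[i, ::-1]
    if sort_by_sum:
        order = np.argsort(-mat.sum(axis=1), kind="stable")
        mat = mat[order]
        ids = [ids[int(k)] for k in order]
    return mat, ids
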
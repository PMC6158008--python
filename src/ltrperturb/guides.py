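"""Multiplex guide design against a repeat family.

The matching model is the seed+PAM counting rule: a candidate is the 16 nt
immediately 5' of an NGG PAM; genomic hits are Hamming matches of the seed
(0..3 mismatches, no bulges) followed by a valid NGG, on either strand.
N never matches any guide base.  Hits inside masked families are not
counted as off-targets.

The engine uses a 4-mer pigeonhole index (a 16-mer within 3 mismatches of
a genomic window shares at least one exact 4-mer chunk with it) and is
oracle-equivalent to a naive both-strand scan; the naive scanner lives in
the test suite.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomeSequence, RepeatInstance, revcomp

log = logging.getLogger(__name__)

SEED_LEN = 16
PAM_LEN = 3  # NGG
_WIN = SEED_LEN + PAM_LEN

_ENC = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A0 C1 G2 T3, anything else 4)."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class GuideCandidate:
    """A 16-nt PAM-adjacent seed with mismatch-stratified tallies.

    ontarget_instances[m] counts target-family instances matched at <= m
    mismatches; offtarget_counts[m] counts PAM-valid genomic matches at
    exactly m mismatches whose protospacer does not overlap a masked-family
    instance.
    """

    seed_seq: str
    ontarget_instances: list[int] = field(default_factory=lambda: [0, 0, 0, 0])
    offtarget_counts: list[int] = field(default_factory=lambda: [0, 0, 0, 0])

    def __post_init__(self) -> None:
        if len(self.seed_seq) != SEED_LEN:
            raise ValueError(f"seed must be {SEED_LEN} nt, got {len(self.seed_seq)}")


@dataclass(frozen=True)
class GuideHit:
    guide: str
    chrom: str
    start: int  # protospacer interval on the forward axis, 0-based half-open
    end: int
    strand: str
    mismatches: int
    pam_valid: bool


@dataclass
class CoverageRecord:
    instance_id: str
    family: str
    guides_matching: list[int]  # index m -> guides with >=1 hit at <= m mm

    def __post_init__(self) -> None:
        gm = self.guides_matching
        if any(gm[i] > gm[i + 1] for i in range(len(gm) - 1)):
            raise ValueError("guides_matching must be non-decreasing in m")


# ---------------------------------------------------------------------------
# matching engine

class _StrandIndex:
    """4-mer chunk index over one strand of one chromosome."""

    def __init__(self, enc: np.ndarray):
        self.enc = enc
        n = len(enc)
        self.n_windows = max(0, n - _WIN + 1)
        if self.n_windows == 0:
            self.pam_ok = np.zeros(0, dtype=bool)
            self.sorted_codes = np.zeros(0, dtype=np.int32)
            self.order = np.zeros(0, dtype=np.int64)
            return
        # PAM NGG: first base unconstrained (N allowed), then G, G
        self.pam_ok = (enc[SEED_LEN + 1 : SEED_LEN + 1 + self.n_windows + 1][: self.n_windows] == 2) & (
            enc[SEED_LEN + 2 : SEED_LEN + 2 + self.n_windows] == 2
        )
        e = enc.astype(np.int32)
        codes = e[:-3] * 125 + e[1:-2] * 25 + e[2:-1] * 5 + e[3:]  # base-5 4-mer codes
        self.codes = codes
        self.order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[self.order]

    def hits(self, seed_enc: np.ndarray, max_mm: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(window starts, mismatch counts, pam flags) for matches <= max_mm."""
        if self.n_windows == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy(), np.zeros(0, dtype=bool)
        cand = []
        s = seed_enc.astype(np.int64)
        for off in (0, 4, 8, 12):
            c = int(s[off] * 125 + s[off + 1] * 25 + s[off + 2] * 5 + s[off + 3])
            lo = np.searchsorted(self.sorted_codes, c, "left")
            hi = np.searchsorted(self.sorted_codes, c, "right")
            cand.append(self.order[lo:hi] - off)
        pos = np.unique(np.concatenate(cand))
        pos = pos[(pos >= 0) & (pos < self.n_windows)]
        if len(pos) == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy(), np.zeros(0, dtype=bool)
        windows = self.enc[pos[:, None] + np.arange(SEED_LEN)]
        mm = (windows != seed_enc).sum(axis=1)
        keep = mm <= max_mm
        return pos[keep], mm[keep].astype(np.int64), self.pam_ok[pos[keep]]


class GenomeIndex:
    """Both-strand chunk index over a whole genome, built once and reused."""

    def __init__(self, genome: GenomeSequence):
        self.chrom_len = {c: len(s) for c, s in genome.sequences.items()}
        self._idx: dict[tuple[str, str], _StrandIndex] = {}
        for chrom, seq in genome.sequences.items():
            enc = encode(seq)
            self._idx[(chrom, "+")] = _StrandIndex(enc)
            self._idx[(chrom, "-")] = _StrandIndex((3 - np.clip(enc, 0, 3))[::-1] | (enc[::-1] // 4 * 4))

    def seed_hits(self, seed: str, max_mm: int) -> list[tuple[str, int, int, str, int, bool]]:
        """All genomic hits of a seed: (chrom, start, end, strand, mm, pam).

        Coordinates are the protospacer interval on the forward axis.
        """
        seed_enc = encode(seed)
        if (seed_enc > 3).any():
            raise ValueError("seed contains non-ACGT characters")
        out = []
        for (chrom, strand), idx in self._idx.items():
            pos, mm, pam = idx.hits(seed_enc, max_mm)
            L = self.chrom_len[chrom]
            for p, m, ok in zip(pos.tolist(), mm.tolist(), pam.tolist()):
                if strand == "+":
                    s, e = p, p + SEED_LEN
                else:
                    s, e = L - p - SEED_LEN, L - p
                out.append((chrom, s, e, strand, m, bool(ok)))
        out.sort(key=lambda h: (h[0], h[1], h[3]))
        return out


class _IntervalLookup:
    """Overlap/containment queries against merged per-chromosome intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        per: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            per.setdefault(chrom, []).append((s, e))
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        for chrom, ivs in per.items():
            ivs.sort()
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self.starts[chrom] = np.array([s for s, _ in merged])
            self.ends[chrom] = np.array([e for _, e in merged])

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self.starts:
            return False
        starts, ends = self.starts[chrom], self.ends[chrom]
        j = int(np.searchsorted(starts, end, "left"))
        return j > 0 and ends[j - 1] > start


class _InstanceLocator:
    """Find instances whose interval contains a query interval."""

    def __init__(self, instances: Sequence[RepeatInstance]):
        per: dict[str, list[RepeatInstance]] = {}
        for r in instances:
            per.setdefault(r.chrom, []).append(r)
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]] = {}
        for chrom, rows in per.items():
            rows.sort(key=lambda r: (r.start, r.end))
            starts = np.array([r.start for r in rows])
            ends = np.array([r.end for r in rows])
            cummax_end = np.maximum.accumulate(ends)
            self._data[chrom] = (starts, ends, cummax_end, [r.instance_id for r in rows])

    def containing(self, chrom: str, start: int, end: int) -> list[str]:
        if chrom not in self._data:
            return []
        starts, ends, cummax_end, ids = self._data[chrom]
        j = int(np.searchsorted(starts, start, "right")) - 1
        out = []
        while j >= 0 and cummax_end[j] >= end:
            if ends[j] >= end:
                out.append(ids[j])
            j -= 1
        return out


# ---------------------------------------------------------------------------
# operations

def enumerate_seed_candidates(
    genome: GenomeSequence,
    instances: Sequence[RepeatInstance],
    target_family: str,
    seed_len: int = SEED_LEN,
    pam: str = "NGG",
) -> list[GuideCandidate]:
    """Every distinct seed immediately 5' of an NGG inside a target instance.

    Both strands are scanned; the full protospacer+PAM window must lie
    within the instance interval.  Seeds containing N are excluded.  An
    empty result is a warning, not an error.
    """
    if seed_len != SEED_LEN or pam != "NGG":
        raise ValueError("only 16-nt seeds with an NGG PAM are supported")
    members = [r for r in instances if r.family == target_family]
    if not members:
        raise ValueError(f"no instances of family {target_family!r}")
    seeds: set[str] = set()
    for inst in members:
        seq = genome.fetch(inst.chrom, inst.start, inst.end)
        for s in (seq, revcomp(seq)):
            enc = encode(s)
            if len(enc) < _WIN:
                continue
            gg = (enc[SEED_LEN + 1 : len(enc) - 1] == 2) & (enc[SEED_LEN + 2 :] == 2)
            for p in np.flatnonzero(gg):
                seed = s[p : p + SEED_LEN]
                if "N" not in seed:
                    seeds.add(seed)
    if not seeds:
        log.warning("no PAM-adjacent seed candidates found in %s", target_family)
    return [GuideCandidate(s) for s in sorted(seeds)]


def score_offtargets(
    candidates: Sequence[GuideCandidate],
    genome: GenomeSequence,
    masked_families: Sequence[str],
    instances: Sequence[RepeatInstance],
    max_mm: int = 3,
    *,
    target_family: Optional[str] = None,
    require_pam: bool = True,
    index: Optional[GenomeIndex] = None,
) -> list[GuideCandidate]:
    """Fill mismatch-stratified on-/off-target tallies for every candidate.

    offtarget_counts[m]: PAM-valid genomic matches at exactly m mismatches
    whose protospacer does not overlap any masked-family instance (set
    require_pam=False for the PAM-free off-target variant).
    ontarget_instances[m]: target-family instances containing >=1 PAM-valid
    hit at <= m mismatches.
    """
    target_family = target_family or (masked_families[0] if masked_families else None)
    if target_family is None:
        raise ValueError("target_family is required")
    idx = index or GenomeIndex(genome)
    masked = _IntervalLookup(
        (r.chrom, r.start, r.end)
        for r in instances
        if r.family in set(masked_families)
    )
    locator = _InstanceLocator([r for r in instances if r.family == target_family])
    out = []
    for cand in candidates:
        hits = idx.seed_hits(cand.seed_seq, max_mm)
        off = [0] * (max_mm + 1)
        best_by_instance: dict[str, int] = {}
        for chrom, s, e, _strand, mm, pam in hits:
            if require_pam and not pam:
                continue
            if not masked.overlaps(chrom, s, e):
                off[mm] += 1
            for iid in locator.containing(chrom, s, e):
                best_by_instance[iid] = min(best_by_instance.get(iid, max_mm + 1), mm)
        on = [
            sum(1 for v in best_by_instance.values() if v <= m)
            for m in range(max_mm + 1)
        ]
        cand.offtarget_counts = off
        cand.ontarget_instances = on
        out.append(cand)
    return out


def select_guides(
    candidates: Sequence[GuideCandidate],
    k: int = 12,
    *,
    prefer_coverage: bool = False,
) -> list[GuideCandidate]:
    """The k candidates with the lowest off-target key, deterministically.

    Default key: ascending lexicographic over the mismatch-stratified
    off-target count vector, ties broken by descending zero-mismatch
    on-target instance count, then ascending seed sequence.  With
    prefer_coverage=True the on-target count leads instead.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if prefer_coverage:
        key = lambda c: (-c.ontarget_instances[0], tuple(c.offtarget_counts), c.seed_seq)
    else:
        key = lambda c: (tuple(c.offtarget_counts), -c.ontarget_instances[0], c.seed_seq)
    ranked = sorted(candidates, key=key)
    if len(ranked) < k:
        log.warning("only %d candidates available for k=%d", len(ranked), k)
    return ranked[:k]


def map_guides_to_instances(
    guides: Sequence[GuideCandidate],
    genome: GenomeSequence,
    instances: Sequence[RepeatInstance],
    families: Sequence[str],
    max_mm: int = 3,
    *,
    index: Optional[GenomeIndex] = None,
) -> tuple[list[CoverageRecord], list[GuideHit]]:
    """Per-instance coverage over the families of interest, plus all hits.

    A guide covers an instance at level m iff it has >=1 PAM-valid hit with
    <= m mismatches whose protospacer lies within the instance interval.
    """
    if not guides:
        raise ValueError("no guides supplied")
    idx = index or GenomeIndex(genome)
    fams = set(families)
    members = [r for r in instances if r.family in fams]
    locator = _InstanceLocator(members)

    all_hits: list[GuideHit] = []
    # best mm per (instance, guide)
    best: dict[tuple[str, int], int] = {}
    for gi, guide in enumerate(guides):
        for chrom, s, e, strand, mm, pam in idx.seed_hits(guide.seed_seq, max_mm):
            all_hits.append(GuideHit(guide.seed_seq, chrom, s, e, strand, mm, pam))
            if not pam:
                continue
            for iid in locator.containing(chrom, s, e):
                k = (iid, gi)
                best[k] = min(best.get(k, max_mm + 1), mm)

    records = []
    for inst in sorted(members, key=lambda r: r.instance_id):
        gm = [
            sum(
                1
                for gi in range(len(guides))
                if best.get((inst.instance_id, gi), max_mm + 1) <= m
            )
            for m in range(max_mm + 1)
        ]
        records.append(CoverageRecord(inst.instance_id, inst.family, gm))
    return records, all_hits


def coverage_summary(
    records: Sequence[CoverageRecord],
    thresholds: Sequence[int] = (1, 2, 4),
) -> pd.DataFrame:
    """Fraction of instances with >= t covering guides, per family per m."""
    if not records:
        raise ValueError("no coverage records (empty denominator)")
    rows = []
    by_family: dict[str, list[CoverageRecord]] = {}
    for r in records:
        by_family.setdefault(r.family, []).append(r)
    n_m = len(records[0].guides_matching)
    for family in sorted(by_family):
        recs = by_family[family]
        for m in range(n_m):
            for t in thresholds:
                frac = sum(1 for r in recs if r.guides_matching[m] >= t) / len(recs)
                rows.append(
                    {"family": family, "mismatches": m, "threshold": int(t),
                     "fraction": frac, "n_instances": len(recs)}
                )
    return pd.DataFrame(rows)


def correlate_coverage_with_signal(
    records: Sequence[CoverageRecord],
    signal: dict[str, float],
    m: int = 0,
) -> tuple[float, int]:
    """Spearman rho between guide coverage at level m and a per-instance
    signal score (average-rank ties), over instances present in both."""
    pairs = [
        (r.guides_matching[m], signal[r.instance_id])
        for r in records
        if r.instance_id in signal
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 paired observations")
    x, y = zip(*pairs)
    rho = stats.spearmanr(x, y).statistic
    return float(rho), len(pairs)
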
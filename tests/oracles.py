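"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's indexed engines: guide matching is
a dense both-strand Hamming scan, pair placement is an exhaustive window
scan, and the statistics are computed from first principles.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

from ltrperturb.io import GenomeSequence, RepeatInstance, revcomp

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def enc(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# guide matching

def naive_seed_hits(genome: GenomeSequence, seed: str, max_mm: int = 3):
    """Dense both-strand scan: (chrom, start, end, strand, mm, pam_valid).

    Coordinates are the protospacer interval on the forward axis; N in the
    genome never matches a guide base.
    """
    s_enc = enc(seed)
    k = len(seed)
    out = []
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        for strand in "+-":
            s2 = seq if strand == "+" else revcomp(seq)
            e2 = enc(s2)
            n_win = L - (k + 3) + 1
            if n_win <= 0:
                continue
            win = np.lib.stride_tricks.sliding_window_view(e2, k)[:n_win]
            mm = (win != s_enc).sum(axis=1)
            pam = (e2[k + 1 : k + 1 + n_win] == 2) & (e2[k + 2 : k + 2 + n_win] == 2)
            for p in np.flatnonzero(mm <= max_mm).tolist():
                if strand == "+":
                    iv = (p, p + k)
                else:
                    iv = (L - p - k, L - p)
                out.append((chrom, iv[0], iv[1], strand, int(mm[p]), bool(pam[p])))
    return sorted(out)


def naive_candidates(
    genome: GenomeSequence, instances, family: str, k: int = 16
) -> set[str]:
    """Brute-force window scan for PAM-adjacent seeds inside instances."""
    seeds = set()
    for inst in instances:
        if inst.family != family:
            continue
        seq = genome.fetch(inst.chrom, inst.start, inst.end)
        for s2 in (seq, revcomp(seq)):
            for p in range(len(s2) - (k + 3) + 1):
                if s2[p + k + 1 : p + k + 3] == "GG" and "N" not in s2[p : p + k]:
                    seeds.add(s2[p : p + k])
    return seeds


def naive_offtarget_counts(
    genome, instances, masked_families, seed, max_mm=3, require_pam=True
):
    """Mismatch-stratified off-target counts from the dense scan."""
    masked = [
        (r.chrom, r.start, r.end) for r in instances if r.family in set(masked_families)
    ]
    counts = [0] * (max_mm + 1)
    for chrom, s, e, _strand, mm, pam in naive_seed_hits(genome, seed, max_mm):
        if require_pam and not pam:
            continue
        if any(c == chrom and s < me and ms < e for c, ms, me in masked):
            continue
        counts[mm] += 1
    return counts


def naive_instance_coverage(genome, instances, families, seeds, max_mm=3):
    """instance_id -> guides_matching[m] from the dense scan (containment)."""
    members = [r for r in instances if r.family in set(families)]
    best: dict[tuple[str, int], int] = {}
    for gi, seed in enumerate(seeds):
        for chrom, s, e, _strand, mm, pam in naive_seed_hits(genome, seed, max_mm):
            if not pam:
                continue
            for inst in members:
                if inst.chrom == chrom and inst.start <= s and e <= inst.end:
                    key = (inst.instance_id, gi)
                    best[key] = min(best.get(key, max_mm + 1), mm)
    return {
        inst.instance_id: [
            sum(
                1
                for gi in range(len(seeds))
                if best.get((inst.instance_id, gi), max_mm + 1) <= m
            )
            for m in range(max_mm + 1)
        ]
        for inst in members
    }


# ---------------------------------------------------------------------------
# paired-end placement

def naive_unique_fraction(
    genome: GenomeSequence,
    pairs,
    min_margin: int = 2,
    cap: int = 4,
) -> float:
    """Exhaustive concordant-placement scan over every genome position."""
    R = pairs.read_len
    chroms = sorted(genome.sequences)
    encs = {c: enc(genome.sequences[c]) for c in chroms}
    wins = {
        c: np.lib.stride_tricks.sliding_window_view(encs[c], R)
        for c in chroms
        if len(encs[c]) >= R
    }
    region = enc(genome.sequences[pairs.chrom])
    sizes = np.unique(pairs.sizes)
    min_gap, max_gap = int(sizes.min()) - R, int(sizes.max()) - R

    def word_placements(word):
        out = []
        for c in chroms:
            if c not in wins:
                continue
            mm = (wins[c] != word).sum(axis=1)
            for p in np.flatnonzero(mm <= cap).tolist():
                out.append((c, p, int(mm[p])))
        return out

    n_unique = 0
    cache_f: dict[int, list] = {}
    cache_r: dict[int, list] = {}
    for a, f in zip(pairs.starts.tolist(), pairs.sizes.tolist()):
        b = a + f - R
        for ws in (a, b):
            if ws not in cache_f:
                w = region[ws : ws + R]
                cache_f[ws] = word_placements(w)
                cache_r[ws] = word_placements((3 - np.clip(w, 0, 3))[::-1])
        totals = []
        for combos, lkey, rkey in (
            (None, cache_f[a], cache_f[b]),
            (None, cache_r[b], cache_r[a]),
        ):
            for (c1, p1, m1) in lkey:
                for (c2, p2, m2) in rkey:
                    if c1 == c2 and min_gap <= p2 - p1 <= max_gap and m1 + m2 <= cap:
                        totals.append(m1 + m2)
        totals.sort()
        if totals and (len(totals) == 1 or totals[1] - totals[0] >= min_margin):
            n_unique += 1
    return n_unique / len(pairs)


# ---------------------------------------------------------------------------
# statistics

def spearman_oracle(x, y) -> float:
    """Average-rank ties, then Pearson, from first principles."""

    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_comb(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    def log_p(a_):
        return (
            log_comb(r1, a_) + log_comb(r2, c1 - a_) - log_comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    obs = log_p(a)
    total = 0.0
    for a_ in range(lo, hi + 1):
        lp = log_p(a_)
        if lp <= obs + 1e-9:
            total += math.exp(lp)
    return min(1.0, total)


def ranksum_exact_oracle(x, y) -> float:
    """Two-sided rank-sum p by full subset enumeration (average-rank ties)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    mean = n1 * (len(pooled) + 1) / 2.0
    obs = abs(sum(ranks[:n1]) - mean)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(sum(ranks[i] for i in comb) - mean) >= obs - 1e-9:
            hits += 1
    return hits / total
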
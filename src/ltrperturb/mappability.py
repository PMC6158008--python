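"""Paired-end unique-mappability enumeration over repeat instances.

For each instance, all possible read pairs (150 bp mates, fragment sizes
150-400 bp) over the instance plus flanks are enumerated and placed back
against the whole genome with a mismatch-tolerant concordant search.  A
pair counts as uniquely mappable when its best concordant placement is
unique and the runner-up needs at least `min_margin` more mismatches --
an aligner-independent stand-in for a MAPQ > 20 cut.

The placement search is exact up to a total mismatch cap (default 4 per
pair); placements beyond the cap are ignored.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .guides import encode
from .io import GenomeSequence, RepeatInstance

_GAP = 10_000  # N-gap between chromosomes in the concatenated index


@dataclass
class MappabilityResult:
    instance_id: str
    n_pairs_enumerated: int
    n_unique: int

    @property
    def fraction_unique(self) -> float:
        if self.n_pairs_enumerated == 0:
            return 0.0
        return self.n_unique / self.n_pairs_enumerated


@dataclass
class ReadPairSet:
    """All (fragment start, fragment size) pairs over one region.

    mate1 is the first read_len bases of the fragment; mate2 the reverse
    complement of the last read_len bases.  Starts are absolute forward
    coordinates on `chrom`.
    """

    chrom: str
    region_start: int
    region_end: int
    read_len: int
    starts: np.ndarray
    sizes: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)


def enumerate_read_pairs(
    genome: GenomeSequence,
    instance: RepeatInstance,
    read_len: int = 150,
    frag_min: int = 150,
    frag_max: int = 400,
    flank: int = 400,
) -> ReadPairSet:
    """One pair per fragment placement fully inside instance +/- flank.

    The region is truncated at chromosome edges; fragments shorter than
    read_len are excluded.
    """
    clen = genome.chrom_length(instance.chrom)
    lo = max(0, instance.start - flank)
    hi = min(clen, instance.end + flank)
    region_len = hi - lo
    starts, sizes = [], []
    for size in range(max(frag_min, read_len), frag_max + 1):
        n = region_len - size + 1
        if n > 0:
            starts.append(np.arange(lo, lo + n, dtype=np.int64))
            sizes.append(np.full(n, size, dtype=np.int64))
    if starts:
        s = np.concatenate(starts)
        z = np.concatenate(sizes)
    else:
        s = np.zeros(0, dtype=np.int64)
        z = np.zeros(0, dtype=np.int64)
    return ReadPairSet(instance.chrom, lo, hi, read_len, s, z)


class PairMapper:
    """Whole-genome mismatch-tolerant placement search for read-length words.

    Chromosomes are concatenated with large N gaps; a word placement is a
    start in the concatenated coordinate space.  Word matching uses a
    pigeonhole chunk index: a word of length R within `max_mm` mismatches
    of a genomic window shares at least one exact chunk of length
    R // (max_mm + 1) with it.
    """

    def __init__(self, genome: GenomeSequence, read_len: int = 150, max_mm: int = 4):
        self.read_len = read_len
        self.max_mm = max_mm
        self.chunk = read_len // (max_mm + 1)
        if self.chunk < 8:
            raise ValueError("read too short for the mismatch cap")
        self.offsets = {}
        parts = []
        pos = 0
        for chrom in sorted(genome.sequences):
            self.offsets[chrom] = pos
            enc = encode(genome.sequences[chrom])
            parts.append(enc)
            parts.append(np.full(_GAP, 4, dtype=np.uint8))
            pos += len(enc) + _GAP
        self.enc = np.concatenate(parts)
        n = len(self.enc)
        # chunk codes (base-4 packed); windows containing N get code -1
        c = self.chunk
        w = np.lib.stride_tricks.sliding_window_view(self.enc, c)
        pows = (4 ** np.arange(c - 1, -1, -1)).astype(np.int64)
        codes = w.astype(np.int64) @ pows
        codes[(w == 4).any(axis=1)] = -1
        self.codes = codes
        self.order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[self.order]
        self.n_starts = n - read_len + 1

    def _word_code(self, word: np.ndarray, off: int) -> int:
        c = self.chunk
        chunk = word[off : off + c].astype(np.int64)
        pows = (4 ** np.arange(c - 1, -1, -1)).astype(np.int64)
        return int(chunk @ pows)

    def placements(self, word: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(global starts, mismatch counts) of all placements <= max_mm."""
        R = self.read_len
        if (word > 3).any():
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        cand = []
        n_chunks = self.max_mm + 1
        for ci in range(n_chunks):
            off = ci * self.chunk
            code = self._word_code(word, off)
            lo = np.searchsorted(self.sorted_codes, code, "left")
            hi = np.searchsorted(self.sorted_codes, code, "right")
            cand.append(self.order[lo:hi] - off)
        pos = np.unique(np.concatenate(cand))
        pos = pos[(pos >= 0) & (pos < self.n_starts)]
        if len(pos) == 0:
            return pos, pos.copy()
        windows = self.enc[pos[:, None] + np.arange(R)]
        mm = (windows != word).sum(axis=1)
        keep = mm <= self.max_mm
        return pos[keep], mm[keep].astype(np.int64)


def _join_concordant(
    left: tuple[np.ndarray, np.ndarray],
    right: tuple[np.ndarray, np.ndarray],
    min_gap: int,
    max_gap: int,
    cap: int,
) -> list[int]:
    """Total-mismatch list of concordant placements (left word at p, right
    word at q, min_gap <= q-p <= max_gap) with total mismatches <= cap."""
    lp, lm = left
    rp, rm = right
    out = []
    if len(lp) == 0 or len(rp) == 0:
        return out
    j0 = np.searchsorted(rp, lp + min_gap, "left")
    j1 = np.searchsorted(rp, lp + max_gap, "right")
    for i in range(len(lp)):
        for j in range(int(j0[i]), int(j1[i])):
            tot = int(lm[i] + rm[j])
            if tot <= cap:
                out.append(tot)
    return out


def unique_mappable_fraction(
    genome: GenomeSequence,
    pairs: ReadPairSet,
    min_margin: int = 2,
    max_pair_mm: int = 4,
    mapper: PairMapper | None = None,
) -> MappabilityResult:
    """Count pairs whose best concordant placement is unique with margin.

    A placement is concordant when both mates land in the correct relative
    orientation with a fragment size inside the enumerated range.  A pair
    is unique iff exactly one placement attains the minimal total mismatch
    count and any runner-up needs >= min_margin more mismatches.
    """
    R = pairs.read_len
    mp = mapper or PairMapper(genome, read_len=R, max_mm=max_pair_mm)
    if mp.read_len != R:
        raise ValueError("mapper read length does not match the pair set")
    offset = mp.offsets[pairs.chrom]
    if len(pairs) == 0:
        return MappabilityResult("", 0, 0)
    frag_sizes = np.unique(pairs.sizes)
    # q - p window for concordant end-word placement
    min_gap = int(frag_sizes.min()) - R
    max_gap = int(frag_sizes.max()) - R

    # distinct word start offsets needed: fragment starts and end-word starts
    word_starts = np.unique(
        np.concatenate([pairs.starts, pairs.starts + pairs.sizes - R])
    )
    fwd: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    rev: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for ws in word_starts.tolist():
        g = offset + ws
        word = mp.enc[g : g + R]
        fwd[ws] = mp.placements(word)
        rev[ws] = mp.placements((3 - word)[::-1])

    n_unique = 0
    for a, f in zip(pairs.starts.tolist(), pairs.sizes.tolist()):
        b = a + f - R  # start of the fragment-end word
        # fast path: both words place uniquely forward and have no
        # reverse-sense placements -> the self placement is the only one
        if (
            len(fwd[a][0]) == 1
            and len(fwd[b][0]) == 1
            and (len(rev[b][0]) == 0 or len(rev[a][0]) == 0)
        ):
            n_unique += 1
            continue
        mms = _join_concordant(fwd[a], fwd[b], min_gap, max_gap, max_pair_mm)
        mms += _join_concordant(rev[b], rev[a], min_gap, max_gap, max_pair_mm)
        if not mms:
            continue  # placement search found nothing; count as non-unique
        mms.sort()
        if len(mms) == 1 or mms[1] - mms[0] >= min_margin:
            n_unique += 1
    return MappabilityResult("", len(pairs), n_unique)


def mappability_for_instances(
    genome: GenomeSequence,
    instances: list[RepeatInstance],
    read_len: int = 150,
    frag_min: int = 150,
    frag_max: int = 400,
    flank: int = 400,
    min_margin: int = 2,
    max_pair_mm: int = 4,
) -> list[MappabilityResult]:
    """MappabilityResult per instance, sharing one genome index."""
    mapper = PairMapper(genome, read_len=read_len, max_mm=max_pair_mm)
    out = []
    for inst in instances:
        pairs = enumerate_read_pairs(
            genome, inst, read_len=read_len, frag_min=frag_min,
            frag_max=frag_max, flank=flank,
        )
        res = unique_mappable_fraction(
            genome, pairs, min_margin=min_margin,
            max_pair_mm=max_pair_mm, mapper=mapper,
        )
        out.append(MappabilityResult(inst.instance_id, res.n_pairs_enumerated, res.n_unique))
    return out
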
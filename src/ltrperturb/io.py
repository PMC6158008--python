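"""Domain types and readers/writers for the formats the pipeline touches.

Coordinate convention: every interval in this package is 0-based half-open
(BED-native).  GTF-lite input is 1-based closed and is converted on read;
writing converts back, so read/write pairs round-trip bit-identically on
valid files.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """A name -> uppercase DNA sequence map over the alphabet {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome must contain at least one sequence")
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("empty sequence name")
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            bad = set(seq) - _DNA
            if bad:
                raise ParseError(
                    f"sequence {name!r} contains non-DNA characters {sorted(bad)}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand slice [start, end), clipped to chromosome bounds."""
        seq = self.sequences[chrom]
        return seq[max(0, start) : min(len(seq), end)]


@dataclass(frozen=True)
class RepeatInstance:
    """One annotated transposable-element copy."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    instance_id: str
    age_my: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.instance_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.instance_id}: bad strand {self.strand!r}")
        if not self.family:
            raise ValueError(f"{self.instance_id}: empty family")
        if self.age_my is not None and self.age_my < 0:
            raise ValueError(f"{self.instance_id}: negative age")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    span: tuple[int, int]

    def __post_init__(self) -> None:
        s, e = self.span
        if not (0 <= s < e):
            raise ValueError(f"{self.gene_id}: invalid span {self.span}")
        if not (s <= self.tss < e):
            raise ValueError(f"{self.gene_id}: TSS {self.tss} outside span {self.span}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    count: float = 0.0
    tpm: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ParseError(f"{self.transcript_id}: transcript with zero exons")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = -1
        for a, b in self.exons:
            if a >= b:
                raise ValueError(f"{self.transcript_id}: invalid exon [{a}, {b})")
            if a < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = b
        if self.count < 0:
            raise ValueError(f"{self.transcript_id}: negative count")

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def five_prime(self) -> int:
        """0-based position of the 5'-most transcribed base."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus a sample -> condition map."""

    counts: pd.DataFrame  # rows gene_id, columns sample_id
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without a condition: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a multi-record FASTA into a GenomeSequence (uppercased)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate FASTA header {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED6 repeat annotation: name column is family or family:instance_id

def read_bed_repeats(path: str | Path) -> list[RepeatInstance]:
    out: list[RepeatInstance] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 BED columns")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            if ":" in name:
                family, instance_id = name.split(":", 1)
            else:
                family, instance_id = name, f"{name}_{lineno}"
            if instance_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate instance id {instance_id!r}")
            seen.add(instance_id)
            age = float(fields[6]) if len(fields) > 6 and fields[6] not in (".", "") else None
            out.append(
                RepeatInstance(chrom, start, end, strand, family, instance_id, age)
            )
    out.sort(key=lambda r: (r.chrom, r.start, r.end, r.instance_id))
    return out


def write_bed_repeats(instances: Sequence[RepeatInstance], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(instances, key=lambda r: (r.chrom, r.start, r.end, r.instance_id)):
            name = f"{r.family}:{r.instance_id}"
            line = f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}"
            if r.age_my is not None:
                line += f"\t{r.age_my:g}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# GTF-lite: exon features only, gene_id/transcript_id attributes,
# 1-based closed coordinates on disk.

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_lite(path: str | Path) -> tuple[list[TranscriptModel], list[GeneModel]]:
    exons: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise ParseError(f"{path}:{lineno}: missing gene_id/transcript_id")
            tid = attr["transcript_id"]
            start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
            if tid not in exons:
                exons[tid] = {
                    "gene_id": attr["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                }
                order.append(tid)
            rec = exons[tid]
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise ParseError(f"{path}:{lineno}: transcript {tid} changes chrom/strand")
            rec["exons"].append((start, end))

    transcripts = [
        TranscriptModel(tid, rec["gene_id"], rec["chrom"], rec["strand"], rec["exons"])
        for tid, rec in ((t, exons[t]) for t in order)
    ]
    genes = genes_from_transcripts(transcripts)
    return transcripts, genes


def genes_from_transcripts(transcripts: Sequence[TranscriptModel]) -> list[GeneModel]:
    """One GeneModel per gene_id; TSS is the strand-aware 5'-most exon boundary."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = []
    for gid, ts in by_gene.items():
        chroms = {t.chrom for t in ts}
        strands = {t.strand for t in ts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ParseError(f"gene {gid}: transcripts disagree on chrom/strand")
        start = min(t.exons[0][0] for t in ts)
        end = max(t.exons[-1][1] for t in ts)
        strand = strands.pop()
        tss = start if strand == "+" else end - 1
        genes.append(GeneModel(gid, chroms.pop(), strand, tss, (start, end)))
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes


def write_gtf_lite(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for a, b in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\tltrperturb\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# TSV count matrices and sample sheets

def read_counts_tsv(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    if not {"sample_id", "condition"} <= set(sheet.columns):
        raise ParseError(f"{samples_path}: need sample_id and condition columns")
    conditions = dict(zip(sheet["sample_id"].astype(str), sheet["condition"].astype(str)))
    if not np.issubdtype(counts.values.dtype, np.number):
        raise ParseError(f"{counts_path}: non-numeric counts")
    return CountMatrix(counts.astype(int), conditions)


def write_counts_tsv(
    matrix: CountMatrix, counts_path: str | Path, samples_path: str | Path
) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample_id": matrix.sample_ids,
         "condition": [matrix.conditions[s] for s in matrix.sample_ids]}
    ).to_csv(samples_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fragment BED (ChIP): minimal chrom/start/end intervals

def read_fragments_bed(path: str | Path) -> dict[str, np.ndarray]:
    frames: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            frames.setdefault(chrom, []).append((start, end))
    return {c: np.array(v, dtype=np.int64) for c, v in frames.items()}


def write_fragments_bed(fragments: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(fragments):
            arr = fragments[chrom]
            arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
            for s, e in arr:
                fh.write(f"{chrom}\t{s}\t{e}\n")
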
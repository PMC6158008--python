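"""LTR-origin chimeric transcript detection and TPM quantification.

A spliced transcript whose strand-aware 5' end originates inside, or
within a small window of, a targeted repeat instance indicates LTR
promoter (rather than enhancer) activity.  Calls with TPM above a
threshold are marked appreciable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io import RepeatInstance, TranscriptModel


@dataclass(frozen=True)
class ChimericCall:
    transcript_id: str
    instance_id: str
    offset: int  # signed bp from instance start to the transcript 5' end
    tpm: float
    appreciable: bool


def compute_tpm(transcripts: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """Fill transcripts-per-million from counts and exonic lengths.

    rate_t = count_t / exonic length; tpm_t = rate_t / sum(rates) * 1e6,
    so TPM sums to one million.
    """
    rates = [t.count / t.length for t in transcripts]
    total = sum(rates)
    if total <= 0:
        raise ValueError("all transcript counts are zero; TPM undefined")
    for t, r in zip(transcripts, rates):
        t.tpm = r / total * 1e6
    return list(transcripts)


def detect_chimeric(
    transcripts: Sequence[TranscriptModel],
    instances: Sequence[RepeatInstance],
    target_family: Optional[str] = None,
    window: int = 100,
    tpm_min: float = 1.0,
    require_spliced: bool = True,
    upstream_only: bool = False,
) -> list[ChimericCall]:
    """Transcripts whose 5' end lies within `window` bp of an instance.

    The detection window is [instance.start - window, instance.end + window)
    (closed-left / open-right on both flanks); with upstream_only=True only
    the flank 5' of the instance in the transcript's reading direction is
    extended.  By default only spliced (>= 2 exon) transcripts qualify.
    Calls with tpm > tpm_min are flagged appreciable; transcripts without a
    TPM get one computed over the input set.
    """
    if any(t.tpm is None for t in transcripts):
        compute_tpm(list(transcripts))
    fams = [r for r in instances if target_family is None or r.family == target_family]
    calls: list[ChimericCall] = []
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        if require_spliced and len(t.exons) < 2:
            continue
        p5 = t.five_prime
        for inst in fams:
            if inst.chrom != t.chrom:
                continue
            lo, hi = inst.start - window, inst.end + window
            if upstream_only:
                if t.strand == "+":
                    lo, hi = inst.start - window, inst.end
                else:
                    lo, hi = inst.start, inst.end + window
            if lo <= p5 < hi:
                calls.append(
                    ChimericCall(
                        t.transcript_id, inst.instance_id, p5 - inst.start,
                        float(t.tpm), bool(t.tpm > tpm_min),
                    )
                )
                break
    return calls
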
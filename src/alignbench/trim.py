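"""Quality trimming of reads from both ends, with discard accounting.

The protocol trims from the 5' and the 3' end until reaching a base with
quality strictly above the threshold (default Phred 20), then discards
reads that end up shorter than the minimum length (default 24) or that
retain more than the allowed number of N bases (default 2).  The threshold
comparison is strict: a base with Q = 21 stops the trim, Q = 20 is
removed.  N bases are counted on the trimmed read by default (the
constraint applies to what the trimmer outputs); ``count_n_pre_trim``
switches to counting on the raw read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .simulate import SimulatedRead


@dataclass(frozen=True)
class TrimPolicy:
    q_threshold: int = 20
    max_n: int = 2
    min_length: int = 24
    count_n_pre_trim: bool = False

    def __post_init__(self):
        if self.q_threshold < 0:
            raise ValueError("q_threshold must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class TrimOutcome:
    status: str  # "kept" | "discarded"
    trimmed_5p: int = 0
    trimmed_3p: int = 0
    reason: Optional[str] = None  # "too_short" | "too_many_n" when discarded


@dataclass
class TrimReport:
    total: int = 0
    kept: int = 0
    discarded_too_short: int = 0
    discarded_too_many_n: int = 0
    length_histogram: Dict[int, int] = None

    def __post_init__(self):
        if self.length_histogram is None:
            self.length_histogram = {}

    @property
    def discarded(self) -> int:
        return self.discarded_too_short + self.discarded_too_many_n

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "kept": self.kept,
            "discarded": self.discarded,
            "discarded_too_short": self.discarded_too_short,
            "discarded_too_many_n": self.discarded_too_many_n,
            "length_histogram": dict(sorted(self.length_histogram.items())),
        }


def trim_read(
    sequence: str, qualities: Sequence[int], policy: TrimPolicy = TrimPolicy()
) -> Tuple[str, List[int], TrimOutcome]:
    """Trim one read; returns (trimmed sequence, trimmed qualities, outcome).

    Removes the maximal prefix and maximal suffix of bases with
    Q <= q_threshold, then discards if the remainder is shorter than
    min_length or carries more than max_n N bases.  Kept reads therefore
    start and end with a base of Q > q_threshold.
    """
    if len(sequence) != len(qualities):
        raise ValueError("sequence and qualities must have equal length")

    n = len(sequence)
    lo = 0
    while lo < n and qualities[lo] <= policy.q_threshold:
        lo += 1
    hi = n
    while hi > lo and qualities[hi - 1] <= policy.q_threshold:
        hi -= 1

    trimmed_seq = sequence[lo:hi]
    trimmed_quals = list(qualities[lo:hi])
    outcome = TrimOutcome(status="kept", trimmed_5p=lo, trimmed_3p=n - hi)

    if len(trimmed_seq) < policy.min_length:
        outcome.status = "discarded"
        outcome.reason = "too_short"
        return trimmed_seq, trimmed_quals, outcome

    n_count = (sequence if policy.count_n_pre_trim else trimmed_seq).count("N")
    if n_count > policy.max_n:
        outcome.status = "discarded"
        outcome.reason = "too_many_n"
    return trimmed_seq, trimmed_quals, outcome


def trim_reads(
    reads: Iterable[SimulatedRead], policy: TrimPolicy = TrimPolicy()
) -> Tuple[List[SimulatedRead], TrimReport]:
    """Trim a stream of reads; kept reads pass through with IDs unchanged.

    The 5'-trim shifts the origin coordinate of a kept read: for a
    plus-strand read the leftmost reference position advances by the bases
    removed at the 5' end, for a minus-strand read by the bases removed at
    the 3' end (which sit leftmost on the reference).  Origin positions are
    updated accordingly so truth comparison stays exact.
    """
    kept: List[SimulatedRead] = []
    report = TrimReport()
    for read in reads:
        report.total += 1
        seq, quals, outcome = trim_read(read.sequence, read.qualities, policy)
        if outcome.status != "kept":
            if outcome.reason == "too_short":
                report.discarded_too_short += 1
            else:
                report.discarded_too_many_n += 1
            continue
        report.kept += 1
        report.length_histogram[len(seq)] = report.length_histogram.get(len(seq), 0) + 1
        left_shift = (
            outcome.trimmed_5p if read.origin_strand == "+" else outcome.trimmed_3p
        )
        offsets = [
            o - outcome.trimmed_5p
            for o in read.mismatch_offsets
            if outcome.trimmed_5p <= o < outcome.trimmed_5p + len(seq)
        ]
        kept.append(
            SimulatedRead(
                read_id=read.read_id,
                sequence=seq,
                qualities=quals,
                origin_chrom=read.origin_chrom,
                origin_pos=read.origin_pos + left_shift,
                origin_strand=read.origin_strand,
                mismatch_offsets=offsets,
            )
        )
    return kept, report


def trim_fastq(
    in_path, out_path, policy: TrimPolicy = TrimPolicy(), encoding: str = "phred33"
) -> TrimReport:
    """Trim a FASTQ file to another FASTQ file; returns the trim report."""
    from .simulate import read_fastq, write_fastq

    reads = read_fastq(in_path, encoding=encoding)
    kept, report = trim_reads(reads, policy)
    write_fastq(kept, out_path, encoding=encoding)
    return report
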
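"""Alignment normalization: SAM ingestion and an exhaustive oracle aligner.

External aligners are compared through a single normalized record type.
SAM files (from any aligner) are ingested with the study's filters: only
primary alignments, unmapped flags become "unaligned", records exceeding
the mismatch budget (NM tag) become "unaligned", and an optional MAPQ
floor can be applied.

The built-in oracle aligner finds *all* locations on both strands where a
read matches the reference within the mismatch budget (Hamming distance;
reference N mismatches everything), making it an exact reference semantics
for "best hit" (fewest mismatches) alignment.  Internally it uses a
pigeonhole-seeded search — the read is split into ``budget + 1`` chunks,
at least one of which must match exactly at any within-budget location, so
exact chunk lookup in a substring index followed by full Hamming
verification enumerates the complete hit set.  Two reporting modes mirror
the study: ``random_one`` picks uniformly among the minimum-distance hits
(seeded per read, order-independent), ``unique_only`` suppresses any read
with more than one location.
"""

from __future__ import annotations

import hashlib
import logging
import random
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pysam

from .refspace import ReferenceGenome, reverse_complement
from .simulate import SimulatedRead

logger = logging.getLogger("alignbench")

STATUS_ALIGNED = "aligned"
STATUS_UNALIGNED = "unaligned"
STATUS_SUPPRESSED = "suppressed"

MODE_RANDOM_ONE = "random_one"
MODE_UNIQUE_ONLY = "unique_only"


@dataclass
class AlignmentRecord:
    read_id: str
    status: str
    chrom: Optional[str] = None
    pos: Optional[int] = None  # 0-based leftmost
    strand: Optional[str] = None
    n_mismatches: Optional[int] = None
    mapq: Optional[int] = None
    n_hits: Optional[int] = None

    def __post_init__(self):
        if self.status == STATUS_ALIGNED:
            if self.chrom is None or self.pos is None or self.strand is None:
                raise ValueError(f"aligned record {self.read_id} missing coordinates")
        if self.status == STATUS_SUPPRESSED and (self.n_hits or 0) < 2:
            raise ValueError(f"suppressed record {self.read_id} needs n_hits >= 2")

    @property
    def is_aligned(self) -> bool:
        return self.status == STATUS_ALIGNED


@dataclass
class AlignmentSet:
    """Per-read alignment records from one aligner run, keyed by read_id."""

    label: str
    mode: str
    records: Dict[str, AlignmentRecord] = field(default_factory=dict)
    max_mismatches: Optional[int] = None
    n_secondary_ignored: int = 0
    n_missing_nm: int = 0

    def add(self, record: AlignmentRecord) -> None:
        if record.read_id in self.records:
            raise ValueError(f"duplicate read_id {record.read_id}")
        self.records[record.read_id] = record

    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def n_aligned(self) -> int:
        return sum(1 for r in self.records.values() if r.is_aligned)

    def aligned_fraction(self) -> float:
        return self.n_aligned / self.n_total if self.n_total else 0.0


# ---------------------------------------------------------------------------
# SAM ingestion
# ---------------------------------------------------------------------------

def ingest_sam(
    path,
    max_mismatches: Optional[int] = 2,
    mapq_min: Optional[int] = None,
    label: str = "external",
    mode: str = "unknown",
) -> AlignmentSet:
    """Normalize a SAM file into an :class:`AlignmentSet`.

    One record per read, taken from the primary alignment (secondary and
    supplementary records are counted and ignored).  Unmapped reads, reads
    with NM above ``max_mismatches``, and reads with MAPQ below
    ``mapq_min`` become "unaligned".  Records lacking an NM tag when NM
    filtering is requested are kept with unknown mismatch count, exempt
    from the NM filter, and counted in ``n_missing_nm``.  pysam reports
    0-based coordinates, matching the internal convention.
    """
    aset = AlignmentSet(label=label, mode=mode, max_mismatches=max_mismatches)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                aset.n_secondary_ignored += 1
                continue
            if rec.is_unmapped:
                aset.add(AlignmentRecord(rec.query_name, STATUS_UNALIGNED))
                continue
            nm: Optional[int] = None
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif max_mismatches is not None:
                aset.n_missing_nm += 1
                logger.warning(
                    "record %s lacks NM tag; kept, exempt from mismatch filter",
                    rec.query_name,
                )
            mapq = rec.mapping_quality
            if max_mismatches is not None and nm is not None and nm > max_mismatches:
                aset.add(
                    AlignmentRecord(rec.query_name, STATUS_UNALIGNED, n_mismatches=nm)
                )
                continue
            if mapq_min is not None and mapq < mapq_min:
                aset.add(
                    AlignmentRecord(
                        rec.query_name, STATUS_UNALIGNED, n_mismatches=nm, mapq=mapq
                    )
                )
                continue
            aset.add(
                AlignmentRecord(
                    read_id=rec.query_name,
                    status=STATUS_ALIGNED,
                    chrom=rec.reference_name,
                    pos=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    n_mismatches=nm,
                    mapq=mapq,
                )
            )
    return aset


# ---------------------------------------------------------------------------
# oracle aligner
# ---------------------------------------------------------------------------

def _chunk_spans(read_length: int, n_chunks: int) -> List[Tuple[int, int]]:
    """Split [0, read_length) into n_chunks near-equal spans."""
    base = read_length // n_chunks
    extra = read_length % n_chunks
    spans = []
    start = 0
    for i in range(n_chunks):
        ln = base + (1 if i < extra else 0)
        spans.append((start, ln))
        start += ln
    return spans


class _SubstringIndex:
    """Exact-match lookup of fixed-length substrings over a genome."""

    def __init__(self, genome: ReferenceGenome, lengths: Sequence[int]):
        self.tables: Dict[int, Dict[str, List[Tuple[str, int]]]] = {}
        for ln in sorted(set(lengths)):
            table: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
            for chrom, seq in genome.sequences.items():
                for i in range(len(seq) - ln + 1):
                    table[seq[i : i + ln]].append((chrom, i))
            self.tables[ln] = dict(table)

    def lookup(self, substring: str) -> List[Tuple[str, int]]:
        return self.tables[len(substring)].get(substring, [])


def _hamming_at_most(a: str, b: str, limit: int) -> Optional[int]:
    """Hamming distance of equal-length strings, or None if it exceeds limit.

    Reference N mismatches every read base (reads contain no N by
    construction; an N in the read likewise never matches reference N
    because the comparison is literal only for A/C/G/T-vs-same).
    """
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            d += 1
            if d > limit:
                return None
    return d


def find_all_hits(
    sequence: str,
    genome: ReferenceGenome,
    max_mismatches: int,
    index: Optional[_SubstringIndex] = None,
) -> List[Tuple[str, int, str, int]]:
    """All (chrom, leftmost pos, strand, n_mismatches) within the budget.

    Equivalent to a full both-strand sliding scan; tests verify this
    against an independent naive implementation.
    """
    L = len(sequence)
    spans = _chunk_spans(L, max_mismatches + 1)
    if index is None:
        index = _SubstringIndex(genome, [ln for _, ln in spans])
    hits: Dict[Tuple[str, int, str], int] = {}
    for strand in "+-":
        query = sequence if strand == "+" else reverse_complement(sequence)
        seen_candidates = set()
        for off, ln in spans:
            for chrom, p in index.lookup(query[off : off + ln]):
                start = p - off
                if start < 0:
                    continue
                seq = genome.sequences[chrom]
                if start + L > len(seq):
                    continue
                key = (chrom, start)
                if key in seen_candidates:
                    continue
                seen_candidates.add(key)
                d = _hamming_at_most(seq[start : start + L], query, max_mismatches)
                if d is not None:
                    hits[(chrom, start, strand)] = d
    return sorted((c, p, s, d) for (c, p, s), d in hits.items())


def _read_rng(seed: int, read_id: str) -> random.Random:
    """Order-independent per-read RNG derived from (global seed, read_id)."""
    digest = hashlib.sha256(f"{seed}:{read_id}".encode()).digest()
    return random.Random(int.from_bytes(digest[:8], "big"))


def oracle_align(
    reads: Sequence[Union[SimulatedRead, Tuple[str, str]]],
    genome: ReferenceGenome,
    max_mismatches: int = 2,
    mode: str = MODE_RANDOM_ONE,
    seed: int = 0,
    unique_scope: str = "budget",
    label: str = "oracle",
) -> AlignmentSet:
    """Exhaustive best-hit alignment of uniform-length reads.

    For each read the complete hit set within ``max_mismatches`` is
    enumerated on both strands; "best" hits are those at the minimum
    distance.  ``random_one`` reports one best hit drawn uniformly with a
    per-read seeded RNG and sets ``n_hits`` to the best-stratum size.
    ``unique_only`` reports the hit only when the read's multiplicity is 1,
    otherwise the read is suppressed; multiplicity counts every hit within
    the budget by default (``unique_scope="budget"``) or only the best
    stratum with ``unique_scope="best"``.  Reads with no hit (including
    reads longer than every chromosome) are unaligned.

    MAPQ follows the familiar unique/ambiguous convention: 37 when the read
    has a single within-budget hit, else 0.
    """
    if mode not in (MODE_RANDOM_ONE, MODE_UNIQUE_ONLY):
        raise ValueError(f"unknown mode {mode!r}")
    if unique_scope not in ("budget", "best"):
        raise ValueError(f"unknown unique_scope {unique_scope!r}")

    norm: List[Tuple[str, str]] = []
    for item in reads:
        if isinstance(item, SimulatedRead):
            norm.append((item.read_id, item.sequence))
        else:
            rid, seq = item
            norm.append((rid, seq.upper()))
    lengths = {len(seq) for _, seq in norm}
    if len(lengths) > 1:
        raise ValueError("oracle_align requires uniform read length")

    index = None
    if norm:
        L = lengths.pop()
        spans = _chunk_spans(L, max_mismatches + 1)
        if any(ln < 1 for _, ln in spans):
            raise ValueError("read length must exceed the mismatch budget")
        index = _SubstringIndex(genome, [ln for _, ln in spans])

    aset = AlignmentSet(label=label, mode=mode, max_mismatches=max_mismatches)
    for read_id, seq in norm:
        hits = find_all_hits(seq, genome, max_mismatches, index=index)
        if not hits:
            aset.add(AlignmentRecord(read_id, STATUS_UNALIGNED))
            continue
        min_d = min(h[3] for h in hits)
        stratum = [h for h in hits if h[3] == min_d]
        mapq = 37 if len(hits) == 1 else 0

        if mode == MODE_RANDOM_ONE:
            chrom, pos, strand, d = _read_rng(seed, read_id).choice(stratum)
            aset.add(
                AlignmentRecord(
                    read_id,
                    STATUS_ALIGNED,
                    chrom=chrom,
                    pos=pos,
                    strand=strand,
                    n_mismatches=d,
                    mapq=mapq,
                    n_hits=len(stratum),
                )
            )
        else:
            multiplicity = len(hits) if unique_scope == "budget" else len(stratum)
            if multiplicity == 1:
                chrom, pos, strand, d = stratum[0]
                aset.add(
                    AlignmentRecord(
                        read_id,
                        STATUS_ALIGNED,
                        chrom=chrom,
                        pos=pos,
                        strand=strand,
                        n_mismatches=d,
                        mapq=mapq,
                        n_hits=1,
                    )
                )
            else:
                aset.add(
                    AlignmentRecord(
                        read_id, STATUS_SUPPRESSED, n_hits=multiplicity
                    )
                )
    return aset


# ---------------------------------------------------------------------------
# SAM output and MAPQ summaries
# ---------------------------------------------------------------------------

def write_sam(
    aset: AlignmentSet,
    reads: Sequence[SimulatedRead],
    genome: ReferenceGenome,
    path,
) -> None:
    """Write an alignment set as SAM (suppressed/unaligned reads as unmapped)."""
    names = list(genome.sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(genome.sequences[n])} for n in names],
        "PG": [{"ID": "alignbench", "PN": f"alignbench-{aset.label}"}],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            rec = aset.records.get(read.read_id)
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.read_id
            if rec is not None and rec.is_aligned:
                seq = (
                    read.sequence
                    if rec.strand == "+"
                    else reverse_complement(read.sequence)
                )
                quals = (
                    read.qualities if rec.strand == "+" else read.qualities[::-1]
                )
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in quals)
                )
                a.flag = 16 if rec.strand == "-" else 0
                a.reference_id = tid[rec.chrom]
                a.reference_start = rec.pos
                a.mapping_quality = rec.mapq if rec.mapq is not None else 255
                a.cigarstring = f"{len(seq)}M"
                tags = []
                if rec.n_mismatches is not None:
                    tags.append(("NM", rec.n_mismatches))
                if rec.n_hits is not None:
                    tags.append(("XH", rec.n_hits))
                a.tags = tags
            else:
                a.query_sequence = read.sequence
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in read.qualities)
                )
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
            out.write(a)


def mapq_histogram(aset: AlignmentSet) -> Tuple[Dict[int, int], int]:
    """Counts of MAPQ values over aligned records.

    Returns (histogram, n_without_mapq); records lacking a MAPQ are tallied
    separately, so ``sum(histogram.values()) + n_without_mapq`` equals the
    aligned count.
    """
    hist: Counter = Counter()
    missing = 0
    for rec in aset.records.values():
        if not rec.is_aligned:
            continue
        if rec.mapq is None:
            missing += 1
        else:
            hist[rec.mapq] += 1
    return dict(sorted(hist.items())), missing
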
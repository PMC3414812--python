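"""Read simulation under controlled mismatch-count / quality-band scenarios.

Four scenarios cross the number of injected mismatches (1 or 2) with the
Phred band assigned to the mismatched bases: HIGH (30-40, mimicking true
novel single-nucleotide variants, which tend to be called confidently) or
LOW (5-15, mimicking pure sequencing errors).  Non-mismatch bases always
draw from the HIGH band.  Every read carries a machine-readable truth
channel (origin chromosome, leftmost forward-strand position, strand, and
the mutated read offsets), so downstream accuracy scoring needs no
bookkeeping beyond the read ID and a truth table.

Phred convention: Q = -10*log10(p) for base-calling error probability p,
so Q30 is one error in a thousand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .refspace import GenomicRegion, ReferenceGenome, reverse_complement

#: Phred bands (closed integer intervals)
LOW_BAND = (5, 15)
HIGH_BAND = (30, 40)

_FASTQ_FORMAT = {"phred33": "fastq", "phred64": "fastq-illumina"}
_MAX_ENCODABLE = {"phred33": 93, "phred64": 62}


def phred_quality(p: float) -> float:
    """Phred score of a base-calling error probability: Q = -10*log10(p)."""
    if not 0 < p <= 1:
        raise ValueError("error probability must be in (0, 1]")
    return -10.0 * math.log10(p)


@dataclass(frozen=True)
class QualityScenario:
    """Mismatch count and quality-band assignment for simulated reads."""

    n_mismatches: int
    mismatch_band: Tuple[int, int] = HIGH_BAND
    background_band: Tuple[int, int] = HIGH_BAND

    def __post_init__(self):
        if self.n_mismatches not in (1, 2):
            raise ValueError("n_mismatches must be 1 or 2")
        for lo, hi in (self.mismatch_band, self.background_band):
            if lo > hi or lo < 0:
                raise ValueError("quality bands are closed intervals of Phred >= 0")

    @classmethod
    def make(cls, n_mismatches: int, mismatch_quality: str) -> "QualityScenario":
        """Factory by band name: ``make(2, "low")`` etc."""
        band = {"low": LOW_BAND, "high": HIGH_BAND}[mismatch_quality.lower()]
        return cls(n_mismatches=n_mismatches, mismatch_band=band)

    @property
    def label(self) -> str:
        band = "low" if self.mismatch_band == LOW_BAND else "high"
        return f"mm{self.n_mismatches}_{band}"


#: the four study scenarios
SCENARIOS = (
    QualityScenario.make(1, "high"),
    QualityScenario.make(2, "high"),
    QualityScenario.make(1, "low"),
    QualityScenario.make(2, "low"),
)


@dataclass
class SimulatedRead:
    """One simulated read plus its origin truth.

    ``origin_pos`` is always the leftmost forward-reference coordinate of
    the source window, for both strands (the SAM POS convention), and
    ``mismatch_offsets`` are read-coordinate offsets, i.e. positions in the
    sequence as an aligner sees it (after reverse complementing for minus-
    strand reads).
    """

    read_id: str
    sequence: str
    qualities: List[int]
    origin_chrom: str
    origin_pos: int
    origin_strand: str
    mismatch_offsets: List[int] = field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")
        if self.origin_strand not in "+-":
            raise ValueError("strand must be + or -")


def _format_read_id(
    serial: int, chrom: str, pos: int, strand: str, offsets: Sequence[int]
) -> str:
    offs = ",".join(str(o) for o in offsets)
    return f"r{serial}|{chrom}|{pos}|{strand}|{offs}"


def parse_read_id(read_id: str) -> Tuple[str, int, str, List[int]]:
    """Recover (chrom, pos, strand, mismatch_offsets) from a simulated read ID."""
    _, chrom, pos, strand, offs = read_id.split("|")
    offsets = [int(x) for x in offs.split(",")] if offs else []
    return chrom, int(pos), strand, offsets


def simulate_reads(
    genome: ReferenceGenome,
    regions: Sequence[GenomicRegion],
    scenario: QualityScenario,
    n_reads: int,
    read_length: int = 50,
    strands: str = "both",
    seed: int = 0,
    max_redraws: int = 1000,
) -> List[SimulatedRead]:
    """Draw reads uniformly over all valid (region, offset) start pairs.

    Start positions are uniform over every window of ``read_length`` fully
    inside a region; the strand is drawn per read when ``strands="both"``.
    Exactly ``scenario.n_mismatches`` distinct read offsets are mutated to a
    uniformly chosen different base; those offsets get qualities uniform in
    the mismatch band, all others uniform in the background band.  Windows
    containing reference N are rejected and redrawn, so the Hamming
    distance between each read and its origin window is exactly the
    scenario's mismatch count.  Deterministic given ``seed``.

    Regions shorter than ``read_length`` are skipped with a warning; if no
    region is usable a ValueError is raised.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")

    usable: List[GenomicRegion] = []
    for region in regions:
        if len(region) < read_length:
            warnings.warn(
                f"region {region.chrom}:{region.start}-{region.end} shorter "
                f"than read length {read_length}; skipped"
            )
            continue
        if region.chrom not in genome.sequences:
            raise KeyError(f"region chromosome {region.chrom!r} not in genome")
        if region.end > len(genome.sequences[region.chrom]):
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} outside genome"
            )
        usable.append(region)
    if not usable:
        raise ValueError("no region long enough to draw reads from")

    rng = np.random.default_rng(seed)
    n_starts = np.array([len(r) - read_length + 1 for r in usable])
    cum = np.cumsum(n_starts)
    total_starts = int(cum[-1])

    bases = np.array(list("ACGT"))
    reads: List[SimulatedRead] = []
    for serial in range(n_reads):
        window = None
        for _ in range(max_redraws):
            flat = int(rng.integers(0, total_starts))
            ridx = int(np.searchsorted(cum, flat, side="right"))
            offset = flat - (int(cum[ridx - 1]) if ridx else 0)
            region = usable[ridx]
            pos = region.start + offset
            candidate = genome.sequences[region.chrom][pos : pos + read_length]
            if "N" not in candidate:
                window = candidate
                break
        if window is None:
            raise ValueError("could not draw an N-free window; too many Ns in regions")

        strand = "+"
        if strands == "both" and rng.integers(0, 2):
            strand = "-"
        seq = window if strand == "+" else reverse_complement(window)

        offsets = sorted(
            int(o)
            for o in rng.choice(read_length, size=scenario.n_mismatches, replace=False)
        )
        seq_arr = np.array(list(seq))
        for off in offsets:
            others = bases[bases != seq_arr[off]]
            seq_arr[off] = others[int(rng.integers(0, 3))]

        lo_b, hi_b = scenario.background_band
        quals = rng.integers(lo_b, hi_b + 1, size=read_length)
        lo_m, hi_m = scenario.mismatch_band
        for off in offsets:
            quals[off] = rng.integers(lo_m, hi_m + 1)

        reads.append(
            SimulatedRead(
                read_id=_format_read_id(serial, region.chrom, pos, strand, offsets),
                sequence="".join(seq_arr),
                qualities=[int(q) for q in quals],
                origin_chrom=region.chrom,
                origin_pos=pos,
                origin_strand=strand,
                mismatch_offsets=offsets,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# FASTQ + truth I/O
# ---------------------------------------------------------------------------

def write_fastq(
    reads: Sequence[SimulatedRead],
    fastq_path,
    truth_path=None,
    encoding: str = "phred33",
) -> None:
    """Write reads as FASTQ (phred33 or phred64) and, optionally, a truth TSV.

    The truth TSV has columns (read_id, chrom, pos, strand, n_mismatches)
    and round-trips through :func:`read_truth`.
    """
    fmt = _FASTQ_FORMAT[encoding]
    limit = _MAX_ENCODABLE[encoding]
    records = []
    for read in reads:
        if max(read.qualities) > limit or min(read.qualities) < 0:
            raise ValueError(
                f"quality outside {encoding} encodable range [0, {limit}] "
                f"for read {read.read_id}"
            )
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(read.qualities)
        records.append(rec)
    SeqIO.write(records, fastq_path, fmt)
    if truth_path is not None:
        write_truth(reads, truth_path)


def read_fastq(path, encoding: str = "phred33") -> List[SimulatedRead]:
    """Read FASTQ back into :class:`SimulatedRead` objects.

    Truth fields are recovered from the read ID when it follows the
    simulator's ``r{n}|chrom|pos|strand|offsets`` convention; otherwise the
    origin fields are placeholders (chrom "*", pos -1).
    """
    fmt = _FASTQ_FORMAT[encoding]
    out = []
    for rec in SeqIO.parse(path, fmt):
        quals = list(rec.letter_annotations["phred_quality"])
        try:
            chrom, pos, strand, offsets = parse_read_id(rec.id)
        except (ValueError, KeyError):
            chrom, pos, strand, offsets = "*", -1, "+", []
        out.append(
            SimulatedRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=quals,
                origin_chrom=chrom,
                origin_pos=pos if pos >= 0 else 0,
                origin_strand=strand,
                mismatch_offsets=offsets,
            )
        )
    return out


def write_truth(reads: Sequence[SimulatedRead], path) -> None:
    df = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "chrom": [r.origin_chrom for r in reads],
            "pos": [r.origin_pos for r in reads],
            "strand": [r.origin_strand for r in reads],
            "n_mismatches": [len(r.mismatch_offsets) for r in reads],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    """Truth table indexed by read_id with columns chrom, pos, strand, n_mismatches."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df.set_index("read_id")


def truth_from_reads(reads: Sequence[SimulatedRead]) -> pd.DataFrame:
    """Build the in-memory truth table directly from simulated reads."""
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "chrom": [r.origin_chrom for r in reads],
            "pos": [r.origin_pos for r in reads],
            "strand": [r.origin_strand for r in reads],
            "n_mismatches": [len(r.mismatch_offsets) for r in reads],
        }
    ).set_index("read_id")


# ---------------------------------------------------------------------------
# per-cycle quality profile
# ---------------------------------------------------------------------------

def per_cycle_quality_profile(
    source: Union[str, Sequence[SimulatedRead]], encoding: str = "phred33"
) -> pd.DataFrame:
    """Mean and population SD of Phred scores at each read cycle.

    ``source`` is a FASTQ path or a sequence of reads.  Cycles are 1-based;
    reads shorter than a cycle are ignored at that cycle.  Raises on empty
    input.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        reads = read_fastq(source, encoding=encoding)
    else:
        reads = list(source)
    if not reads:
        raise ValueError("no reads to profile")
    max_len = max(len(r.qualities) for r in reads)
    rows = []
    for cycle in range(max_len):
        vals = np.array([r.qualities[cycle] for r in reads if len(r.qualities) > cycle])
        rows.append(
            {
                "cycle": cycle + 1,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std()),  # population SD
            }
        )
    return pd.DataFrame(rows)
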
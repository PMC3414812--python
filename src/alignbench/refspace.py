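"""Reference workspaces: synthetic genomes, repeat annotation, region
selection, and k-mer mapability tracks.

A benchmark of read aligners needs a reference whose repeat structure is
known exactly.  Rather than depending on a full genome assembly plus a
RepeatMasker track, this module synthesises genomes with an i.i.d.-uniform
background into which repeat units are copied a controlled number of times
(optionally with per-copy divergence), recording every copy footprint as
the repeat annotation.  On top of that it provides the two region-level
analyses used downstream: selecting "repetitive" regions by a
repeat-fraction / repeat-run criterion, and scoring per-position
mapability as 1/occurrences of the k-mer starting there (the Duke
uniqueness convention: 1, 0.5, 1/3, 0.25, or 0 for >4 occurrences).

All coordinates are 0-based half-open; conversion to 1-based happens only
at SAM boundaries (see :mod:`alignbench.alignio`).
"""

from __future__ import annotations

import io
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: mapability score is clamped to 0 beyond this many genome-wide occurrences
MAX_MAPABILITY_COUNT = 4


class PlacementError(RuntimeError):
    """Repeat copies could not be placed without overlap."""


class BoundsError(ValueError):
    """A region lies outside its chromosome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """Uppercase DNA sequences over {A,C,G,T,N}, keyed by chromosome name."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome has no chromosomes")
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if set(seq) - set("ACGTN"):
                raise ValueError(f"chromosome {name!r} has non-ACGTN characters")

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
        return cls(seqs)


@dataclass
class RepeatAnnotation:
    """Intervals (chrom, start, end) marked repetitive, 0-based half-open."""

    intervals: List[Tuple[str, int, int]] = field(default_factory=list)

    def merged(self) -> Dict[str, List[Tuple[int, int]]]:
        """Per-chromosome intervals, sorted and merged where adjacent/overlapping."""
        by_chrom: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
        for chrom, start, end in self.intervals:
            by_chrom[chrom].append((start, end))
        out: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: List[Tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            out[chrom] = merged
        return out

    def to_bed(self, path) -> None:
        write_bed(
            [GenomicRegion(c, s, e, name="repeat") for c, s, e in self.intervals],
            path,
        )

    @classmethod
    def from_bed(cls, path) -> "RepeatAnnotation":
        return cls([(r.chrom, r.start, r.end) for r in read_bed(path)])


@dataclass
class GenomicRegion:
    """A half-open genomic interval, optionally annotated with repeat content.

    ``repeat_fraction`` and ``longest_repeat_run`` are filled in by
    :func:`annotate_regions` / :func:`select_repetitive_regions`; they are
    ``None`` on freshly constructed regions.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    repeat_fraction: Optional[float] = None
    longest_repeat_run: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class MapabilityTrack:
    """Per-position k-mer uniqueness scores.

    ``scores[chrom][i]`` is 1/c for the k-mer starting at i occurring c
    times genome-wide (0 when c > 4); positions with fewer than k bases
    remaining carry no entry (arrays are length L - k + 1).
    """

    scores: Dict[str, np.ndarray]
    k: int

    def to_bedgraph(self, path) -> None:
        """Write as bedGraph-style TSV (chrom, start, end, score), merging runs."""
        handle = open(path, "w") if not hasattr(path, "write") else path
        close = handle is not path
        try:
            for chrom, arr in self.scores.items():
                i = 0
                n = len(arr)
                while i < n:
                    j = i
                    while j + 1 < n and arr[j + 1] == arr[i]:
                        j += 1
                    handle.write(f"{chrom}\t{i}\t{j + 1}\t{arr[i]:.6g}\n")
                    i = j + 1
        finally:
            if close:
                handle.close()


# ---------------------------------------------------------------------------
# BED I/O (0-based half-open, standard BED semantics)
# ---------------------------------------------------------------------------

def read_bed(path) -> List[GenomicRegion]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    regions = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if len(row) > 3 else ""
        regions.append(GenomicRegion(str(row[0]), int(row[1]), int(row[2]), name=name))
    return regions


def write_bed(regions: Sequence[GenomicRegion], path) -> None:
    rows = [(r.chrom, r.start, r.end, r.name or ".") for r in regions]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# synthetic genome generation
# ---------------------------------------------------------------------------

def generate_synthetic_genome(
    n_chroms: int = 1,
    chrom_length: int = 100_000,
    repeat_units: Sequence[Tuple[int, int, float]] = (),
    seed: int = 0,
    max_placement_attempts: int = 10_000,
) -> Tuple[ReferenceGenome, RepeatAnnotation]:
    """Generate a genome of i.i.d.-uniform bases with planted repeat families.

    Each ``(unit_length, copies, divergence)`` entry creates one random
    unit sequence and pastes it ``copies`` times at non-overlapping,
    uniformly drawn positions (across all chromosomes), mutating each copy
    independently at per-base rate ``divergence``.  Every copy footprint is
    recorded in the returned :class:`RepeatAnnotation`.  Fully reproducible
    from ``seed``.

    Raises
    ------
    PlacementError
        if a copy cannot be placed without overlapping earlier placements.
    """
    if n_chroms < 1 or chrom_length < 1:
        raise ValueError("need at least one chromosome of positive length")
    total_repeat = sum(ul * c for ul, c, _ in repeat_units)
    for unit_length, copies, divergence in repeat_units:
        if copies < 2:
            raise ValueError("each repeat unit needs at least 2 copies")
        if unit_length < 1:
            raise ValueError("repeat unit length must be positive")
        if not 0.0 <= divergence <= 1.0:
            raise ValueError("divergence must be a fraction in [0, 1]")
    if repeat_units and total_repeat >= chrom_length:
        raise ValueError("total repeat length must be below chrom_length")

    rng = np.random.default_rng(seed)
    bases = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    chroms = {
        name: bytearray(bases[rng.integers(0, 4, size=chrom_length)].tobytes())
        for name in chrom_names
    }

    occupied: Dict[str, List[Tuple[int, int]]] = {name: [] for name in chrom_names}
    annotation = RepeatAnnotation()
    for unit_length, copies, divergence in repeat_units:
        unit = bases[rng.integers(0, 4, size=unit_length)]
        for _ in range(copies):
            placed = False
            for _attempt in range(max_placement_attempts):
                chrom = chrom_names[int(rng.integers(0, n_chroms))]
                start = int(rng.integers(0, chrom_length - unit_length + 1))
                end = start + unit_length
                if all(e <= start or end <= s for s, e in occupied[chrom]):
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place a {unit_length}-bp copy without overlap"
                )
            copy = unit.copy()
            if divergence > 0:
                hits = np.nonzero(rng.random(unit_length) < divergence)[0]
                for pos in hits:
                    # mutate to one of the three other bases
                    cur = copy[pos]
                    choices = bases[bases != cur]
                    copy[pos] = choices[int(rng.integers(0, 3))]
            chroms[chrom][start:end] = copy.tobytes()
            occupied[chrom].append((start, end))
            annotation.intervals.append((chrom, start, end))

    genome = ReferenceGenome({n: chroms[n].decode() for n in chrom_names})
    return genome, annotation


# ---------------------------------------------------------------------------
# repetitive-region selection
# ---------------------------------------------------------------------------

def _region_repeat_stats(
    region: GenomicRegion, merged: Dict[str, List[Tuple[int, int]]]
) -> Tuple[float, int]:
    """(fraction of region bases repetitive, longest repetitive run clipped
    to the region), measured on merged annotation intervals."""
    total = 0
    longest = 0
    for s, e in merged.get(region.chrom, []):
        lo = max(s, region.start)
        hi = min(e, region.end)
        if hi > lo:
            total += hi - lo
            longest = max(longest, hi - lo)
    return total / len(region), longest


def annotate_regions(
    regions: Sequence[GenomicRegion], annot: RepeatAnnotation
) -> List[GenomicRegion]:
    """Return copies of ``regions`` with repeat_fraction / longest_repeat_run set."""
    merged = annot.merged()
    out = []
    for region in regions:
        frac, run = _region_repeat_stats(region, merged)
        out.append(replace(region, repeat_fraction=frac, longest_repeat_run=run))
    return out


def select_repetitive_regions(
    regions: Sequence[GenomicRegion],
    annot: RepeatAnnotation,
    min_fraction: float = 0.25,
    min_run: int = 50,
    genome: Optional[ReferenceGenome] = None,
) -> List[GenomicRegion]:
    """Filter regions by repeat content.

    A region qualifies when at least ``min_fraction`` of its bases overlap
    repetitive intervals AND it contains a contiguous repetitive run of at
    least ``min_run`` bp (runs measured on merged annotation intervals,
    clipped to the region).  Input order is preserved.

    When ``genome`` is given, regions outside chromosome bounds raise
    :class:`BoundsError`.
    """
    if genome is not None:
        lengths = genome.lengths
        for region in regions:
            if region.chrom not in lengths or region.end > lengths[region.chrom]:
                raise BoundsError(
                    f"region {region.chrom}:{region.start}-{region.end} "
                    "outside genome bounds"
                )
    selected = []
    for region in annotate_regions(regions, annot):
        if region.repeat_fraction >= min_fraction and region.longest_repeat_run >= min_run:
            selected.append(region)
    return selected


# ---------------------------------------------------------------------------
# mapability
# ---------------------------------------------------------------------------

def compute_mapability(
    genome: ReferenceGenome, k: int = 35, fold_strands: bool = False
) -> MapabilityTrack:
    """Score each k-mer start position by 1/(genome-wide occurrence count).

    Counts occurrences of the forward-strand k-mer over the forward text of
    all chromosomes; with ``fold_strands`` the reverse complement's forward
    occurrences are added (palindromic k-mers are not double-counted).
    Scores are 1, 0.5, 1/3, 0.25, and 0 for more than four occurrences.
    k-mers containing N score 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    for seq in genome.sequences.values():
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1

    scores: Dict[str, np.ndarray] = {}
    for name, seq in genome.sequences.items():
        n = max(len(seq) - k + 1, 0)
        arr = np.zeros(n, dtype=float)
        for i in range(n):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            c = counts[kmer]
            if fold_strands:
                rc = reverse_complement(kmer)
                if rc != kmer:
                    c += counts[rc]
            if c <= MAX_MAPABILITY_COUNT:
                arr[i] = 1.0 / c
        scores[name] = arr
    return MapabilityTrack(scores=scores, k=k)


def summarize_region_mapability(
    track: MapabilityTrack, regions: Sequence[GenomicRegion]
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-region and cohort mapability summaries.

    A region's scored positions are the k-mer windows lying fully inside it
    (start in ``[region.start, region.end - k]``).  A region is completely
    unique when every scored position has score 1.  The cohort summary
    reports the fraction of completely-unique regions plus the mean and
    median over all per-position scores pooled across regions.

    Returns an empty frame and an empty dict for an empty region list.
    """
    rows = []
    pooled: List[np.ndarray] = []
    for region in regions:
        arr = track.scores.get(region.chrom)
        if arr is None:
            raise KeyError(f"chromosome {region.chrom!r} not in track")
        lo = region.start
        hi = min(region.end - track.k + 1, len(arr))
        window = arr[lo:hi] if hi > lo else np.empty(0)
        pooled.append(window)
        if window.size:
            rows.append(
                {
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "name": region.name,
                    "n_scored": window.size,
                    "mean": float(window.mean()),
                    "median": float(np.median(window)),
                    "completely_unique": bool(np.all(window == 1.0)),
                }
            )
        else:
            rows.append(
                {
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "name": region.name,
                    "n_scored": 0,
                    "mean": np.nan,
                    "median": np.nan,
                    "completely_unique": True,
                }
            )
    per_region = pd.DataFrame(rows)
    if not regions:
        return per_region, {}
    allpos = np.concatenate([w for w in pooled]) if pooled else np.empty(0)
    cohort = {
        "n_regions": len(regions),
        "fraction_completely_unique": float(per_region["completely_unique"].mean()),
        "mean": float(allpos.mean()) if allpos.size else float("nan"),
        "median": float(np.median(allpos)) if allpos.size else float("nan"),
    }
    return per_region, cohort
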
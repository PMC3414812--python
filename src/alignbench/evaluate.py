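"""Scoring: pairwise concordance classes and truth-based accuracy.

Two complementary measures of aligner performance:

* For real data with no ground truth, reads aligned by at least one of a
  pair of aligners are partitioned into four classes — class 1: same
  location by both; class 2: different locations by both; class 3: aligned
  only by the first; class 4: aligned only by the second.  Percentages use
  the union size as denominator, so the four classes form a partition.

* For simulated data the truth is known: an alignment is true when the
  reported chromosome, leftmost position (within an optional tolerance)
  and strand equal the read's origin; the false-alignment rate is
  false / aligned.  Suppressed and unaligned reads count as not aligned in
  both procedures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .alignio import AlignmentRecord, AlignmentSet


@dataclass
class ConcordanceTable:
    label_a: str
    label_b: str
    class1: int
    class2: int
    class3: int
    class4: int

    @property
    def union_size(self) -> int:
        return self.class1 + self.class2 + self.class3 + self.class4

    def percentages(self) -> Dict[str, float]:
        u = self.union_size
        if u == 0:
            return {f"class{i}": 0.0 for i in range(1, 5)}
        return {
            "class1": 100.0 * self.class1 / u,
            "class2": 100.0 * self.class2 / u,
            "class3": 100.0 * self.class3 / u,
            "class4": 100.0 * self.class4 / u,
        }


@dataclass
class AccuracyReport:
    label: str
    total_reads: int
    aligned: int
    true: int
    false: int

    def __post_init__(self):
        if self.true + self.false != self.aligned:
            raise ValueError("true + false must equal aligned")

    @property
    def aligned_pct(self) -> float:
        return 100.0 * self.aligned / self.total_reads if self.total_reads else 0.0

    @property
    def false_rate(self) -> float:
        """False alignments as a fraction of aligned (reported) reads."""
        return self.false / self.aligned if self.aligned else 0.0

    @property
    def false_pct(self) -> float:
        return 100.0 * self.false_rate

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "total_reads": self.total_reads,
            "aligned": self.aligned,
            "aligned_pct": self.aligned_pct,
            "true": self.true,
            "false": self.false,
            "false_pct": self.false_pct,
        }


def _same_location(
    a: AlignmentRecord,
    b: AlignmentRecord,
    tolerance: int,
    require_strand: bool,
) -> bool:
    if a.chrom != b.chrom:
        return False
    if abs(a.pos - b.pos) > tolerance:
        return False
    if require_strand and a.strand != b.strand:
        return False
    return True


def classify_pair(
    set_a: AlignmentSet,
    set_b: AlignmentSet,
    tolerance: int = 0,
    require_strand: bool = True,
) -> ConcordanceTable:
    """Four-class concordance between two aligners over the same reads.

    The universe is the set of reads aligned by at least one member of the
    pair; suppressed and unaligned records are both "not aligned".  A read
    counted in class 1 has the same chromosome, a leftmost-position
    difference of at most ``tolerance`` bp, and (by default) the same
    strand in both sets.
    """
    ids_a = set(set_a.records)
    ids_b = set(set_b.records)
    if not (ids_a & ids_b):
        raise ValueError(
            "alignment sets share no read IDs; were they produced from the "
            "same read set?"
        )
    c1 = c2 = c3 = c4 = 0
    for read_id in ids_a | ids_b:
        rec_a = set_a.records.get(read_id)
        rec_b = set_b.records.get(read_id)
        a_on = rec_a is not None and rec_a.is_aligned
        b_on = rec_b is not None and rec_b.is_aligned
        if a_on and b_on:
            if _same_location(rec_a, rec_b, tolerance, require_strand):
                c1 += 1
            else:
                c2 += 1
        elif a_on:
            c3 += 1
        elif b_on:
            c4 += 1
    return ConcordanceTable(set_a.label, set_b.label, c1, c2, c3, c4)


def score_accuracy(
    aset: AlignmentSet,
    truth: pd.DataFrame,
    tolerance: int = 0,
) -> AccuracyReport:
    """Truth-based accuracy of one alignment set.

    ``truth`` is indexed by read_id with columns chrom, pos, strand (as
    written by the simulator).  An aligned read is true when it sits at its
    origin: same chromosome, leftmost position within ``tolerance``, same
    strand; otherwise it is false.  Suppressed/unaligned reads are excluded
    from the false-rate denominator; the aligned percentage uses all reads
    in the set as denominator.  An aligned read absent from the truth table
    raises KeyError.
    """
    n_true = n_false = 0
    for read_id, rec in aset.records.items():
        if not rec.is_aligned:
            continue
        if read_id not in truth.index:
            raise KeyError(f"aligned read {read_id!r} missing from truth table")
        row = truth.loc[read_id]
        ok = (
            rec.chrom == row["chrom"]
            and abs(rec.pos - int(row["pos"])) <= tolerance
            and rec.strand == row["strand"]
        )
        if ok:
            n_true += 1
        else:
            n_false += 1
    return AccuracyReport(
        label=f"{aset.label}/{aset.mode}",
        total_reads=aset.n_total,
        aligned=n_true + n_false,
        true=n_true,
        false=n_false,
    )


def concordance_report(
    tables: Sequence[Tuple[str, ConcordanceTable]]
) -> pd.DataFrame:
    """Agreement table: one row per (mode, pair) with union size and class %.

    ``tables`` is a sequence of (mode label, ConcordanceTable).
    """
    if not tables:
        raise ValueError("need at least one concordance table")
    rows = []
    for mode, t in tables:
        pct = t.percentages()
        rows.append(
            {
                "mode": mode,
                "pair": f"{t.label_a} vs. {t.label_b}",
                "union_size": t.union_size,
                "class1_pct": pct["class1"],
                "class2_pct": pct["class2"],
                "class3_pct": pct["class3"],
                "class4_pct": pct["class4"],
            }
        )
    return pd.DataFrame(rows)


def accuracy_report(reports: Sequence[AccuracyReport]) -> pd.DataFrame:
    """Accuracy table: aligned % and false-alignment % per aligner/mode row."""
    return pd.DataFrame([r.as_dict() for r in reports])
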
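"""Independent brute-force references used to check the implementation.

These deliberately avoid the package's search strategy: the alignment
reference is a full numpy sliding-window scan over both strands, and the
k-mer reference is plain substring counting.
"""

from collections import Counter

import numpy as np

from alignbench import ReferenceGenome, reverse_complement


def naive_hits(sequence: str, genome: ReferenceGenome, max_mismatches: int):
    """All (chrom, pos, strand, distance) within budget, by full scan."""
    L = len(sequence)
    hits = []
    for chrom, text in genome.sequences.items():
        if len(text) < L:
            continue
        arr = np.frombuffer(text.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        n_mask = windows == ord("N")
        for strand in "+-":
            query = sequence if strand == "+" else reverse_complement(sequence)
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            mism = ((windows != q) | n_mask).sum(axis=1)
            for pos in np.nonzero(mism <= max_mismatches)[0]:
                hits.append((chrom, int(pos), strand, int(mism[pos])))
    return sorted(hits)


def kmer_occurrences(genome: ReferenceGenome, k: int, fold_strands: bool = False):
    """Genome-wide occurrence count of every k-mer, by substring counting."""
    counts = Counter()
    for text in genome.sequences.values():
        for i in range(len(text) - k + 1):
            counts[text[i : i + k]] += 1

    def count(kmer: str) -> int:
        c = counts[kmer]
        if fold_strands:
            rc = reverse_complement(kmer)
            if rc != kmer:
                c += counts[rc]
        return c

    return count
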
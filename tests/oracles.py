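"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately written in the most literal way possible
(per-base loops, exhaustive enumeration) and shares no code with the
package internals it checks.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

from smrna.ingest import AlignedRead, Locus

SPAN_RANGE = range(14, 31)


def oracle_length_features(locus: Locus, alpha: float = 0.5) -> np.ndarray:
    """Literal per-base evaluation: f_L = (sum_k N_Lk) / Length."""
    n_lk = {L: 0.0 for L in SPAN_RANGE}
    for k in range(locus.start, locus.end):
        for r in locus.reads:
            if r.strand != locus.strand:
                continue
            L = r.end - r.start
            if L in n_lk and r.start <= k < r.end:
                n_lk[L] += r.multiplicity
    length = locus.end - locus.start
    f = [n_lk[L] / length for L in SPAN_RANGE]
    c = alpha / length
    total = sum(f)
    out = []
    for fi in f:
        p = (fi + c) / (total + 17 * c)
        out.append(math.log2(p / (1 - p)))
    return np.array(out)


def oracle_positional_entropy(locus: Locus, which_end: str) -> float:
    ends = Counter()
    for r in locus.reads:
        if r.strand != locus.strand:
            continue
        if locus.strand == "+":
            pos = r.start if which_end == "5p" else r.end - 1
        else:
            pos = r.end - 1 if which_end == "5p" else r.start
        ends[pos] += r.multiplicity
    total = sum(ends.values())
    if total == 0:
        return 0.0
    return -sum((c / total) * math.log2(c / total) for c in ends.values())


def oracle_antisense(locus: Locus, alpha: float = 0.5) -> float:
    n_s = sum(r.multiplicity for r in locus.reads if r.strand == locus.strand)
    n_a = sum(r.multiplicity for r in locus.reads if r.strand != locus.strand)
    q = (n_a + alpha) / (n_s + n_a + 2 * alpha)
    return math.log2(q / (1 - q))


def oracle_nucleotide(locus: Locus, alpha: float = 0.5) -> np.ndarray:
    counts = Counter()
    for r in locus.reads:
        if r.strand != locus.strand:
            continue
        for b in r.seq:
            if b in "ACGT":
                counts[b] += r.multiplicity
    total = sum(counts.values())
    return np.array(
        [math.log2(((counts[b] + alpha) / (total + 4 * alpha)) / 0.25) for b in "ACGT"]
    )


_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def enumerate_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Exhaustive backtracking over all non-crossing pairings."""
    s = seq.upper().replace("U", "T")
    n = len(s)

    def crosses(i, k, chosen):
        return any(a < i < b < k or i < a < k < b for a, b in chosen)

    def rec(pos: int, chosen: tuple) -> int:
        free = [q for q in range(pos, n) if all(q != a and q != b for a, b in chosen)]
        if not free:
            return len(chosen)
        i = free[0]
        best = rec(i + 1, chosen)  # i unpaired
        for k in free[1:]:
            if k - i > min_loop and (s[i], s[k]) in _PAIRS and not crosses(i, k, chosen):
                best = max(best, rec(i + 1, chosen + ((i, k),)))
        return best

    return rec(0, ())


def coverage_array_segments(
    reads: list[AlignedRead], min_coverage: int, max_gap: int, max_coord: int = 2000
) -> dict[str, list[tuple[int, int]]]:
    """Per-base coverage-array thresholding + gap merge, per chromosome."""
    out: dict[str, list[tuple[int, int]]] = {}
    chroms = sorted({r.chrom for r in reads})
    for chrom in chroms:
        cov = np.zeros(max_coord, dtype=int)
        for r in reads:
            if r.chrom == chrom:
                cov[r.start : r.end] += r.multiplicity
        above = cov >= min_coverage
        intervals = []
        start = None
        for i in range(max_coord + 1):
            on = above[i] if i < max_coord else False
            if on and start is None:
                start = i
            elif not on and start is not None:
                intervals.append((start, i))
                start = None
        merged: list[list[int]] = []
        for a, b in intervals:
            if merged and a - merged[-1][1] <= max_gap:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        out[chrom] = [tuple(iv) for iv in merged]
    return out


def random_locus(
    rng: np.random.Generator,
    with_seq: bool = False,
    max_reads: int = 30,
) -> Locus:
    """A random small locus with a mix of spans, strands and multiplicities."""
    start = int(rng.integers(0, 200))
    length = int(rng.integers(40, 160))
    end = start + length
    strand = "+" if rng.random() < 0.5 else "-"
    n_reads = int(rng.integers(1, max_reads + 1))
    reads = []
    for _ in range(n_reads):
        span = int(rng.integers(10, 36))  # includes spans outside 14..30
        r_start = int(rng.integers(max(0, start - 8), max(1, end - 2)))
        r_strand = strand if rng.random() > 0.25 else ("-" if strand == "+" else "+")
        seq = "".join(rng.choice(list("ACGTN"), size=span, p=[0.24] * 4 + [0.04])) if with_seq else None
        reads.append(
            AlignedRead(
                chrom="c", start=r_start, end=r_start + span, strand=r_strand,
                seq=seq, multiplicity=int(rng.integers(1, 5)),
            )
        )
    return Locus(id=f"c:{start}-{end}", chrom="c", start=start, end=end, strand=strand, reads=reads)


def random_reads(rng: np.random.Generator, n: int, max_coord: int = 450) -> list[AlignedRead]:
    reads = []
    for _ in range(n):
        start = int(rng.integers(0, max_coord))
        span = int(rng.integers(14, 31))
        reads.append(
            AlignedRead(
                chrom=f"chr{int(rng.integers(1, 3))}",
                start=start,
                end=start + span,
                strand="+" if rng.random() < 0.5 else "-",
                multiplicity=int(rng.integers(1, 4)),
            )
        )
    return reads
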
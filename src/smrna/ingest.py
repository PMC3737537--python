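"""Read, filter and segment aligned small-RNA reads into transcribed loci.

Small RNA-seq reads (BAM or BED6) are loaded into a lightweight collapsed
representation, optionally filtered to uniquely-mapping reads, and merged
into transcribed loci by thresholding the multiplicity-weighted,
strand-pooled coverage profile. All coordinates are 0-based half-open
(BED-native); BAM records are converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignedRead:
    """One mapped small-RNA read (possibly collapsing identical copies).

    ``seq`` is the read sequence in its own 5'->3' orientation (i.e. the
    reverse complement of the reference slice for minus-strand reads); it
    may be ``None`` for BED input until hydrated from a genome.
    ``multiplicity`` counts identical reads collapsed into this record.
    """

    chrom: str
    start: int
    end: int
    strand: str
    seq: str | None = None
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer")
        if self.seq is not None and len(self.seq) != self.end - self.start:
            raise ValueError("sequence length does not match coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def end5(self) -> int:
        """Genomic coordinate of the 5' terminal base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def end3(self) -> int:
        """Genomic coordinate of the 3' terminal base."""
        return self.end - 1 if self.strand == "+" else self.start


class GenomeSequence:
    """Genome as a mapping from chromosome name to nucleotide string.

    Backed either by an in-memory dict (synthetic genomes) or by a
    pyfaidx-indexed FASTA file. Coordinates are 0-based half-open.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}
        self.lengths = {name: len(seq) for name, seq in self._seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the forward-strand slice [start, end), clipped to the chromosome."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = self.lengths[chrom]
        return self._seqs[chrom][max(0, start) : min(n, end)]

    def fetch_stranded(self, chrom: str, start: int, end: int, strand: str) -> str:
        s = self.fetch(chrom, start, end)
        return reverse_complement(s) if strand == "-" else s


@dataclass
class Locus:
    """A contiguous transcribed region with its assigned reads.

    ``strand`` is the strand carrying the majority of assigned read
    multiplicity (ties resolved to '+'); sense/antisense counts are
    relative to it and multiplicity-weighted.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    reads: list[AlignedRead] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_sense(self) -> int:
        return sum(r.multiplicity for r in self.reads if r.strand == self.strand)

    @property
    def n_antisense(self) -> int:
        return sum(r.multiplicity for r in self.reads if r.strand != self.strand)

    @property
    def total_reads(self) -> int:
        return sum(r.multiplicity for r in self.reads)

    def sense_reads(self) -> list[AlignedRead]:
        return [r for r in self.reads if r.strand == self.strand]

    def antisense_reads(self) -> list[AlignedRead]:
        return [r for r in self.reads if r.strand != self.strand]


def _collapse(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Merge identical (chrom, start, end, strand, seq) records, summing multiplicity."""
    counts: dict[tuple, int] = {}
    for r in reads:
        key = (r.chrom, r.start, r.end, r.strand, r.seq)
        counts[key] = counts.get(key, 0) + r.multiplicity
    out = [
        AlignedRead(chrom=c, start=s, end=e, strand=st, seq=sq, multiplicity=m)
        for (c, s, e, st, sq), m in counts.items()
    ]
    out.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    return out


def _read_bed6(path: str | Path, genome: GenomeSequence | None) -> list[AlignedRead]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns, got {len(fields)}")
            chrom, start, end, _name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            seq = None
            if genome is not None:
                if chrom not in genome:
                    raise KeyError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                seq = genome.fetch_stranded(chrom, start_i, end_i, strand)
            reads.append(AlignedRead(chrom=chrom, start=start_i, end=end_i, strand=strand, seq=seq))
    return reads


def _read_bam(path: str | Path, unique_only: bool) -> list[AlignedRead]:
    import pysam

    reads = []
    saw_nh = False
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            saw_nh = saw_nh or nh is not None
            if unique_only and nh is not None and nh > 1:
                continue
            seq = rec.query_sequence
            if seq is not None and rec.is_reverse:
                seq = reverse_complement(seq)
            reads.append(
                AlignedRead(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    seq=seq.upper() if seq else None,
                )
            )
    if unique_only and reads and not saw_nh:
        log.warning("no NH tags present in %s; treating all reads as uniquely mapped", path)
    return reads


def read_alignments(
    path: str | Path,
    genome: GenomeSequence | None = None,
    unique_only: bool = False,
) -> list[AlignedRead]:
    """Load aligned reads from a BAM/SAM or BED6 file.

    Coordinates are normalised to 0-based half-open. When ``unique_only``
    is set, BAM records whose NH tag reports more than one placement are
    discarded; BED input carries no hit count and is treated as unique
    (with a warning). BED reads are hydrated with sequence from ``genome``
    when it is provided. Identical reads are collapsed with multiplicity.
    """
    path = Path(path)
    if path.suffix.lower() in {".bam", ".sam"}:
        reads = _read_bam(path, unique_only)
    else:
        if unique_only:
            log.warning("BED input has no multi-mapping annotation; treating all reads as unique")
        reads = _read_bed6(path, genome)
    return _collapse(reads)


def hydrate_sequences(reads: list[AlignedRead], genome: GenomeSequence) -> list[AlignedRead]:
    """Fill in missing read sequences from the genome (strand-aware)."""
    out = []
    for r in reads:
        if r.seq is None:
            if r.chrom not in genome:
                raise KeyError(f"unknown chromosome {r.chrom!r}")
            out.append(replace(r, seq=genome.fetch_stranded(r.chrom, r.start, r.end, r.strand)))
        else:
            out.append(r)
    return out


def segment_loci(
    reads: list[AlignedRead],
    min_coverage: int = 1,
    max_gap: int = 0,
) -> list[Locus]:
    """Merge reads into transcribed loci by coverage thresholding.

    Per chromosome, both strands pooled, finds maximal intervals where the
    multiplicity-weighted coverage is >= ``min_coverage``, then merges
    intervals separated by <= ``max_gap`` bases. Each locus receives every
    read overlapping it; locus strand is the majority read strand (tie ->
    '+'); ids are ``chrom:start-end``.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    by_chrom: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)

    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        chrom_reads = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        # sweep over coverage change-points
        events: dict[int, int] = {}
        for r in chrom_reads:
            events[r.start] = events.get(r.start, 0) + r.multiplicity
            events[r.end] = events.get(r.end, 0) - r.multiplicity
        cov = 0
        open_start = None
        raw: list[list[int]] = []
        for pos in sorted(events):
            prev = cov
            cov += events[pos]
            if prev < min_coverage <= cov:
                open_start = pos
            elif prev >= min_coverage > cov:
                raw.append([open_start, pos])
                open_start = None
        merged: list[list[int]] = []
        for iv in raw:
            if merged and iv[0] - merged[-1][1] <= max_gap:
                merged[-1][1] = iv[1]
            else:
                merged.append(iv)
        for start, end in merged:
            assigned = [r for r in chrom_reads if r.start < end and r.end > start]
            plus = sum(r.multiplicity for r in assigned if r.strand == "+")
            minus = sum(r.multiplicity for r in assigned if r.strand == "-")
            strand = "+" if plus >= minus else "-"
            loci.append(
                Locus(
                    id=f"{chrom}:{start}-{end}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    reads=assigned,
                )
            )
    return loci


def filter_loci(loci: list[Locus], min_reads: int = 15) -> list[Locus]:
    """Discard loci covered by fewer than ``min_reads`` reads (multiplicity-weighted)."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [loc for loc in loci if loc.total_reads >= min_reads]


def write_loci_bed(loci: list[Locus], path: str | Path) -> None:
    """Write loci as BED6 with the multiplicity-weighted read count in the score column."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.id}\t{loc.total_reads}\t{loc.strand}\n"
            )


def write_reads_bed(reads: list[AlignedRead], path: str | Path) -> None:
    """Write reads as BED6; one line per collapsed copy is expanded by multiplicity."""
    with open(path, "w") as fh:
        i = 0
        for r in reads:
            for _ in range(r.multiplicity):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread_{i}\t0\t{r.strand}\n")
                i += 1
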
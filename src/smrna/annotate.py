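"""Assign ncRNA class labels to loci by interval overlap with annotations."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .ingest import Locus

log = logging.getLogger(__name__)

#: The six functional classes the classifier distinguishes, in tie-break
#: priority order (most specific annotations first), plus homology-trivial
#: classes accepted for the three-class comparison mode.
CLASS_PRIORITY = [
    "miRNA",
    "CD_box_snoRNA",
    "snRNA",
    "scRNA",
    "transposon",
    "lincRNA",
    "tRNA",
    "rRNA",
    "other",
]

SIX_CLASSES = frozenset(CLASS_PRIORITY[:6])

_PRIORITY_RANK = {c: i for i, c in enumerate(CLASS_PRIORITY)}


@dataclass(frozen=True)
class AnnotationRecord:
    chrom: str
    start: int
    end: int
    strand: str
    rna_class: str
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.rna_class not in _PRIORITY_RANK:
            raise ValueError(f"unknown RNA class {self.rna_class!r}")


@dataclass
class LabeledLocus:
    locus: Locus
    label: str
    overlap_bp: int


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_annotations(
    path: str | Path,
    class_map: Mapping[str, str] | None = None,
    gtf_attribute: str = "gene_biotype",
) -> list[AnnotationRecord]:
    """Read BED or GTF annotations, resolving RNA classes through ``class_map``.

    For BED, the class token is the name column (the part after the last
    ``|`` when present). For GTF, the token comes from ``gtf_attribute``
    (falling back to ``gene_type``). Records whose token resolves to no
    known class are dropped, with a logged count.
    """
    path = Path(path)
    class_map = dict(class_map or {})
    records: list[AnnotationRecord] = []
    dropped = 0

    def resolve(token: str) -> str | None:
        cls = class_map.get(token, token if token in _PRIORITY_RANK else None)
        return cls if cls in _PRIORITY_RANK else None

    is_gtf = path.suffix.lower() in {".gtf", ".gff"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if is_gtf:
                    if len(fields) < 9:
                        raise ValueError("GTF requires 9 columns")
                    chrom, _src, _feat, start, end, _score, strand, _frame, attrs = fields[:9]
                    attrd = _parse_gtf_attributes(attrs)
                    token = attrd.get(gtf_attribute) or attrd.get("gene_type", "")
                    name = attrd.get("gene_id", f"{chrom}:{start}-{end}")
                    start_i, end_i = int(start) - 1, int(end)  # GTF is 1-based inclusive
                else:
                    if len(fields) < 6:
                        raise ValueError("BED annotation requires 6 columns")
                    chrom, start, end, name, _score, strand = fields[:6]
                    token = name.rsplit("|", 1)[-1]
                    start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            cls = resolve(token)
            if cls is None:
                dropped += 1
                continue
            records.append(
                AnnotationRecord(
                    chrom=chrom, start=start_i, end=end_i, strand=strand, rna_class=cls, name=name
                )
            )
    if dropped:
        log.info("dropped %d annotation records with unmapped classes", dropped)
    return records


def label_loci(
    loci: list[Locus],
    annotations: list[AnnotationRecord],
    strand_aware: bool = True,
    classes: frozenset[str] | set[str] = SIX_CLASSES,
) -> list[LabeledLocus]:
    """Label each locus with the class of the annotation it overlaps most.

    Only annotations whose class is in ``classes`` compete; ties on
    overlap are broken by class priority (miRNA > C/D box snoRNA > snRNA >
    scRNA > transposon > lincRNA), then annotation name. Loci overlapping
    nothing in the active class set are labelled ``"unknown"`` and form
    the prediction-only pool. With ``strand_aware``, only same-strand
    annotations are considered.
    """
    classes = frozenset(classes)
    by_chrom: dict[str, list[AnnotationRecord]] = {}
    for ann in annotations:
        if ann.rna_class in classes:
            by_chrom.setdefault(ann.chrom, []).append(ann)
    for anns in by_chrom.values():
        anns.sort(key=lambda a: (a.start, a.end, a.name))

    out = []
    for loc in loci:
        best: tuple[int, int, str, str] | None = None  # (-overlap, rank, name, class)
        for ann in by_chrom.get(loc.chrom, []):
            if strand_aware and ann.strand != loc.strand:
                continue
            overlap = min(loc.end, ann.end) - max(loc.start, ann.start)
            if overlap <= 0:
                continue
            key = (-overlap, _PRIORITY_RANK[ann.rna_class], ann.name, ann.rna_class)
            if best is None or key < best:
                best = key
        if best is None:
            out.append(LabeledLocus(locus=loc, label="unknown", overlap_bp=0))
        else:
            out.append(LabeledLocus(locus=loc, label=best[3], overlap_bp=-best[0]))
    return out


def write_labeled_loci(labeled: list[LabeledLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tchrom\tstart\tend\tstrand\tlabel\toverlap_bp\tn_reads\n")
        for ll in labeled:
            loc = ll.locus
            fh.write(
                f"{loc.id}\t{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.strand}\t"
                f"{ll.label}\t{ll.overlap_bp}\t{loc.total_reads}\n"
            )
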
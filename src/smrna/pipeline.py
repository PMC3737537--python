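"""End-to-end convenience: reads -> loci -> labels -> feature matrix."""

from __future__ import annotations

from .annotate import SIX_CLASSES, AnnotationRecord, label_loci
from .features import FeatureMatrix, build_feature_matrix
from .ingest import AlignedRead, GenomeSequence, filter_loci, segment_loci
from .simulate import SyntheticDataset


def features_from_reads(
    reads: list[AlignedRead],
    genome: GenomeSequence,
    annotations: list[AnnotationRecord],
    min_coverage: int = 1,
    max_gap: int = 0,
    min_reads: int = 15,
    strand_aware: bool = True,
    classes=SIX_CLASSES,
    alpha: float = 0.5,
    mfe_backend: str | None = None,
    mfe_table: dict[str, float] | None = None,
    flank: int = 40,
) -> FeatureMatrix:
    """Segment, filter, label and featurise a read set in one call."""
    loci = filter_loci(segment_loci(reads, min_coverage, max_gap), min_reads)
    labelled = label_loci(loci, annotations, strand_aware=strand_aware, classes=classes)
    return build_feature_matrix(
        labelled, genome, alpha=alpha, mfe_backend=mfe_backend,
        mfe_table=mfe_table, flank=flank,
    )


def features_from_dataset(
    dataset: SyntheticDataset,
    min_reads: int = 15,
    mfe_backend: str = "table",
    **kwargs,
) -> FeatureMatrix:
    """Run the pipeline on a synthetic dataset.

    By default the per-locus folding scores shipped with the dataset are
    used (``table`` backend); pass ``mfe_backend='nussinov'`` or
    ``'vienna'`` to fold the synthetic genome instead.
    """
    loci = filter_loci(
        segment_loci(
            dataset.reads,
            kwargs.pop("min_coverage", 1),
            kwargs.pop("max_gap", 0),
        ),
        min_reads,
    )
    labelled = label_loci(
        loci, dataset.annotations,
        strand_aware=kwargs.pop("strand_aware", True),
        classes=kwargs.pop("classes", SIX_CLASSES),
    )
    mfe_table = dataset.mfe_for_loci(loci) if mfe_backend == "table" else None
    return build_feature_matrix(
        labelled, dataset.genome, mfe_backend=mfe_backend, mfe_table=mfe_table, **kwargs
    )
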
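"""The 25-feature representation of a small-RNA locus.

Each transcribed locus is summarised by interpretable statistics of its
read pileup: 17 log-odds read-length features (spans 14-30 nt), a
log-odds antisense-abundance feature, Shannon entropies of the 5' and 3'
read end-position distributions (cleavage specificity, in bits), four
log-odds base-composition features, and a secondary-structure stability
score of the locus plus 40 bp of flanking genome.

Length, entropy and nucleotide features are computed from sense-strand
reads only (reads on the locus strand); antisense reads feed only the
antisense feature. All counts are multiplicity-weighted. Log-odds are
base 2 with a Jeffreys-style pseudocount (default 0.5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import fold
from .annotate import LabeledLocus
from .ingest import GenomeSequence, Locus

log = logging.getLogger(__name__)

MIN_SPAN, MAX_SPAN = 14, 30
N_SPANS = MAX_SPAN - MIN_SPAN + 1

LENGTH_FEATURES = [f"L{L}" for L in range(MIN_SPAN, MAX_SPAN + 1)]

#: Fixed feature order of every feature matrix.
FEATURE_NAMES = LENGTH_FEATURES + [
    "antisense",
    "pos_entropy5p",
    "pos_entropy3p",
    "nuc_A",
    "nuc_C",
    "nuc_G",
    "nuc_T",
    "mfe",
]

DEFAULT_ALPHA = 0.5


def _log_odds(p: float) -> float:
    return math.log2(p / (1.0 - p))


def length_features(
    locus: Locus, alpha: float = DEFAULT_ALPHA, count_mode: str = "coverage"
) -> np.ndarray:
    """Log-odds read-length spectrum of a locus.

    For span L in 14..30 the raw feature is f_L = (sum_k N_Lk) / Length(i)
    where N_Lk counts (multiplicity-weighted) sense reads of reference
    span L covering base k of the locus (``count_mode='coverage'``), or
    whose 5' end lies at base k (``'start'``). The 17 raw values are
    converted to proportions with a pseudocount scaled to the per-base
    feature units (alpha / Length) and returned as log2(p / (1 - p)).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if count_mode not in {"coverage", "start"}:
        raise ValueError(f"unknown count_mode {count_mode!r}")
    length = locus.length
    f = np.zeros(N_SPANS)
    n_sense = 0
    for r in locus.sense_reads():
        n_sense += r.multiplicity
        span = r.length
        if not (MIN_SPAN <= span <= MAX_SPAN):
            continue
        if count_mode == "coverage":
            covered = min(r.end, locus.end) - max(r.start, locus.start)
            if covered > 0:
                f[span - MIN_SPAN] += r.multiplicity * covered / length
        elif locus.start <= r.end5 < locus.end:
            f[span - MIN_SPAN] += r.multiplicity / length
    if n_sense == 0:
        log.info("locus %s has no sense-strand reads; length features are all-pseudocount", locus.id)
    c = alpha / length
    p = (f + c) / (f.sum() + N_SPANS * c)
    return np.array([_log_odds(pi) for pi in p])


def positional_entropy(locus: Locus, which_end: str) -> float:
    """Shannon entropy (bits) of the 5' or 3' read end-position distribution.

    Uses multiplicity-weighted sense-strand reads; for a minus-strand
    locus the 5' end of a read is its maximum genomic coordinate. End
    positions outside the locus bounds still count (they are real
    cleavage sites). Zero sense reads give 0 bits.
    """
    if which_end not in {"5p", "3p"}:
        raise ValueError("which_end must be '5p' or '3p'")
    counts: dict[int, int] = {}
    for r in locus.sense_reads():
        pos = r.end5 if which_end == "5p" else r.end3
        counts[pos] = counts.get(pos, 0) + r.multiplicity
    total = sum(counts.values())
    if total == 0:
        log.info("locus %s has no sense-strand reads; positional entropy is 0", locus.id)
        return 0.0
    h = 0.0
    for c in counts.values():
        p = c / total
        h -= p * math.log2(p)
    return h


def antisense_feature(locus: Locus, alpha: float = DEFAULT_ALPHA) -> float:
    """Log-odds of the antisense read fraction with pseudocount ``alpha``."""
    n_a, n_s = locus.n_antisense, locus.n_sense
    q = (n_a + alpha) / (n_s + n_a + 2 * alpha)
    return _log_odds(q)


_BASES = "ACGT"


def nucleotide_features(locus: Locus, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Log-odds base composition of sense reads vs equal base frequencies.

    Each read contributes length x multiplicity bases (expression
    weighting); N bases are ignored. Requires read sequences (hydrate BED
    reads from a genome first).
    """
    counts = dict.fromkeys(_BASES, 0)
    for r in locus.sense_reads():
        if r.seq is None:
            raise ValueError(
                f"locus {locus.id}: read sequences unavailable; supply a genome FASTA "
                "to hydrate BED reads before computing nucleotide features"
            )
        for b in r.seq.upper():
            if b in counts:
                counts[b] += r.multiplicity
    total = sum(counts.values())
    out = np.empty(4)
    for i, b in enumerate(_BASES):
        f_b = (counts[b] + alpha) / (total + 4 * alpha)
        out[i] = math.log2(f_b / 0.25)
    return out


def mfe_feature(
    locus: Locus,
    genome: GenomeSequence | None = None,
    flank: int = 40,
    backend: str = "vienna",
    table: dict[str, float] | None = None,
) -> float:
    """Secondary-structure stability of the locus plus flanking sequence.

    The sense-strand genomic slice [start - flank, end + flank), clipped
    at chromosome ends, is folded with the chosen backend; ``table``
    looks the value up from a per-locus mapping instead (e.g. scores
    computed elsewhere).
    """
    if backend == "table":
        if table is None or locus.id not in table:
            raise KeyError(f"locus {locus.id} missing from MFE table")
        return float(table[locus.id])
    if genome is None:
        raise ValueError("mfe_feature requires a genome for folding backends")
    seq = genome.fetch_stranded(locus.chrom, locus.start - flank, locus.end + flank, locus.strand)
    if backend == "vienna":
        return fold.vienna_mfe(seq)
    if backend == "nussinov":
        return fold.nussinov_energy(seq)
    raise ValueError(f"unknown MFE backend {backend!r}")


@dataclass(frozen=True)
class FeatureVector:
    """One locus's fixed-order 25-feature representation."""

    locus_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features")


def compute_features(
    locus: Locus,
    genome: GenomeSequence | None = None,
    alpha: float = DEFAULT_ALPHA,
    mfe_backend: str = "vienna",
    mfe_table: dict[str, float] | None = None,
    flank: int = 40,
    length_count_mode: str = "coverage",
) -> FeatureVector:
    values = np.concatenate(
        [
            length_features(locus, alpha, length_count_mode),
            [antisense_feature(locus, alpha)],
            [positional_entropy(locus, "5p"), positional_entropy(locus, "3p")],
            nucleotide_features(locus, alpha),
            [mfe_feature(locus, genome, flank, mfe_backend, mfe_table)],
        ]
    )
    return FeatureVector(locus_id=locus.id, values=values)


@dataclass
class FeatureMatrix:
    """Loci x features table with an optional parallel label vector."""

    data: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.data.columns) != FEATURE_NAMES:
            raise ValueError("feature columns must match the fixed 25-feature order")
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.labels is not None and not self.labels.index.equals(self.data.index):
            raise ValueError("labels index must match feature rows")

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("feature matrix has no labels")
        return self.labels.to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def subset_labelled(self, classes=None) -> "FeatureMatrix":
        """Rows with a known label (optionally restricted to ``classes``)."""
        if self.labels is None:
            raise ValueError("feature matrix has no labels")
        mask = self.labels != "unknown"
        if classes is not None:
            mask &= self.labels.isin(set(classes))
        return FeatureMatrix(self.data.loc[mask], self.labels.loc[mask])

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "label", self.labels if self.labels is not None else "unknown")
        out.to_csv(path, sep="\t", index_label="locus_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="locus_id", float_precision="round_trip")
        labels = df.pop("label").astype(str) if "label" in df.columns else None
        return cls(df[FEATURE_NAMES], labels)


def build_feature_matrix(
    loci: list[LabeledLocus] | list[Locus],
    genome: GenomeSequence | None = None,
    alpha: float = DEFAULT_ALPHA,
    mfe_backend: str | None = None,
    mfe_table: dict[str, float] | None = None,
    flank: int = 40,
    length_count_mode: str = "coverage",
) -> FeatureMatrix:
    """Assemble the full feature matrix for a list of (labelled) loci.

    ``mfe_backend`` defaults to ``vienna`` when the bindings are
    installed, otherwise ``nussinov`` (logged loudly); a single backend
    is used for every row so model features stay homogeneous.
    """
    if mfe_backend is None:
        if mfe_table is not None:
            mfe_backend = "table"
        elif fold.vienna_available():
            mfe_backend = "vienna"
        else:
            mfe_backend = "nussinov"
            log.warning("ViennaRNA unavailable; falling back to the nussinov base-pair proxy")
    rows, ids, labels = [], [], []
    for item in loci:
        locus = item.locus if isinstance(item, LabeledLocus) else item
        label = item.label if isinstance(item, LabeledLocus) else "unknown"
        fv = compute_features(
            locus, genome, alpha, mfe_backend, mfe_table, flank, length_count_mode
        )
        rows.append(fv.values)
        ids.append(locus.id)
        labels.append(label)
    data = pd.DataFrame(np.array(rows).reshape(-1, len(FEATURE_NAMES)),
                        index=pd.Index(ids, name="locus_id"), columns=FEATURE_NAMES)
    return FeatureMatrix(data, pd.Series(labels, index=data.index, name="label"))


def read_mfe_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (locus_id, mfe) TSV, with or without a header."""
    df = pd.read_csv(path, sep="\t")
    if "locus_id" not in df.columns:
        df = pd.read_csv(path, sep="\t", header=None, names=["locus_id", "mfe"])
    return dict(zip(df["locus_id"].astype(str), df["mfe"].astype(float)))
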
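"""Synthetic genomes, annotations and class-specific small-RNA pileups.

The generator emulates the statistical structure the classifier relies
on: each ncRNA class is a :class:`ClassProfile` specifying a read-span
multinomial over 14-30 nt, 5'/3' cleavage-position concentrations
(larger concentration -> tighter cleavage -> lower positional entropy),
an antisense read fraction, base-composition weights, and a normal
folding-score distribution used with the ``table`` MFE backend. Loci are
placed non-overlapping (>= 100 bp apart) on one synthetic chromosome, so
the full ingest -> annotate -> features -> model pipeline can run with
no external data. All output is byte-deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AnnotationRecord
from .ingest import AlignedRead, GenomeSequence, Locus, write_reads_bed

SPANS = np.arange(14, 31)
_BASES = np.array(list("ACGT"))


@dataclass
class ClassProfile:
    """Generative description of one ncRNA class's read pileup."""

    name: str
    length_weights: list[float]  # 17 weights over spans 14..30
    end5_concentration: float
    end3_concentration: float
    antisense_fraction: float
    base_weights: list[float]  # A, C, G, T
    mfe_mean: float
    mfe_sd: float
    locus_length_range: tuple[int, int] = (70, 130)
    reads_per_locus_range: tuple[int, int] = (40, 120)

    def __post_init__(self) -> None:
        if len(self.length_weights) != len(SPANS):
            raise ValueError("length_weights must have 17 entries (spans 14-30)")
        if min(self.length_weights) < 0 or sum(self.length_weights) <= 0:
            raise ValueError("length_weights must be non-negative and normalizable")
        if self.end5_concentration <= 0 or self.end3_concentration <= 0:
            raise ValueError("concentrations must be positive")
        if not 0 <= self.antisense_fraction <= 1:
            raise ValueError("antisense_fraction must lie in [0, 1]")
        lo, hi = self.reads_per_locus_range
        if lo < 15 or hi < lo:
            raise ValueError("reads_per_locus_range minimum must be >= 15")
        lo, hi = self.locus_length_range
        if lo < 40 or hi < lo:
            raise ValueError("locus_length_range must be non-empty with minimum >= 40")

    @property
    def length_probs(self) -> np.ndarray:
        w = np.asarray(self.length_weights, float)
        return w / w.sum()

    @property
    def base_probs(self) -> np.ndarray:
        w = np.asarray(self.base_weights, float)
        return w / w.sum()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["locus_length_range"] = list(self.locus_length_range)
        d["reads_per_locus_range"] = list(self.reads_per_locus_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClassProfile":
        d = dict(d)
        d["locus_length_range"] = tuple(d["locus_length_range"])
        d["reads_per_locus_range"] = tuple(d["reads_per_locus_range"])
        return cls(**d)


def _weights(peaks: dict[int, float], floor: float = 0.01) -> list[float]:
    w = [peaks.get(int(s), floor) for s in SPANS]
    return w


def default_profiles() -> dict[str, ClassProfile]:
    """The six stock class profiles.

    Shapes follow the qualitative class signatures seen in real tissue
    pileups: miRNA with a strong 22-nt span peak, precise 5' cleavage and
    sloppier 3' ends; C/D box snoRNA fragments short-or-long with high
    positional entropy at both ends; transposon-derived RNAs short
    (<19 nt), tightly cleaved, weakly folding (high MFE) and with
    substantial antisense transcription; lincRNA fragments 14-17 nt with
    moderate dispersion; scRNA with a 27-nt peak and weak folding; snRNA
    dominated by 14-nt products.
    """
    return {
        "miRNA": ClassProfile(
            name="miRNA",
            length_weights=_weights({20: 0.05, 21: 0.12, 22: 0.55, 23: 0.12, 24: 0.04}),
            end5_concentration=50.0,
            end3_concentration=10.0,
            antisense_fraction=0.02,
            base_weights=[0.22, 0.20, 0.22, 0.36],
            mfe_mean=-42.0,
            mfe_sd=4.0,
            locus_length_range=(70, 100),
        ),
        "CD_box_snoRNA": ClassProfile(
            name="CD_box_snoRNA",
            length_weights=_weights(
                {14: 0.08, 15: 0.08, 26: 0.12, 27: 0.14, 28: 0.14, 29: 0.12, 30: 0.12}
            ),
            end5_concentration=6.0,
            end3_concentration=6.0,
            antisense_fraction=0.05,
            base_weights=[0.28, 0.22, 0.28, 0.22],
            mfe_mean=-30.0,
            mfe_sd=4.0,
            locus_length_range=(80, 140),
        ),
        "transposon": ClassProfile(
            name="transposon",
            length_weights=_weights({15: 0.18, 16: 0.22, 17: 0.22, 18: 0.18, 19: 0.06}),
            end5_concentration=70.0,
            end3_concentration=70.0,
            antisense_fraction=0.30,
            base_weights=[0.27, 0.23, 0.23, 0.27],
            mfe_mean=-6.0,
            mfe_sd=2.5,
            locus_length_range=(70, 120),
        ),
        "lincRNA": ClassProfile(
            name="lincRNA",
            length_weights=_weights({14: 0.17, 15: 0.19, 16: 0.19, 17: 0.17, 18: 0.06}),
            end5_concentration=15.0,
            end3_concentration=15.0,
            antisense_fraction=0.15,
            base_weights=[0.30, 0.20, 0.20, 0.30],
            mfe_mean=-14.0,
            mfe_sd=4.0,
            locus_length_range=(80, 150),
        ),
        "scRNA": ClassProfile(
            name="scRNA",
            length_weights=_weights({25: 0.06, 26: 0.15, 27: 0.42, 28: 0.15, 29: 0.07}),
            end5_concentration=20.0,
            end3_concentration=20.0,
            antisense_fraction=0.02,
            base_weights=[0.22, 0.28, 0.28, 0.22],
            mfe_mean=-9.0,
            mfe_sd=3.0,
            locus_length_range=(90, 140),
        ),
        "snRNA": ClassProfile(
            name="snRNA",
            length_weights=_weights({14: 0.48, 15: 0.18, 16: 0.08, 17: 0.04}),
            end5_concentration=18.0,
            end3_concentration=18.0,
            antisense_fraction=0.05,
            base_weights=[0.25, 0.25, 0.25, 0.25],
            mfe_mean=-22.0,
            mfe_sd=4.0,
            locus_length_range=(80, 140),
        ),
    }


def profiles_to_yaml(profiles: dict[str, ClassProfile], path: str | Path) -> None:
    import yaml

    data = {name: p.to_dict() for name, p in profiles.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def profiles_from_yaml(path: str | Path) -> dict[str, ClassProfile]:
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    return {name: ClassProfile.from_dict(d) for name, d in data.items()}


@dataclass
class SyntheticDataset:
    genome: GenomeSequence
    annotations: list[AnnotationRecord]
    reads: list[AlignedRead]
    truth: pd.DataFrame  # locus_id, chrom, start, end, strand, rna_class
    mfe: dict[str, float]  # keyed by planted locus id
    seed: int
    profiles: dict[str, ClassProfile] = field(default_factory=dict)

    def mfe_for_loci(self, loci: list[Locus]) -> dict[str, float]:
        """Map segmented loci to the planted folding score they overlap most."""
        out: dict[str, float] = {}
        rows = list(self.truth.itertuples())
        for loc in loci:
            best, best_ov = None, 0
            for row in rows:
                if row.chrom != loc.chrom:
                    continue
                ov = min(loc.end, row.end) - max(loc.start, row.start)
                if ov > best_ov:
                    best, best_ov = row.locus_id, ov
            if best is not None:
                out[loc.id] = self.mfe[best]
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for chrom, length in self.genome.lengths.items():
                fh.write(f">{chrom}\n")
                seq = self.genome.fetch(chrom, 0, length)
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        write_reads_bed(self.reads, outdir / "reads.bed")
        with open(outdir / "annotations.bed", "w") as fh:
            for ann in self.annotations:
                fh.write(
                    f"{ann.chrom}\t{ann.start}\t{ann.end}\t{ann.name}\t0\t{ann.strand}\n"
                )
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "mfe.tsv", "w") as fh:
            fh.write("locus_id\tmfe\n")
            for lid in self.truth["locus_id"]:
                fh.write(f"{lid}\t{self.mfe[lid]!r}\n")


def _draw_reads(
    rng: np.random.Generator,
    profile: ClassProfile,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    n_reads: int,
) -> list[AlignedRead]:
    """Draw one locus's pileup.

    Read spans follow the profile multinomial exactly. The 5' end jitter
    is Gaussian with sd = locus_length / end5_concentration; the 3' end
    is 5' + span, with the implied 3' dispersion reconciled toward
    locus_length / end3_concentration by rank-coupling the 5' jitter with
    the span (preserving both marginals).
    """
    length = end - start
    probs = profile.length_probs
    n_anti = int(rng.binomial(n_reads, profile.antisense_fraction))
    n_sense = n_reads - n_anti
    mean_span = float(SPANS @ probs)
    sd_span = math.sqrt(float(((SPANS - mean_span) ** 2) @ probs))
    sigma5 = length / profile.end5_concentration
    sigma3 = length / profile.end3_concentration
    if sd_span > 1e-9 and sigma5 > 1e-9:
        cov_target = (sigma3**2 - sigma5**2 - sd_span**2) / 2.0
        w = max(-1.0, min(1.0, cov_target / (sigma5 * sd_span)))
    else:
        w = 0.0

    reads = []
    for i in range(n_reads):
        read_strand = strand if i < n_sense else ("-" if strand == "+" else "+")
        span = int(rng.choice(SPANS, p=probs))
        z_span = (span - mean_span) / sd_span if sd_span > 1e-9 else 0.0
        u = w * z_span + math.sqrt(max(0.0, 1.0 - w * w)) * rng.standard_normal()
        j5 = int(round(sigma5 * u))
        anchor = (length - int(round(mean_span))) // 2
        if read_strand == "+":
            pos5 = start + anchor + j5
            r_start, r_end = pos5, pos5 + span
        else:
            pos5 = end - 1 - anchor - j5
            r_start, r_end = pos5 - span + 1, pos5 + 1
        # keep the read inside the locus neighbourhood without changing its span
        if r_start < start - 10:
            r_start, r_end = start - 10, start - 10 + span
        if r_end > end + 10:
            r_start, r_end = end + 10 - span, end + 10
        reads.append(
            AlignedRead(chrom=chrom, start=r_start, end=r_end, strand=read_strand)
        )
    return reads


def generate_dataset(
    profiles: dict[str, ClassProfile] | None = None,
    n_loci_per_class: int = 100,
    seed: int = 0,
    chrom: str = "synth1",
    spacing: tuple[int, int] = (100, 300),
) -> SyntheticDataset:
    """Generate a full synthetic dataset (genome, annotations, reads, truth, MFE)."""
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(seed)
    if n_loci_per_class < 0:
        raise ValueError("n_loci_per_class must be >= 0")

    placements = []  # (class, start, end, strand)
    pos = 200
    for name in sorted(profiles):
        prof = profiles[name]
        for _ in range(n_loci_per_class):
            pos += int(rng.integers(spacing[0], spacing[1] + 1))
            lo, hi = prof.locus_length_range
            length = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            placements.append((name, pos, pos + length, strand))
            pos += length
    genome_len = pos + 200

    order = rng.permutation(len(placements))  # interleave classes along the chromosome? no:
    # placements are already sequential per class; keep genomic order for determinism
    del order
    base_seq = rng.choice(_BASES, size=genome_len, p=[0.25] * 4)
    annotations, all_reads, truth_rows = [], [], []
    mfe: dict[str, float] = {}
    for idx, (name, start, end, strand) in enumerate(placements):
        prof = profiles[name]
        lid = f"{name}_{idx:05d}"
        lo, hi = prof.reads_per_locus_range
        n_reads = int(rng.integers(lo, hi + 1))
        all_reads.extend(_draw_reads(rng, prof, chrom, start, end, strand, n_reads))
        g_start, g_end = max(0, start - 60), min(genome_len, end + 60)
        base_seq[g_start:g_end] = rng.choice(
            _BASES, size=g_end - g_start, p=prof.base_probs
        )
        annotations.append(
            AnnotationRecord(
                chrom=chrom, start=start, end=end, strand=strand,
                rna_class=name, name=f"{lid}|{name}",
            )
        )
        truth_rows.append((lid, chrom, start, end, strand, name))
        mfe[lid] = float(rng.normal(prof.mfe_mean, prof.mfe_sd))

    genome = GenomeSequence({chrom: "".join(base_seq)})
    from .ingest import hydrate_sequences

    all_reads = hydrate_sequences(all_reads, genome)
    truth = pd.DataFrame(
        truth_rows, columns=["locus_id", "chrom", "start", "end", "strand", "rna_class"]
    )
    return SyntheticDataset(
        genome=genome, annotations=annotations, reads=all_reads, truth=truth,
        mfe=mfe, seed=int(seed), profiles=dict(profiles),
    )


def interpolate_profiles(
    profiles: dict[str, ClassProfile], scale: float
) -> dict[str, ClassProfile]:
    """Blend every profile toward the pooled mean profile.

    ``scale = 1`` returns the profiles unchanged; ``scale = 0`` makes all
    classes generatively identical (so class labels carry no signal).
    Concentrations blend on the log scale.
    """
    if not 0 <= scale <= 1:
        raise ValueError("scale must lie in [0, 1]")
    names = sorted(profiles)
    mean_lw = np.mean([profiles[n].length_probs for n in names], axis=0)
    mean_bw = np.mean([profiles[n].base_probs for n in names], axis=0)
    mean_anti = float(np.mean([profiles[n].antisense_fraction for n in names]))
    mean_log_c5 = float(np.mean([math.log(profiles[n].end5_concentration) for n in names]))
    mean_log_c3 = float(np.mean([math.log(profiles[n].end3_concentration) for n in names]))
    mean_mfe = float(np.mean([profiles[n].mfe_mean for n in names]))
    mean_sd = float(np.mean([profiles[n].mfe_sd for n in names]))
    out = {}
    for n in names:
        p = profiles[n]
        out[n] = ClassProfile(
            name=p.name,
            length_weights=list(scale * p.length_probs + (1 - scale) * mean_lw),
            end5_concentration=math.exp(
                scale * math.log(p.end5_concentration) + (1 - scale) * mean_log_c5
            ),
            end3_concentration=math.exp(
                scale * math.log(p.end3_concentration) + (1 - scale) * mean_log_c3
            ),
            antisense_fraction=scale * p.antisense_fraction + (1 - scale) * mean_anti,
            base_weights=list(scale * p.base_probs + (1 - scale) * mean_bw),
            mfe_mean=scale * p.mfe_mean + (1 - scale) * mean_mfe,
            mfe_sd=scale * p.mfe_sd + (1 - scale) * mean_sd,
            locus_length_range=p.locus_length_range,
            reads_per_locus_range=p.reads_per_locus_range,
        )
    return out


def sweep_separability(
    scale: float,
    profiles: dict[str, ClassProfile] | None = None,
    n_loci_per_class: int = 100,
    seed: int = 0,
) -> SyntheticDataset:
    """Dataset whose achievable accuracy degrades continuously as scale -> 0."""
    if profiles is None:
        profiles = default_profiles()
    return generate_dataset(
        interpolate_profiles(profiles, scale), n_loci_per_class, seed=seed
    )
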
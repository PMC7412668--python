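"""End-to-end pipeline: annotation → regions → read vectors → features.

The analysis has three stages: (1) identify short fixed-site-count regions
inside annotated elements, per strand; (2) extract the reads fully
overlapping each region as binary state vectors; (3) average read data
into region features and element summaries. Filter attrition (skipped
reads, duplicate removal, regions below the read/methylation thresholds,
elements below the region minimum) is counted at every stage and logged.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import PatternModel, pattern_score
from .features import (
    ElementSummary,
    RegionFeatures,
    aggregate_elements,
    features_to_frame,
    region_features,
    select_hypermethylated,
)
from .genome import ElementAnnotation, GenomeSequence, load_fasta, load_gff
from .reads import AlignedRead, ReadIndex, ReadVector, dedupe_exact, parse_sam, write_vector_table
from .regions import Region, RegionSpec, build_regions, write_region_table
from .simulate import build_element_regions

logger = logging.getLogger("srmeth")

__all__ = [
    "AnalysisConfig",
    "PipelineResult",
    "CompareResult",
    "run_pipeline",
    "analyze",
    "compare_samples",
]

_CONFIG_TYPES = {
    "context": str,
    "n_sites": int,
    "max_span": int,
    "min_meth": float,
    "min_reads": int,
    "min_regions": int,
    "hyper_delta": float,
    "feature_filter": str,
    "seed": int,
}


@dataclass(frozen=True)
class AnalysisConfig:
    """All pipeline thresholds, with the published defaults.

    ``context`` CHH with 5 sites in ≤ 30 bp; regions kept with ≥ 4 reads
    and ≥ 10% mean methylation; elements kept with ≥ 2 surviving regions;
    hypermethylation calls need a > 10% methylation increase.
    """

    context: str = "CHH"
    n_sites: int = 5
    max_span: int = 30
    min_meth: float = 0.10
    min_reads: int = 4
    min_regions: int = 2
    hyper_delta: float = 0.10
    feature_filter: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        RegionSpec(self.n_sites, self.max_span, self.context)  # validates
        for name in ("min_meth", "hyper_delta"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_reads < 1 or self.min_regions < 1:
            raise ValueError("min_reads and min_regions must be >= 1")

    @property
    def region_spec(self) -> RegionSpec:
        return RegionSpec(self.n_sites, self.max_span, self.context)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for key, value in asdict(self).items():
                handle.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        values: dict = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                if key in _CONFIG_TYPES:
                    values[key] = _CONFIG_TYPES[key](val.strip())
        values.update(overrides)
        return cls(**values)


@dataclass
class PipelineResult:
    """All stage outputs of one sample's analysis."""

    genome: dict[str, GenomeSequence]
    elements: list[ElementAnnotation]
    regions: list[Region]
    vectors: dict[str, list[ReadVector]]
    features: list[RegionFeatures]  # all regions with >= 1 read
    element_summaries: list[ElementSummary]
    counts: dict[str, int]
    config: AnalysisConfig

    def passing_features(self) -> list[RegionFeatures]:
        """Regions surviving the read-count and methylation thresholds."""
        return [
            f
            for f in self.features
            if f.n_reads >= self.config.min_reads
            and f.mean_read_meth >= self.config.min_meth
        ]

    def features_by_id(self) -> dict[str, RegionFeatures]:
        return {f.region_id: f for f in self.features}


def _check_chroms(
    genome: Mapping[str, GenomeSequence],
    elements: Sequence[ElementAnnotation],
) -> None:
    missing = sorted({e.chrom for e in elements} - set(genome))
    if missing:
        raise ValueError(
            f"annotation chromosome(s) absent from genome FASTA: {', '.join(missing)}"
        )


def analyze(
    genome: Mapping[str, GenomeSequence],
    elements: Sequence[ElementAnnotation],
    reads: Sequence[AlignedRead],
    config: AnalysisConfig = AnalysisConfig(),
    counts: dict[str, int] | None = None,
) -> PipelineResult:
    """Run stages 1–3 on in-memory inputs (see :func:`run_pipeline` for files)."""
    counts = dict(counts or {})
    _check_chroms(genome, elements)

    n_before = len(reads)
    reads = dedupe_exact(reads)
    counts["duplicates_removed"] = n_before - len(reads)
    counts["reads_used"] = len(reads)

    regions: list[Region] = []
    for chrom in sorted({e.chrom for e in elements}):
        chrom_elements = [e for e in elements if e.chrom == chrom]
        regions.extend(
            build_element_regions(genome[chrom], chrom_elements, config.region_spec)
        )
    counts["regions_built"] = len(regions)

    index = ReadIndex(reads)
    vectors: dict[str, list[ReadVector]] = {}
    features: list[RegionFeatures] = []
    for region in regions:
        vecs = index.extract(region)
        vectors[region.region_id] = vecs
        feats = region_features(
            vecs,
            region_id=region.region_id,
            element_id=region.element_id,
            gc=region.gc,
            min_reads=1,
        )
        if feats is not None:
            features.append(feats)
    counts["regions_with_reads"] = len(features)
    counts["regions_passing_filters"] = sum(
        f.n_reads >= config.min_reads and f.mean_read_meth >= config.min_meth
        for f in features
    )

    summaries = aggregate_elements(
        features,
        min_meth=config.min_meth,
        min_reads=config.min_reads,
        min_regions=config.min_regions,
    )
    counts["elements_kept"] = len(summaries)
    counts["elements_dropped"] = len({r.element_id for r in regions}) - len(summaries)
    for key, value in sorted(counts.items()):
        logger.info("%s: %d", key, value)
    return PipelineResult(
        genome=dict(genome),
        elements=list(elements),
        regions=regions,
        vectors=vectors,
        features=features,
        element_summaries=summaries,
        counts=counts,
        config=config,
    )


def run_pipeline(
    fasta_path: str | Path,
    gff_path: str | Path,
    sam_path: str | Path,
    config: AnalysisConfig = AnalysisConfig(),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """File-based pipeline: FASTA + GFF3 + SAM → feature/summary tables.

    A chromosome present in the GFF or SAM but absent from the FASTA is a
    hard error naming the offender. With ``out_dir`` set, stage outputs are
    written as TSV along with filter counts and sha256 checksums.
    """
    genome = load_fasta(fasta_path)
    elements = load_gff(gff_path, config.feature_filter or None)
    reads, read_counts = parse_sam(sam_path, genome)
    counts = {f"reads_{k}": v for k, v in read_counts.items()}
    result = analyze(genome, elements, reads, config, counts)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_region_table(result.regions, out / "regions.tsv")
        all_vectors = [v for r in result.regions for v in result.vectors[r.region_id]]
        write_vector_table(all_vectors, out / "read_vectors.tsv")
        features_to_frame(result.features).to_csv(
            out / "region_features.tsv", sep="\t", index=False
        )
        _elements_frame(result.element_summaries).to_csv(
            out / "elements.tsv", sep="\t", index=False
        )
        with open(out / "counts.txt", "w") as handle:
            for key, value in sorted(result.counts.items()):
                handle.write(f"{key} = {value}\n")
        _write_checksums(
            out,
            ["regions.tsv", "read_vectors.tsv", "region_features.tsv", "elements.tsv"],
        )
    return result


def _elements_frame(summaries: Iterable[ElementSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element_id": s.element_id,
                "n_regions_used": s.n_regions_used,
                "mean_read_meth": s.mean_read_meth,
                "sd_read_meth": s.sd_read_meth,
                "mean_stochasticity": s.mean_stochasticity,
                "sd_site_meth": s.sd_site_meth,
                "gc": s.gc,
                "pattern_score": s.pattern_score,
            }
            for s in summaries
        ],
        columns=[
            "element_id",
            "n_regions_used",
            "mean_read_meth",
            "sd_read_meth",
            "mean_stochasticity",
            "sd_site_meth",
            "gc",
            "pattern_score",
        ],
    )


def _write_checksums(out: Path, names: Sequence[str]) -> None:
    with open(out / "checksums.txt", "w") as handle:
        for name in names:
            digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
            handle.write(f"{digest}  {name}\n")


@dataclass
class CompareResult:
    """Two-sample comparison on intersection-matched region/element ids."""

    region_deltas: pd.DataFrame
    hypermethylated: set[str]
    element_shift: pd.DataFrame
    counts: dict[str, int]


def compare_samples(
    sample_a: PipelineResult,
    sample_b: PipelineResult,
    model: PatternModel | None = None,
) -> CompareResult:
    """Per-region methylation deltas, hypermethylated set and score shifts.

    Only ids present in both samples are compared; single-sample ids are
    counted and skipped. Element score shifts (sample B − sample A pattern
    score) need a fitted model and use elements methylated in both samples.
    """
    config = sample_a.config
    a_by_id = sample_a.features_by_id()
    b_by_id = sample_b.features_by_id()
    shared = sorted(a_by_id.keys() & b_by_id.keys())
    counts = {
        "regions_only_a": len(a_by_id.keys() - b_by_id.keys()),
        "regions_only_b": len(b_by_id.keys() - a_by_id.keys()),
        "regions_shared": len(shared),
    }
    region_deltas = pd.DataFrame(
        [
            {
                "region_id": rid,
                "meth_a": a_by_id[rid].mean_read_meth,
                "meth_b": b_by_id[rid].mean_read_meth,
                "delta_meth": b_by_id[rid].mean_read_meth - a_by_id[rid].mean_read_meth,
            }
            for rid in shared
        ],
        columns=["region_id", "meth_a", "meth_b", "delta_meth"],
    )
    hyper = select_hypermethylated(a_by_id, b_by_id, delta=config.hyper_delta)

    rows = []
    if model is not None:
        a_elements = {s.element_id: s for s in sample_a.element_summaries}
        b_elements = {s.element_id: s for s in sample_b.element_summaries}
        shared_elements = sorted(a_elements.keys() & b_elements.keys())
        counts["elements_shared"] = len(shared_elements)
        counts["elements_excluded"] = (
            len(a_elements.keys() ^ b_elements.keys())
        )
        for eid in shared_elements:
            score_a = pattern_score(model, a_elements[eid])
            score_b = pattern_score(model, b_elements[eid])
            rows.append(
                {
                    "element_id": eid,
                    "score_a": score_a,
                    "score_b": score_b,
                    "shift": score_b - score_a,
                }
            )
    element_shift = pd.DataFrame(
        rows, columns=["element_id", "score_a", "score_b", "shift"]
    )
    for key, value in sorted(counts.items()):
        logger.info("%s: %d", key, value)
    return CompareResult(
        region_deltas=region_deltas,
        hypermethylated=hyper,
        element_shift=element_shift,
        counts=counts,
    )
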
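"""Synthetic genomes, TE annotations and bisulfite reads with known truth.

The generator emulates the two CHH methylation regimes the pattern
classifier is built to separate:

* ``cmt2_like`` — every site of every read methylated independently with
  probability ``p`` (plus ``cwa_boost`` at CWA sites, reflecting CMT2's
  CAA/CTA preference). Reads look like binomial noise: unimodal read
  scores, stochasticity near 2p(1−p).
* ``drm2_like`` — a two-component read mixture: a fraction ``f_full`` of
  reads fully methylated across the region, the rest methylated at a low
  background ``p_bg``. Read scores are bimodal (cell-to-cell
  heterogeneity), stochasticity low.

Reads are single-end, uniformly placed, ungapped, split equally between
the two bisulfite strands; ``coverage`` is the per-bisulfite-strand depth,
so the number of same-strand reads fully covering a region of span ``s``
has expectation coverage·(1 − s/read_length) — the coverage-planning
formula exposed as :func:`expected_reads`. Cytosines outside any region
are emitted unmethylated (C→T on the converted strand), isolating signal
in the defined regions. Every simulated read/region pair is logged in a
truth table together with the analytic per-region mean and read-level
variance, so recovery can be checked against exact expectations.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import ContextSite, ElementAnnotation, GenomeSequence, classify_trinucleotide, find_sites, reverse_complement
from .reads import AlignedRead, ReadVector
from .regions import Region, RegionSpec, build_regions

__all__ = [
    "RegimeSpec",
    "CMT2_LIKE",
    "DRM2_LIKE",
    "SimulationTruth",
    "SyntheticDataset",
    "expected_reads",
    "generate_genome",
    "build_element_regions",
    "simulate_reads",
    "simulate_regime_vectors",
    "simulate_dataset",
    "write_fasta",
    "write_gff3",
    "write_sam",
]

_C2T = str.maketrans("C", "T")
_G2A = str.maketrans("G", "A")


@dataclass(frozen=True)
class RegimeSpec:
    """Parameters of one methylation regime.

    For ``drm2_like`` the overall mean must satisfy the mixture identity
    p = f_full + (1 − f_full)·p_bg. ``cwa_boost`` applies only to
    ``cmt2_like`` and is capped so per-site probabilities stay in [0, 1].
    """

    regime: str
    p: float = 0.3
    f_full: float = 0.3
    p_bg: float = 0.05
    cwa_boost: float = 0.2

    def __post_init__(self) -> None:
        if self.regime not in ("cmt2_like", "drm2_like"):
            raise ValueError(f"unknown regime {self.regime!r}")
        for name in ("p", "f_full", "p_bg", "cwa_boost"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.regime == "drm2_like":
            implied = self.f_full + (1.0 - self.f_full) * self.p_bg
            if abs(implied - self.p) > 1e-9:
                raise ValueError(
                    f"drm2_like mixture inconsistent: f_full + (1-f_full)*p_bg "
                    f"= {implied:.6g} but p = {self.p:.6g}"
                )

    def site_probs(self, cwa_flags: Sequence[bool]) -> np.ndarray:
        """Per-site methylation probabilities for a region's sites."""
        n = len(cwa_flags)
        if self.regime == "cmt2_like":
            probs = np.full(n, self.p)
            probs[np.asarray(cwa_flags, dtype=bool)] += self.cwa_boost
            return np.clip(probs, 0.0, 1.0)
        return np.full(n, self.p)  # marginal rate; mixture handled per read

    def mean_read_meth(self, cwa_flags: Sequence[bool]) -> float:
        """Analytic expected mean read methylation at these sites."""
        if self.regime == "cmt2_like":
            return float(self.site_probs(cwa_flags).mean())
        return self.f_full + (1.0 - self.f_full) * self.p_bg

    def read_meth_variance(self, cwa_flags: Sequence[bool]) -> float:
        """Analytic variance of a single read's methylation fraction."""
        n = len(cwa_flags)
        if self.regime == "cmt2_like":
            probs = self.site_probs(cwa_flags)
            return float(np.sum(probs * (1.0 - probs)) / n**2)
        f, q = self.f_full, self.p_bg
        mean = f + (1.0 - f) * q
        second = f + (1.0 - f) * (q * (1.0 - q) / n + q**2)
        return second - mean**2


#: default study conditions for the two regimes
CMT2_LIKE = RegimeSpec("cmt2_like", p=0.3, cwa_boost=0.2)
DRM2_LIKE = RegimeSpec("drm2_like", p=0.335, f_full=0.3, p_bg=0.05)


def expected_reads(coverage: float, region_size: int, read_length: int) -> float:
    """Expected fully-overlapping reads per region for library planning:
    coverage · (1 − region_size / read_length)."""
    if region_size > read_length:
        raise ValueError("region_size must not exceed read_length")
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    return coverage * (1.0 - region_size / read_length)


def build_element_regions(
    seq: GenomeSequence,
    elements: Iterable[ElementAnnotation],
    spec: RegionSpec = RegionSpec(),
) -> list[Region]:
    """Find context sites per element per strand and segment into regions."""
    regions: list[Region] = []
    for element in elements:
        sites = find_sites(seq, element, spec.context)
        for strand in ("+", "-"):
            strand_sites = [s for s in sites if s.strand == strand]
            regions.extend(
                build_regions(strand_sites, spec, element_id=element.element_id, seq=seq)
            )
    return regions


def generate_genome(
    length: int = 100_000,
    gc: float = 0.36,
    seed: int = 0,
    te_fraction: float = 0.5,
    te_length: int = 2_000,
    min_regions: int = 0,
    region_spec: RegionSpec = RegionSpec(),
    name: str = "chr1",
    max_tries: int = 20,
) -> tuple[GenomeSequence, list[ElementAnnotation]]:
    """Random genome at a target GC with evenly spaced, unstranded TEs.

    TEs tile ``te_fraction`` of the sequence in ``te_length`` blocks,
    separated (and flanked) by gaps, so no element sits at a sequence end.
    If fewer than ``min_regions`` valid regions are found across all TEs
    and strands, the sequence is resampled (fresh sub-seed) up to
    ``max_tries`` times.
    """
    if length < 1_000:
        raise ValueError("length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    n_te = max(1, int(length * te_fraction / te_length))
    gap = (length - n_te * te_length) // (n_te + 1)
    if gap < 1:
        raise ValueError("te_fraction/te_length leave no room between elements")
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    for child in np.random.SeedSequence(seed).spawn(max_tries):
        rng = np.random.default_rng(child)
        bases = "".join(rng.choice(list("ACGT"), size=length, p=probs))
        seq = GenomeSequence(name, bases)
        elements = []
        for i in range(n_te):
            start = gap + i * (te_length + gap)
            elements.append(
                ElementAnnotation(
                    element_id=f"TE{i + 1:04d}",
                    chrom=name,
                    start=start,
                    end=start + te_length,
                    strand=".",
                    feature_class="TE",
                )
            )
        if min_regions <= 0:
            return seq, elements
        if len(build_element_regions(seq, elements, region_spec)) >= min_regions:
            return seq, elements
    raise RuntimeError(
        f"could not generate {min_regions} regions in {max_tries} tries; "
        "increase length or relax the region spec"
    )


def _draw_states(
    regime: RegimeSpec, probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if regime.regime == "drm2_like":
        if rng.random() < regime.f_full:
            return np.ones(len(probs), dtype=int)
        return (rng.random(len(probs)) < regime.p_bg).astype(int)
    return (rng.random(len(probs)) < probs).astype(int)


def simulate_regime_vectors(
    regime: RegimeSpec,
    n_sites: int,
    n_reads: int,
    rng: np.random.Generator,
    cwa_flags: Sequence[bool] | None = None,
    region_id: str = "sim",
) -> list[ReadVector]:
    """Draw read vectors for one region directly (no genome or SAM).

    Convenience path for feature/classifier studies at scale; the same
    per-read draw is used by the full read simulator.
    """
    if cwa_flags is None:
        cwa_flags = [False] * n_sites
    probs = regime.site_probs(cwa_flags)
    return [
        ReadVector(
            read_id=f"{region_id}.r{i}",
            region_id=region_id,
            states=tuple(_draw_states(regime, probs, rng)),
        )
        for i in range(n_reads)
    ]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a read simulation.

    ``regions``: one row per region — regime, analytic mean read
    methylation (``p_true``), analytic per-read methylation variance and
    the per-site probabilities. ``reads``: one row per (read, overlapped
    region) with the true state vector at the region sites the read
    covers and whether it covers all of them.
    """

    regions: pd.DataFrame
    reads: pd.DataFrame


def _region_cwa_flags(seq: GenomeSequence, region: Region) -> list[bool]:
    flags = []
    for pos in region.site_positions:
        if region.strand == "+":
            tri = seq.bases[pos : pos + 3]
        else:
            tri = reverse_complement(seq.bases[pos - 2 : pos + 1])
        classified = classify_trinucleotide(tri)
        flags.append(classified is not None and classified[1] == "CWA")
    return flags


def simulate_reads(
    seq: GenomeSequence,
    regions: Sequence[Region],
    regime_of: Mapping[str, RegimeSpec],
    coverage: float = 10.0,
    read_length: int = 100,
    seed: int = 0,
) -> tuple[list[AlignedRead], SimulationTruth]:
    """Simulate bisulfite reads over a genome with per-region regimes.

    ``coverage`` reads per position are drawn per bisulfite strand with
    uniform starts. For every region a read overlaps (same strand), site
    states are drawn from the region's regime; all other cytosines are
    unmethylated. Unmethylated plus-strand Cs are written as T; on the
    minus (OB) strand the reference-forward G becomes A. Reads are valid
    ungapped alignments against the unconverted genome.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_length > len(seq):
        raise ValueError("read_length exceeds genome length")
    max_span = max((r.span_length for r in regions), default=0)
    if max_span > read_length:
        raise ValueError("read_length must exceed the largest region span")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    region_rows = []
    per_strand: dict[str, list[tuple[int, int, Region, RegimeSpec, np.ndarray]]] = {
        "+": [],
        "-": [],
    }
    for region in sorted(regions, key=lambda r: r.span_start):
        regime = regime_of[region.region_id]
        cwa = _region_cwa_flags(seq, region)
        probs = regime.site_probs(cwa)
        per_strand[region.strand].append(
            (region.span_start, region.span_end, region, regime, probs)
        )
        region_rows.append(
            {
                "region_id": region.region_id,
                "element_id": region.element_id,
                "strand": region.strand,
                "span_length": region.span_length,
                "n_sites": region.n_sites,
                "regime": regime.regime,
                "p_true": regime.mean_read_meth(cwa),
                "read_meth_var": regime.read_meth_variance(cwa),
                "site_probs": ",".join(f"{p:.6g}" for p in probs),
            }
        )

    n_per_strand = int(round(coverage * len(seq) / read_length))
    reads: list[AlignedRead] = []
    read_rows = []
    for strand, tag, flag_reverse in (("+", "p", False), ("-", "m", True)):
        entries = per_strand[strand]
        span_starts = [e[0] for e in entries]
        starts = rng.integers(0, len(seq) - read_length + 1, size=n_per_strand)
        for i, start in enumerate(starts):
            start = int(start)
            end = start + read_length
            read_id = f"{tag}{i:06d}"
            methylated: list[int] = []
            lo = bisect_left(span_starts, start - max_span)
            hi = bisect_left(span_starts, end)
            for span_start, span_end, region, regime, probs in entries[lo:hi]:
                if span_end < start or span_start >= end:
                    continue
                covered = [
                    k
                    for k, pos in enumerate(region.site_positions)
                    if start <= pos < end
                ]
                states = _draw_states(regime, probs[covered], rng)
                methylated.extend(
                    region.site_positions[k]
                    for k, s in zip(covered, states)
                    if s == 1
                )
                read_rows.append(
                    {
                        "read_id": read_id,
                        "region_id": region.region_id,
                        "states": "".join(str(s) for s in states),
                        "fully_covers": len(covered) == region.n_sites,
                    }
                )
            frag = seq.bases[start:end]
            conv = list(frag.translate(_C2T if strand == "+" else _G2A))
            restore = "C" if strand == "+" else "G"
            for pos in methylated:
                conv[pos - start] = restore
            reads.append(
                AlignedRead(
                    read_id=read_id,
                    chrom=seq.name,
                    pos=start,
                    is_reverse=flag_reverse,
                    seq="".join(conv),
                    bs_strand=strand,
                )
            )
    truth = SimulationTruth(
        regions=pd.DataFrame(region_rows),
        reads=pd.DataFrame(
            read_rows, columns=["read_id", "region_id", "states", "fully_covers"]
        ),
    )
    return reads, truth


@dataclass
class SyntheticDataset:
    """A complete desk-scale fixture: genome, annotation, regions, reads."""

    genome: GenomeSequence
    elements: list[ElementAnnotation]
    regions: list[Region]
    element_regime: dict[str, str]
    regime_of: dict[str, RegimeSpec]
    reads: list[AlignedRead]
    truth: SimulationTruth
    coverage: float
    read_length: int
    seed: int
    paths: dict[str, Path] = field(default_factory=dict)


def simulate_dataset(
    out_dir: str | Path | None = None,
    length: int = 100_000,
    gc: float = 0.36,
    te_fraction: float = 0.5,
    te_length: int = 2_000,
    region_spec: RegionSpec = RegionSpec(),
    cmt2_regime: RegimeSpec = CMT2_LIKE,
    drm2_regime: RegimeSpec = DRM2_LIKE,
    cmt2_fraction: float = 0.5,
    coverage: float = 10.0,
    read_length: int = 100,
    min_regions: int = 200,
    seed: int = 0,
) -> SyntheticDataset:
    """End-to-end fixture generation under the default study conditions.

    Each TE is assigned a regime (CMT2-like with probability
    ``cmt2_fraction``), all its regions inherit it, and reads are simulated
    at the requested coverage. With ``out_dir`` set, FASTA/GFF3/SAM, the
    truth tables and a config snapshot are written as plain text.
    """
    seeds = np.random.SeedSequence(seed).spawn(3)
    genome, elements = generate_genome(
        length=length,
        gc=gc,
        seed=int(seeds[0].generate_state(1)[0] % (2**31)),
        te_fraction=te_fraction,
        te_length=te_length,
        min_regions=min_regions,
        region_spec=region_spec,
    )
    regions = build_element_regions(genome, elements, region_spec)

    rng = np.random.default_rng(seeds[1])
    element_regime = {
        e.element_id: ("cmt2_like" if rng.random() < cmt2_fraction else "drm2_like")
        for e in elements
    }
    regime_lookup = {"cmt2_like": cmt2_regime, "drm2_like": drm2_regime}
    regime_of = {
        r.region_id: regime_lookup[element_regime[r.element_id]] for r in regions
    }
    reads, truth = simulate_reads(
        genome,
        regions,
        regime_of,
        coverage=coverage,
        read_length=read_length,
        seed=int(seeds[2].generate_state(1)[0] % (2**31)),
    )
    dataset = SyntheticDataset(
        genome=genome,
        elements=elements,
        regions=regions,
        element_regime=element_regime,
        regime_of=regime_of,
        reads=reads,
        truth=truth,
        coverage=coverage,
        read_length=read_length,
        seed=seed,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dataset.paths = {
            "fasta": out / "genome.fa",
            "gff": out / "elements.gff3",
            "sam": out / "reads.sam",
            "truth_regions": out / "truth_regions.tsv",
            "truth_reads": out / "truth_reads.tsv",
            "config": out / "simulation_config.txt",
        }
        write_fasta(dataset.paths["fasta"], [genome])
        write_gff3(dataset.paths["gff"], elements)
        write_sam(dataset.paths["sam"], [genome], reads)
        truth.regions.to_csv(dataset.paths["truth_regions"], sep="\t", index=False)
        truth.reads.to_csv(dataset.paths["truth_reads"], sep="\t", index=False)
        with open(dataset.paths["config"], "w") as handle:
            for key, value in (
                ("length", length),
                ("gc", gc),
                ("te_fraction", te_fraction),
                ("te_length", te_length),
                ("n_sites", region_spec.n_sites),
                ("max_span", region_spec.max_span),
                ("context", region_spec.context),
                ("cmt2_fraction", cmt2_fraction),
                ("coverage", coverage),
                ("read_length", read_length),
                ("seed", seed),
            ):
                handle.write(f"{key} = {value}\n")
    return dataset


def write_fasta(
    path: str | Path, genomes: Iterable[GenomeSequence], width: int = 70
) -> None:
    records = [
        SeqRecord(Seq(g.bases), id=g.name, description="") for g in genomes
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def write_gff3(path: str | Path, elements: Iterable[ElementAnnotation]) -> None:
    """GFF3 output (1-based inclusive coordinates on disk)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for e in elements:
            handle.write(
                f"{e.chrom}\tsrmeth\t{e.feature_class or 'region'}\t{e.start + 1}\t"
                f"{e.end}\t.\t{e.strand}\t.\tID={e.element_id}\n"
            )


def write_sam(
    path: str | Path,
    genomes: Sequence[GenomeSequence],
    reads: Iterable[AlignedRead],
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": g.name, "LN": len(g)} for g in genomes],
    }
    ref_index = {g.name: i for i, g in enumerate(genomes)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = read.read_id
            aln.flag = 16 if read.is_reverse else 0
            aln.reference_id = ref_index[read.chrom]
            aln.reference_start = read.pos
            aln.mapping_quality = 42
            aln.cigartuples = [(0, len(read.seq))]
            aln.query_sequence = read.seq
            out.write(aln)
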
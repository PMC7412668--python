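"""Shared fixtures: the default synthetic dataset and small hand fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from srmeth import (
    AlignedRead,
    AnalysisConfig,
    ContextSite,
    ElementAnnotation,
    GenomeSequence,
    ReadVector,
    analyze,
    fit_pattern_model,
    simulate_dataset,
)
from srmeth.simulate import write_fasta, write_gff3, write_sam

SEED = 1


def make_chh_sites(positions, chrom="chr1", strand="+", trinucleotide="CAT"):
    """Fabricate CHH nonCWA sites at given positions (for region building)."""
    sub = "CWA" if trinucleotide in ("CAA", "CTA") else "nonCWA"
    return [
        ContextSite(chrom, pos, strand, "CHH", sub, trinucleotide)
        for pos in positions
    ]


def make_vectors(patterns, region_id="r1"):
    return [
        ReadVector(read_id=f"read{i}", region_id=region_id, states=tuple(p))
        for i, p in enumerate(patterns)
    ]


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 100 kb genome, 25 TEs, coverage 10."""
    return simulate_dataset(seed=SEED)


@pytest.fixture(scope="session")
def default_result(default_dataset):
    ds = default_dataset
    return analyze({ds.genome.name: ds.genome}, ds.elements, ds.reads)


@pytest.fixture(scope="session")
def regime_by_region(default_dataset):
    truth = default_dataset.truth.regions
    return dict(zip(truth.region_id, truth.regime))


@pytest.fixture(scope="session")
def labeled_features(default_result, regime_by_region):
    """Passing region features split by true regime (drm2, cmt2)."""
    passing = default_result.passing_features()
    drm2 = [f for f in passing if regime_by_region[f.region_id] == "drm2_like"]
    cmt2 = [f for f in passing if regime_by_region[f.region_id] == "cmt2_like"]
    return drm2, cmt2


@pytest.fixture(scope="session")
def fitted_model(labeled_features):
    drm2, cmt2 = labeled_features
    return fit_pattern_model(drm2, cmt2)


# --- exhaustive 32-pattern fixture ------------------------------------------

#: genome with exactly five plus-strand CHH (CAT) sites at 10,13,16,19,22
PATTERN_GENOME = "T" * 10 + "CAT" * 5 + "T" * 10
PATTERN_SITES = (10, 13, 16, 19, 22)


def pattern_read_seq(states, start=5, length=35):
    """Read sequence for one methylation pattern over the 5 CAT sites."""
    bases = list(PATTERN_GENOME[start : start + length])
    for pos, state in zip(PATTERN_SITES, states):
        bases[pos - start] = "C" if state else "T"
    return "".join(bases)


def all_pattern_reads(start=5, length=35):
    """The 2^5 = 32 exhaustive single-read methylation patterns."""
    reads = []
    for k in range(32):
        states = tuple((k >> (4 - j)) & 1 for j in range(5))
        reads.append(
            (
                states,
                AlignedRead(
                    read_id=f"p{k:02d}",
                    chrom="chr1",
                    pos=start,
                    is_reverse=False,
                    seq=pattern_read_seq(states, start, length),
                    bs_strand="+",
                ),
            )
        )
    return reads


@pytest.fixture(scope="session")
def pattern_fixture_paths(tmp_path_factory):
    """FASTA + GFF3 + SAM files holding the 32-pattern fixture."""
    out = tmp_path_factory.mktemp("pattern32")
    genome = GenomeSequence("chr1", PATTERN_GENOME)
    element = ElementAnnotation("te1", "chr1", 0, len(PATTERN_GENOME), ".", "TE")
    write_fasta(out / "genome.fa", [genome])
    write_gff3(out / "elements.gff3", [element])
    write_sam(out / "reads.sam", [genome], [read for _, read in all_pattern_reads()])
    return {
        "fasta": out / "genome.fa",
        "gff": out / "elements.gff3",
        "sam": out / "reads.sam",
    }
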
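"""Aligned bisulfite read parsing and per-region binary methylation vectors.

Bisulfite treatment converts unmethylated cytosine to uracil (read as T);
methylated cytosine stays C. A directional library yields two informative
read populations: original-top (OT) reads report plus-strand cytosines
(C = methylated, T = unmethylated at a C reference position) and
original-bottom (OB) reads report minus-strand cytosines, which in the
reference-forward orientation stored in SAM appear as G (methylated) or A
(unmethylated) at a forward G position.

Only ungapped end-to-end alignments are accepted, matching a no-mismatch,
no-gap bisulfite alignment. A read contributes to a region only if it
covers *all* of the region's sites on the matching bisulfite strand and
every site call is informative; partial vectors are never emitted.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .features import read_stochasticity
from .genome import ContextSite, GenomeSequence
from .regions import Region

__all__ = [
    "AlignedRead",
    "ReadVector",
    "parse_sam",
    "dedupe_exact",
    "call_site",
    "extract_read_vectors",
    "ReadIndex",
    "write_vector_table",
]

_ACCEPTED_CIGAR_OPS = {0, 7, 8}  # M, =, X — full-length matches only


@dataclass(frozen=True)
class AlignedRead:
    """One accepted SAM record (reference-forward base sequence)."""

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost aligned position
    is_reverse: bool
    seq: str
    bs_strand: str  # '+': OT (reports plus-strand Cs); '-': OB

    @property
    def end(self) -> int:
        return self.pos + len(self.seq)


@dataclass(frozen=True)
class ReadVector:
    """Binary methylation states of one read at one region's sites."""

    read_id: str
    region_id: str
    states: tuple[int, ...]

    @property
    def score(self) -> int:
        return int(sum(self.states))

    @property
    def methylation(self) -> float:
        return self.score / len(self.states)

    @property
    def stochasticity(self) -> float:
        return read_stochasticity(self.states)


def parse_sam(
    path: str | Path,
    genome: dict[str, GenomeSequence] | None = None,
) -> tuple[list[AlignedRead], Counter]:
    """Read a SAM file, keeping primary mapped ungapped records.

    Returns the accepted reads and a counter of skipped categories
    (unmapped, secondary, gapped). The bisulfite strand is inferred from
    FLAG bit 16 (directional library: forward = OT, reverse = OB) unless a
    Bismark-style ``XG`` tag (``CT``/``GA``) overrides it. A reference name
    absent from ``genome`` (when given) is a hard error.
    """
    reads: list[AlignedRead] = []
    counts: Counter = Counter()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        for aln in handle:
            counts["total"] += 1
            if aln.is_unmapped:
                counts["unmapped"] += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                counts["secondary"] += 1
                continue
            cigar = aln.cigartuples or []
            if any(op not in _ACCEPTED_CIGAR_OPS for op, _ in cigar):
                counts["gapped"] += 1
                continue
            chrom = aln.reference_name
            if genome is not None and chrom not in genome:
                raise ValueError(f"SAM reference {chrom!r} absent from genome")
            bs_strand = "-" if aln.is_reverse else "+"
            if aln.has_tag("XG"):
                bs_strand = "+" if aln.get_tag("XG") == "CT" else "-"
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    chrom=chrom,
                    pos=aln.reference_start,
                    is_reverse=aln.is_reverse,
                    seq=aln.query_sequence.upper(),
                    bs_strand=bs_strand,
                )
            )
            counts["accepted"] += 1
    return reads, counts


def dedupe_exact(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Collapse exact duplicates — identical (chrom, pos, orientation, seq).

    The first occurrence is kept; output is sorted by (chrom, pos).
    """
    seen: set[tuple] = set()
    out: list[AlignedRead] = []
    for read in sorted(reads, key=lambda r: (r.chrom, r.pos, r.is_reverse, r.seq)):
        key = (read.chrom, read.pos, read.is_reverse, read.seq)
        if key in seen:
            continue
        seen.add(key)
        out.append(read)
    return out


def _call_base(base: str, site_strand: str) -> int | None:
    if site_strand == "+":
        return {"C": 1, "T": 0}.get(base)
    return {"G": 1, "A": 0}.get(base)


def call_site(read: AlignedRead, site: ContextSite) -> int | None:
    """Methylation call of one read at one site: 1, 0 or None (uninformative).

    A plus-strand site is read C→methylated / T→unmethylated; a minus-strand
    site is read on the reference-forward sequence G→methylated /
    A→unmethylated. The site must lie within the read's aligned span.
    """
    offset = site.pos - read.pos
    if offset < 0 or offset >= len(read.seq):
        raise ValueError(
            f"site {site.chrom}:{site.pos} outside read {read.read_id!r} span"
        )
    return _call_base(read.seq[offset], site.strand)


def extract_read_vectors(region: Region, reads: Iterable[AlignedRead]) -> list[ReadVector]:
    """Binary vectors of all reads fully covering a region's sites.

    Reads must be on the region's chromosome and bisulfite strand and their
    aligned span must contain every site. Any uninformative base at a site
    discards the read for this region (no partial vectors).
    """
    first = region.site_positions[0]
    last = region.site_positions[-1]
    vectors: list[ReadVector] = []
    for read in reads:
        if read.chrom != region.chrom or read.bs_strand != region.strand:
            continue
        if read.pos > first or read.end <= last:
            continue
        states = []
        for pos in region.site_positions:
            call = _call_base(read.seq[pos - read.pos], region.strand)
            if call is None:
                break
            states.append(call)
        else:
            vectors.append(ReadVector(read.read_id, region.region_id, tuple(states)))
    return vectors


class ReadIndex:
    """Position index over reads of one sample for fast region extraction.

    Reads are bucketed by (chrom, bisulfite strand) and sorted by start, so
    the candidate reads for a region are found by bisection instead of a
    full scan. Extraction semantics are identical to
    :func:`extract_read_vectors`.
    """

    def __init__(self, reads: Iterable[AlignedRead]):
        self._buckets: dict[tuple[str, str], tuple[list[int], list[AlignedRead]]] = {}
        grouped: dict[tuple[str, str], list[AlignedRead]] = {}
        self._max_len = 0
        for read in reads:
            grouped.setdefault((read.chrom, read.bs_strand), []).append(read)
            self._max_len = max(self._max_len, len(read.seq))
        for key, bucket in grouped.items():
            bucket.sort(key=lambda r: r.pos)
            self._buckets[key] = ([r.pos for r in bucket], bucket)

    def candidates(self, region: Region) -> list[AlignedRead]:
        entry = self._buckets.get((region.chrom, region.strand))
        if entry is None:
            return []
        positions, bucket = entry
        first, last = region.site_positions[0], region.site_positions[-1]
        lo = bisect_left(positions, last + 1 - self._max_len)
        hi = bisect_right(positions, first)
        return bucket[lo:hi]

    def extract(self, region: Region) -> list[ReadVector]:
        return extract_read_vectors(region, self.candidates(region))


def write_vector_table(vectors: Iterable[ReadVector], path: str | Path) -> None:
    """TSV of read vectors: region_id, read_id, states as 0/1 string, score."""
    with open(path, "w") as handle:
        handle.write("region_id\tread_id\tstates\tscore\n")
        for v in vectors:
            states = "".join(str(s) for s in v.states)
            handle.write(f"{v.region_id}\t{v.read_id}\t{states}\t{v.score}\n")
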
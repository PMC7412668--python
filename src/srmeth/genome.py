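"""Reference genome handling and strand-aware methylation-context detection.

Plant cytosine methylation occurs in three sequence contexts — CG, CHG and
CHH, where H is any base except G. CHH is asymmetric: a CHH cytosine on the
plus strand has no partner on the minus strand, so context sites must be
detected separately per strand by reading each strand 5'→3'. The CHH
subcontext CWA (CAA/CTA, W = A or T) is the preferred substrate of the CMT2
methyltransferase and can be selected on its own. ``CH`` (any non-CG
cytosine) is provided for mammalian-style non-CG analyses.

Coordinates are 0-based half-open internally; GFF input is converted at the
boundary. For a minus-strand site, ``pos`` is the forward-genome coordinate
of the base pair (a G on the forward strand) and the trinucleotide is read
5'→3' on the minus strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "ElementAnnotation",
    "ContextSite",
    "load_fasta",
    "load_gff",
    "find_sites",
    "classify_trinucleotide",
    "gc_content",
    "reverse_complement",
    "write_site_table",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: context classes accepted by :func:`find_sites`
CONTEXT_CLASSES = ("CG", "CHG", "CHH", "CH", "CWA", "nonCWA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome or scaffold of the reference assembly."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.bases)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end) with bounds checking."""
        if start < 0 or end > len(self.bases) or start >= end:
            raise IndexError(
                f"window [{start}, {end}) outside sequence {self.name!r} "
                f"of length {len(self.bases)}"
            )
        return self.bases[start:end]


@dataclass(frozen=True)
class ElementAnnotation:
    """An annotated functional element (TE, gene, exon, ...).

    ``start``/``end`` are 0-based half-open. ``strand`` is '+', '-' or '.'
    (unstranded); unstranded elements are scanned on both strands, which is
    the common case for TE annotations since CHH regions are defined per
    strand regardless of element orientation.
    """

    element_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_class: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"element {self.element_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"element {self.element_id!r}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class ContextSite:
    """A single cytosine with its methylation context.

    ``trinucleotide`` is the 3-mer read 5'→3' on the site's own strand and
    always starts with C. ``subcontext`` is CWA/nonCWA for CHH sites and
    'NA' otherwise.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    subcontext: str
    trinucleotide: str


def load_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (possibly multi-record, line-wrapped) FASTA into memory.

    Sequences are uppercased. Raises ``ValueError`` on an empty file or a
    duplicated record name.
    """
    genomes: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genomes:
            raise ValueError(f"duplicate FASTA record {record.id!r} in {path}")
        genomes[record.id] = GenomeSequence(record.id, str(record.seq).upper())
    if not genomes:
        raise ValueError(f"no FASTA records found in {path}")
    return genomes


def load_gff(
    path: str | Path, feature_filter: str | None = None
) -> list[ElementAnnotation]:
    """Load element annotations from GFF3 (1-based inclusive on disk).

    Coordinates are converted to 0-based half-open. Records with end < start
    are rejected with a warning. ``feature_filter`` keeps only rows of one
    feature type (GFF column 3). Elements without an ID attribute get a
    positional identifier.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    elements: list[ElementAnnotation] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feature_filter is not None and feat.featuretype != feature_filter:
            continue
        if feat.end < feat.start:
            warnings.warn(
                f"GFF record {feat.id!r} on {feat.seqid}: end {feat.end} < "
                f"start {feat.start}; record skipped"
            )
            continue
        element_id = feat.attributes.get("ID", [None])[0]
        if element_id is None:
            element_id = f"{feat.featuretype}:{feat.seqid}:{feat.start}-{feat.end}"
        elements.append(
            ElementAnnotation(
                element_id=element_id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else ".",
                feature_class=feat.featuretype,
            )
        )
    return elements


def classify_trinucleotide(tri: str) -> tuple[str, str] | None:
    """Classify a 5'→3' trinucleotide starting at a cytosine.

    Returns ``(context, subcontext)`` with context in {CG, CHG, CHH} and
    subcontext CWA/nonCWA for CHH (NA otherwise), or ``None`` if the 3-mer
    does not start with C or contains an ambiguous base.
    """
    if len(tri) != 3 or tri[0] != "C" or "N" in tri:
        return None
    if tri[1] == "G":
        return "CG", "NA"
    if tri[2] == "G":
        return "CHG", "NA"
    subcontext = "CWA" if tri in ("CAA", "CTA") else "nonCWA"
    return "CHH", subcontext


def _matches(requested: str, context: str, subcontext: str) -> bool:
    if requested == "CH":
        return context in ("CHG", "CHH")
    if requested == "CWA":
        return subcontext == "CWA"
    if requested == "nonCWA":
        return subcontext == "nonCWA"
    return context == requested


def find_sites(
    seq: GenomeSequence,
    interval: ElementAnnotation,
    context: str = "CHH",
) -> list[ContextSite]:
    """Detect context sites of ``context`` inside ``interval``, per strand.

    Stranded intervals are scanned only on their own strand; unstranded
    ('.') intervals on both. Sites whose trinucleotide would run past a
    sequence end, or contains an N, are skipped. Sites are returned plus
    strand first, each strand sorted by position.
    """
    if context not in CONTEXT_CLASSES:
        raise ValueError(f"unknown context class {context!r}")
    if interval.end > len(seq):
        raise ValueError(
            f"element {interval.element_id!r} extends past end of {seq.name!r}"
        )
    bases = seq.bases
    sites: list[ContextSite] = []
    if interval.strand in ("+", "."):
        stop = min(interval.end, len(bases) - 2)
        for pos in range(interval.start, stop):
            if bases[pos] != "C":
                continue
            classified = classify_trinucleotide(bases[pos : pos + 3])
            if classified is None:
                continue
            ctx, sub = classified
            if _matches(context, ctx, sub):
                sites.append(
                    ContextSite(seq.name, pos, "+", ctx, sub, bases[pos : pos + 3])
                )
    if interval.strand in ("-", "."):
        for pos in range(max(interval.start, 2), interval.end):
            if bases[pos] != "G":
                continue
            tri = reverse_complement(bases[pos - 2 : pos + 1])
            classified = classify_trinucleotide(tri)
            if classified is None:
                continue
            ctx, sub = classified
            if _matches(context, ctx, sub):
                sites.append(ContextSite(seq.name, pos, "-", ctx, sub, tri))
    return sites


def gc_content(seq: str) -> float:
    """Fraction (G+C)/(A+C+G+T) of a window; N excluded from both counts.

    Returns NaN (with a warning) for an all-N window; raises on empty input.
    """
    if not seq:
        raise ValueError("gc_content of empty sequence is undefined")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        warnings.warn("gc_content window is all N; returning NaN")
        return float("nan")
    return gc / denom


def write_site_table(sites: Iterable[ContextSite], path: str | Path) -> None:
    """Write sites as TSV: chrom, pos0, strand, context, subcontext, trinucleotide."""
    with open(path, "w") as handle:
        handle.write("chrom\tpos0\tstrand\tcontext\tsubcontext\ttrinucleotide\n")
        for s in sites:
            handle.write(
                f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.context}\t{s.subcontext}\t{s.trinucleotide}\n"
            )
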
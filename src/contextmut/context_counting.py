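"""k-mer context tabulation, variant context extraction, codon usage.

The denominators of every context-dependent rate are occurrence tallies of
k-mers over a region (whole chromosome or one replichore) and a strand.
Windows are keyed by the coordinate of their *mutable* base — the center
for odd k, the left-of-center base for even k — and a window belongs to a
replichore iff that key coordinate does, because rates are per mutable
site. Circular genomes wrap windows across the junction so that exactly L
windows exist; windows containing N are tallied in ``n_skipped`` rather
than silently dropped.

Counting is vectorized (base-4 window encoding + bincount) so whole
bacterial chromosomes tabulate in well under a second; tests check it
against a naive string-slicing oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .errors import ContextUnavailable, DomainError
from .io_formats import AnnotationSet, Genome, VariantRecord
from .replication import ReplicationFrame, assign_replichore, replichore_mask

BASES = "ACGT"
REGIONS = ("genome", "right_replichore", "left_replichore")
STRANDS = ("reference", "complement")
CONVENTIONS = ("as_reference", "lagging_template_revcomp")

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise DomainError(f"illegal characters for reverse complement: {sorted(bad)}")
    return seq.translate(_RC_TABLE)[::-1]


@dataclass
class ContextCountTable:
    """Occurrence counts of k-contexts for one region and strand.

    ``counts`` holds only contexts observed at least once; absent keys are
    zero. ``sum(counts.values()) + n_skipped`` equals the number of windows
    in the region (L for a circular whole genome at any k).
    """

    k: int
    region: str
    strand: str
    counts: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ContextualVariant:
    """A variant with its local sequence context, replichore, and
    strand-convention-oriented alleles.

    ``oriented_*`` fields equal the raw ones unless the lagging-template
    convention applied a reverse complement (right replichore)."""

    position: int
    ref: str
    alt: str
    up_base: str
    down_base: str
    replichore: str
    oriented_triplet: str
    oriented_ref: str
    oriented_alt: str
    extended_up: str = ""
    extended_down: str = ""
    lineage: Optional[str] = None

    @property
    def triplet(self) -> str:
        """Reference-strand triplet (5'→3')."""
        return self.up_base + self.ref + self.down_base


@dataclass
class CodonUsageTable:
    region: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# k-mer counting
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = 254


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_strings(k: int) -> list[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [s + b for s in kmers for b in BASES]
    return kmers


def _revcomp_index_table(k: int) -> np.ndarray:
    kmers = _kmer_strings(k)
    lookup = {s: i for i, s in enumerate(kmers)}
    return np.array([lookup[reverse_complement(s)] for s in kmers], dtype=np.int64)


def key_offsets(k: int) -> tuple[int, int]:
    """(bases to the left, bases to the right) of the window's key base.

    Odd k keys the center; even k keys the left-of-center base (so a k=4
    window covers one upstream and two downstream neighbors)."""
    left = k // 2 if k % 2 == 1 else k // 2 - 1
    return left, k - 1 - left


def count_contexts(
    genome: Genome,
    frame: Optional[ReplicationFrame],
    k: int,
    region: str = "genome",
    strand: str = "reference",
) -> ContextCountTable:
    """Tabulate all width-k windows of a region into a ContextCountTable.

    ``strand='complement'`` counts the reverse complement of each window
    (the context as read on the complementary strand), leaving the window
    set itself unchanged.
    """
    if region not in REGIONS:
        raise DomainError(f"unknown region {region!r}")
    if strand not in STRANDS:
        raise DomainError(f"unknown strand {strand!r}")
    if region != "genome" and frame is None:
        raise DomainError("replichore regions require a ReplicationFrame")
    L = genome.length
    if k > L:
        raise DomainError(f"k={k} exceeds genome length {L}")
    left, right = key_offsets(k)

    codes = _encode(genome.sequence).astype(np.int64)
    if genome.circular:
        key_coords = np.arange(L, dtype=np.int64)
    else:
        key_coords = np.arange(left, L - right, dtype=np.int64)

    win_ids = np.zeros(len(key_coords), dtype=np.int64)
    valid = np.ones(len(key_coords), dtype=bool)
    for j in range(k):
        idx = (key_coords - left + j) % L
        c = codes[idx]
        good = c < 4
        valid &= good
        win_ids = win_ids * 4 + np.where(good, c, 0)

    if region != "genome":
        right_mask = replichore_mask(frame)[key_coords]
        sel = right_mask if region == "right_replichore" else ~right_mask
        win_ids, valid = win_ids[sel], valid[sel]

    if strand == "complement":
        win_ids = _revcomp_index_table(k)[np.where(valid, win_ids, 0)]

    n_skipped = int((~valid).sum())
    tallies = np.bincount(win_ids[valid], minlength=4**k)
    kmers = _kmer_strings(k)
    counts = {kmers[i]: int(tallies[i]) for i in np.nonzero(tallies)[0]}
    return ContextCountTable(k=k, region=region, strand=strand, counts=counts, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# Variant context extraction
# ---------------------------------------------------------------------------


def _neighbor(genome: Genome, position: int, delta: int) -> Optional[str]:
    """Base at (position + delta), wrapping if circular; None if off a
    linear end."""
    idx = position - 1 + delta
    if genome.circular:
        return genome.sequence[idx % genome.length]
    if 0 <= idx < genome.length:
        return genome.sequence[idx]
    return None


def extract_context(
    genome: Genome,
    frame: ReplicationFrame,
    variant: VariantRecord,
    convention: str = "as_reference",
) -> ContextualVariant:
    """Resolve a variant's flanking bases, replichore, and oriented alleles.

    Under ``lagging_template_revcomp`` a right-replichore variant has its
    triplet, ref, and alt replaced by reverse complements so that both
    replichores are read in their synthesis (lagging-template)
    orientation; ``as_reference`` applies no transformation.

    Raises ContextUnavailable for N-containing contexts or variants at the
    termini of a linear genome.
    """
    if convention not in CONVENTIONS:
        raise DomainError(f"unknown convention {convention!r}")
    p = variant.position
    if not 1 <= p <= genome.length:
        raise DomainError(f"position {p} outside 1..{genome.length}")
    up = _neighbor(genome, p, -1)
    down = _neighbor(genome, p, +1)
    if up is None or down is None:
        raise ContextUnavailable("terminal position on linear genome")
    ref = genome.base(p)
    if "N" in (up, ref, down):
        raise ContextUnavailable("ambiguous context")
    eu = (_neighbor(genome, p, -2) or "") + up
    ed = down + (_neighbor(genome, p, +2) or "")
    side = assign_replichore(frame, p)
    triplet = up + ref + down
    if convention == "lagging_template_revcomp" and side == "right":
        o_trip = reverse_complement(triplet)
        o_ref = reverse_complement(ref)
        o_alt = reverse_complement(variant.alt)
        o_eu, o_ed = reverse_complement(ed), reverse_complement(eu)
    else:
        o_trip, o_ref, o_alt = triplet, ref, variant.alt
        o_eu, o_ed = eu, ed
    return ContextualVariant(
        position=p,
        ref=ref,
        alt=variant.alt,
        up_base=up,
        down_base=down,
        replichore=side,
        oriented_triplet=o_trip,
        oriented_ref=o_ref,
        oriented_alt=o_alt,
        extended_up=o_eu,
        extended_down=o_ed,
        lineage=variant.lineage,
    )


def orient_variants(
    genome: Genome,
    frame: ReplicationFrame,
    records: Iterable[VariantRecord],
    convention: str = "as_reference",
    region: str = "genome",
) -> tuple[list[ContextualVariant], list[tuple[int, str]]]:
    """extract_context over a record list, filtering to a region.

    Returns (oriented variants, exclusion log of (source_line, reason)).
    Region filtering is not an exclusion: out-of-region variants are simply
    not part of this region's list.
    """
    out: list[ContextualVariant] = []
    excluded: list[tuple[int, str]] = []
    want = {"genome": None, "right_replichore": "right", "left_replichore": "left"}[region]
    for rec in records:
        try:
            cv = extract_context(genome, frame, rec, convention)
        except ContextUnavailable as exc:
            excluded.append((rec.source_line, exc.reason))
            continue
        if want is None or cv.replichore == want:
            out.append(cv)
    return out, excluded


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------


def count_codon_usage(
    genome: Genome,
    annotations: AnnotationSet,
    frame: Optional[ReplicationFrame],
    region: str = "genome",
) -> CodonUsageTable:
    """In-frame codon tallies over complete CDS of a region.

    Minus-strand CDS are read as the reverse complement of their genomic
    span; join() CDS concatenate their parts in ascending coordinate order
    before the strand flip. A CDS belongs to a replichore by the replichore
    of its leftmost (start) coordinate. Codons containing N are skipped.
    """
    if region not in REGIONS:
        raise DomainError(f"unknown region {region!r}")
    counts: dict[str, int] = {}
    for cds in annotations.cds(complete_only=True):
        if region != "genome":
            side = assign_replichore(frame, cds.start)
            if (region == "right_replichore") != (side == "right"):
                continue
        parts = cds.parts or ((cds.start, cds.end),)
        seq = "".join(genome.sequence[s - 1 : e] for s, e in parts)
        if cds.strand == "-":
            seq = reverse_complement(seq)
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if "N" not in codon:
                counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable(region=region, counts=counts)


def base_totals(genome: Genome, frame: Optional[ReplicationFrame] = None, region: str = "genome") -> dict[str, int]:
    """Per-base occurrence totals for a region (denominator of conditional
    rates)."""
    if region == "genome":
        seq = genome.sequence
        return {b: seq.count(b) for b in BASES}
    mask = replichore_mask(frame)
    if region == "left_replichore":
        mask = ~mask
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)[mask]
    return {b: int((arr == ord(b)).sum()) for b in BASES}
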
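"""Replication origin/terminus determination and replichore partitioning.

A bacterial chromosome replicates bidirectionally from a single origin
(ORI) to a terminus (TER); the two arcs between them are the replichores.
Strand-specific mutational asymmetry is only interpretable after orienting
every site with respect to these landmarks.

The origin is located from the cumulative GC skew: with the leading strand
G-rich, the running sum of (+1 per G, -1 per C) attains its global minimum
at the ORI and its global maximum at the TER. This global-extrema rule is a
deliberately simple stand-in for segmented-regression skew fitting; see
docs/methods.md for the divergence and its consequences. For genomes where
skew detection is unreliable the frame can be specified manually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DetectionError, DomainError
from .io_formats import AnnotationSet, Genome

SITE_SETS = ("all_sites", "synonymous_third_codon")

_SKEW_VALUE = {"G": 1, "C": -1}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class SkewProfile:
    """Cumulative GC-skew profile over a chosen site set.

    ``positions`` are ascending 1-based coordinates of the counted sites;
    ``cumulative[i]`` is the running (+1 G / -1 C) sum through site i.
    """

    positions: np.ndarray
    cumulative: np.ndarray
    site_set: str = "all_sites"

    def __post_init__(self):
        if len(self.positions) != len(self.cumulative):
            raise ValueError("positions and cumulative must have equal length")


@dataclass(frozen=True)
class ReplicationFrame:
    """ORI/TER coordinates partitioning a chromosome into two replichores.

    The *right* replichore is the half-open arc from ORI toward increasing
    coordinates (mod length) up to but excluding TER; the *left* replichore
    is the complementary arc. ORI itself is right, TER is left.
    """

    ori: int  # 1-based
    ter: int  # 1-based
    genome_length: int
    circular: bool = True
    source: str = "skew_extrema"  # or "user"

    def __post_init__(self):
        for name, pos in (("ori", self.ori), ("ter", self.ter)):
            if not 1 <= pos <= self.genome_length:
                raise DomainError(
                    f"{name}={pos} outside 1..{self.genome_length}"
                )
        if self.ori == self.ter:
            raise DomainError("ori and ter must differ")


def make_frame(
    ori: int,
    ter: int,
    genome_length: int,
    circular: bool = True,
    source: str = "user",
) -> ReplicationFrame:
    """Build a user-specified frame. ORI given as 0 is normalized to 1
    (the convention of entering "0" for the first base)."""
    if ori == 0:
        ori = 1
    if ter == 0:
        ter = 1
    return ReplicationFrame(
        ori=ori, ter=ter, genome_length=genome_length, circular=circular, source=source
    )


def cumulative_skew(
    genome: Genome,
    annotations: AnnotationSet | None = None,
    site_set: str = "all_sites",
) -> SkewProfile:
    """Cumulative GC skew over all sites or synonymous third-codon sites.

    Contribution at a counted site is +1 for G, -1 for C, 0 for A/T/N,
    accumulated in genome coordinate order. With
    ``site_set='synonymous_third_codon'`` only third codon positions of
    complete (non-partial, length % 3 == 0) CDS are counted; minus-strand
    CDS contribute the complement of the genome base, so the profile always
    reflects the coding strand.
    """
    if site_set not in SITE_SETS:
        raise ConfigurationError(f"unknown site_set {site_set!r}")
    seq = genome.sequence
    if site_set == "all_sites":
        contrib = np.zeros(genome.length, dtype=np.int64)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        contrib[arr == ord("G")] = 1
        contrib[arr == ord("C")] = -1
        positions = np.arange(1, genome.length + 1, dtype=np.int64)
        return SkewProfile(positions=positions, cumulative=np.cumsum(contrib), site_set=site_set)

    if annotations is None:
        raise ConfigurationError("synonymous_third_codon site set requires annotations")
    site_contrib: dict[int, int] = {}
    usable = annotations.cds(complete_only=True)
    if not usable:
        raise ConfigurationError("no complete CDS available for synonymous skew")
    for cds in usable:
        parts = cds.parts or ((cds.start, cds.end),)
        coords: list[int] = []
        for s, e in parts:
            coords.extend(range(s, e + 1))
        if cds.strand == "-":
            coords.reverse()
        # third codon positions in translation order
        for idx in range(2, len(coords), 3):
            pos = coords[idx]
            base = seq[pos - 1]
            if cds.strand == "-":
                base = _COMPLEMENT[base]
            site_contrib[pos] = _SKEW_VALUE.get(base, 0)
    positions = np.array(sorted(site_contrib), dtype=np.int64)
    contrib = np.array([site_contrib[p] for p in positions], dtype=np.int64)
    return SkewProfile(positions=positions, cumulative=np.cumsum(contrib), site_set=site_set)


def detect_ori_ter(
    profile: SkewProfile,
    genome_length: int,
    circular: bool = True,
    leading_strand_g_rich: bool = True,
) -> ReplicationFrame:
    """Place ORI at the cumulative-skew minimum and TER at the maximum.

    The default encodes the leading-strand-G-rich convention; set
    ``leading_strand_g_rich=False`` for genomes with inverted skew. Ties
    are broken toward the smallest coordinate. A flat profile (no G/C
    asymmetry) raises DetectionError with instructions to supply the frame
    manually.
    """
    if len(profile.positions) == 0:
        raise DetectionError("empty skew profile")
    cum = profile.cumulative
    lo, hi = int(cum.min()), int(cum.max())
    if lo == hi:
        raise DetectionError(
            "flat skew profile: cannot locate ORI/TER; supply them manually"
        )
    i_min = int(np.argmax(cum == lo))  # first index attaining the extremum
    i_max = int(np.argmax(cum == hi))
    ori_pos = int(profile.positions[i_min])
    ter_pos = int(profile.positions[i_max])
    if not leading_strand_g_rich:
        ori_pos, ter_pos = ter_pos, ori_pos
    return ReplicationFrame(
        ori=ori_pos,
        ter=ter_pos,
        genome_length=genome_length,
        circular=circular,
        source="skew_extrema",
    )


def assign_replichore(frame: ReplicationFrame, position: int) -> str:
    """Assign a 1-based position to 'right' or 'left'.

    right = half-open arc [ori, ter) in increasing coordinates mod length;
    ori itself is right, ter is left. The modular rule applies identically
    to linear genomes (the arcs still partition every position exactly
    once).
    """
    if not 1 <= position <= frame.genome_length:
        raise DomainError(f"position {position} outside 1..{frame.genome_length}")
    L = frame.genome_length
    offset = (position - frame.ori) % L
    ter_offset = (frame.ter - frame.ori) % L
    return "right" if offset < ter_offset else "left"


def replichore_mask(frame: ReplicationFrame) -> np.ndarray:
    """Vectorized assign_replichore: boolean array over 0-based positions,
    True where the position lies on the right replichore."""
    L = frame.genome_length
    offsets = (np.arange(L, dtype=np.int64) + 1 - frame.ori) % L
    return offsets < (frame.ter - frame.ori) % L


def rotate_to_ori(frame: ReplicationFrame, position: int) -> int:
    """0-based offset of a 1-based position from the ORI (ORI maps to 0)."""
    if not 1 <= position <= frame.genome_length:
        raise DomainError(f"position {position} outside 1..{frame.genome_length}")
    return (position - frame.ori) % frame.genome_length


def position_from_offset(frame: ReplicationFrame, offset: int) -> int:
    """Inverse of rotate_to_ori: 1-based position at a 0-based ORI offset."""
    if not 0 <= offset < frame.genome_length:
        raise DomainError(f"offset {offset} outside 0..{frame.genome_length - 1}")
    return (frame.ori - 1 + offset) % frame.genome_length + 1
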
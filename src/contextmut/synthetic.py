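"""Synthetic genomes, annotations, and planted mutation sets.

Everything the pipeline consumes can be generated here with fully known
ground truth, emulating a bacterial mutation-accumulation (MA) study: a
circular chromosome with optional replication-associated GC skew, a set of
complete CDS features, and mutations planted per (triplet context,
alternative base) at chosen per-site per-generation rates u, with the
number of events in each context drawn Poisson(occurrences · G · N · u) —
the sampling process an MA experiment approximates. An exact-count mode
replaces the Poisson draw for fully deterministic tests.

Every generator stage draws from its own named PRNG substream derived from
(seed, stage name), so adding a stage never perturbs earlier draws and all
outputs are bit-reproducible per seed.

Skewed genomes are built with fully polarized G/C placement inside each
arc at ``skew_strength=1.0`` (the default when skew is requested) and the
four bases flanking the planted switch points pinned (C|G at the origin
boundary, G|C at the terminus boundary), which makes the cumulative-skew
extrema deterministic at the planted coordinates within one site. A
fractional strength produces noisy, more lifelike profiles whose extrema
wander; see docs/methods.md.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .context_counting import key_offsets
from .errors import ParameterError
from .io_formats import (
    AnnotationSet,
    Feature,
    Genome,
    VariantRecord,
    VariantTable,
)
from .replication import ReplicationFrame

BASES = "ACGT"


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, named PRNG substream for one generator stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def generate_genome(
    length: int,
    gc_fraction: float = 0.45,
    circular: bool = True,
    skew: Optional[tuple[int, int, float]] = None,
    seed: int = 0,
    genome_id: str = "synthetic",
) -> tuple[Genome, dict]:
    """i.i.d. random genome, optionally with planted replication skew.

    ``skew`` is (ori_target, ter_target, skew_strength): the arc
    ori→ter (increasing coordinates, mod length) is enriched for G over C
    by ``skew_strength`` in (0, 1] and the complementary arc for C over G,
    so the cumulative GC-skew profile has its minimum near ori_target and
    maximum near ter_target.
    """
    if not 0 < gc_fraction < 1:
        raise ParameterError(f"gc_fraction must be in (0,1), got {gc_fraction}")
    rng = stage_rng(seed, "genome")
    is_gc = rng.random(length) < gc_fraction
    u = rng.random(length)
    at_coin = rng.random(length) < 0.5

    if skew is None:
        p_g = np.full(length, 0.5)
    else:
        ori_t, ter_t, strength = skew
        for name, pos in (("ori_target", ori_t), ("ter_target", ter_t)):
            if not 1 <= pos <= length:
                raise ParameterError(f"{name}={pos} outside 1..{length}")
        if not 0 < strength <= 1:
            raise ParameterError(f"skew_strength must be in (0,1], got {strength}")
        offsets = (np.arange(length) + 1 - ori_t) % length
        right = offsets < (ter_t - ori_t) % length
        p_g = np.where(right, (1 + strength) / 2, (1 - strength) / 2)

    seq_arr = np.where(is_gc, np.where(u < p_g, "G", "C"), np.where(at_coin, "A", "T"))
    if skew is not None:
        ori_t, ter_t, _ = skew
        # pin switch-point flanks so skew extrema are deterministic
        seq_arr[(ori_t - 2) % length] = "C"
        seq_arr[ori_t - 1] = "G"
        seq_arr[(ter_t - 2) % length] = "G"
        seq_arr[ter_t - 1] = "C"
    seq = "".join(seq_arr)
    genome = Genome(id=genome_id, sequence=seq, circular=circular)
    manifest = {
        "seed": seed,
        "length": length,
        "gc_fraction_target": gc_fraction,
        "circular": circular,
        "skew": None if skew is None else {"ori": skew[0], "ter": skew[1], "strength": skew[2]},
        "base_tallies": {b: seq.count(b) for b in BASES},
    }
    return genome, manifest


def write_fasta(genome: Genome, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([rec], str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def generate_annotations(
    genome: Genome,
    n_cds: int,
    seed: int = 0,
    min_len: int = 30,
    max_len: int = 120,
    include_compound: bool = False,
    path=None,
) -> tuple[AnnotationSet, dict]:
    """Place non-overlapping complete CDS (length % 3 == 0, random strand).

    With ``include_compound`` the last CDS becomes a two-exon join().
    Writes a valid GenBank flat file when ``path`` is given.
    """
    rng = stage_rng(seed, "annotations")
    L = genome.length
    lengths = (rng.integers(min_len // 3, max_len // 3 + 1, size=n_cds) * 3).tolist()
    placed: list[tuple[int, int]] = []  # 1-based inclusive, ascending
    features: list[Feature] = []

    def overlaps(s: int, e: int) -> bool:
        return any(not (e < ps or s > pe) for ps, pe in placed)

    for i, cds_len in enumerate(lengths):
        compound = include_compound and i == n_cds - 1
        extra = 9 if compound else 0  # intron gap inside a join()
        span = cds_len + extra
        for _ in range(400):
            start = int(rng.integers(1, L - span + 1))
            end = start + span - 1
            if not overlaps(start, end):
                break
        else:
            raise ParameterError(
                f"could not place {n_cds} non-overlapping CDS on a {L} bp genome"
            )
        placed.append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        if compound:
            exon1 = cds_len // 2 // 3 * 3 or 3
            parts = (
                (start, start + exon1 - 1),
                (start + exon1 + extra, end),
            )
        else:
            parts = ((start, end),)
        features.append(
            Feature(
                start=start,
                end=end,
                strand=strand,
                kind="CDS",
                locus_tag=f"SYN_{i + 1:04d}",
                compound=compound,
                parts=parts,
            )
        )
    features.sort(key=lambda f: f.start)
    annotations = AnnotationSet(features=features)

    codon_tallies: dict[str, int] = {}
    for f in features:
        seq = "".join(genome.sequence[s - 1 : e] for s, e in f.parts)
        if f.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        for j in range(0, len(seq), 3):
            codon = seq[j : j + 3]
            codon_tallies[codon] = codon_tallies.get(codon, 0) + 1

    if path is not None:
        write_genbank(genome, annotations, path)
    manifest = {
        "seed": seed,
        "n_cds": n_cds,
        "cds": [
            {"start": f.start, "end": f.end, "strand": f.strand,
             "locus_tag": f.locus_tag, "parts": list(map(list, f.parts))}
            for f in features
        ],
        "codon_tallies": codon_tallies,
    }
    return annotations, manifest


def write_genbank(genome: Genome, annotations: AnnotationSet, path) -> None:
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.id[:16] or "synthetic",
        name=(genome.id[:16] or "synthetic").replace(" ", "_"),
        description="synthetic fixture chromosome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for f in annotations.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s - 1, e, strand=strand) for s, e in (f.parts or ((f.start, f.end),))]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        rec.features.append(
            SeqFeature(location, type=f.kind if f.kind != "other" else "misc_feature",
                       qualifiers={"locus_tag": [f.locus_tag]})
        )
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Mutation planting
# ---------------------------------------------------------------------------


def triplet_site_index(genome: Genome) -> dict[str, np.ndarray]:
    """1-based positions of every N-free reference triplet window, keyed by
    the triplet, with circular wrap (linear genomes omit the termini)."""
    L = genome.length
    left, right = key_offsets(3)
    seq = genome.sequence
    ext = seq + seq[:2] if genome.circular else seq
    sites: dict[str, list[int]] = {}
    rng_positions = range(L) if genome.circular else range(left, L - right)
    for c in rng_positions:
        if genome.circular:
            w = (seq[c - 1] if c > 0 else seq[-1]) + ext[c] + ext[c + 1]
        else:
            w = seq[c - 1 : c + 2]
        if "N" not in w:
            sites.setdefault(w, []).append(c + 1)
    return {t: np.array(p, dtype=np.int64) for t, p in sites.items()}


def plant_mutations(
    genome: Genome,
    frame: Optional[ReplicationFrame],
    u_true: dict[tuple[str, str], float],
    generations: float,
    lineages: int,
    seed: int = 0,
    exact_counts: Optional[dict[tuple[str, str], int]] = None,
    vcf_path=None,
    basecall_path=None,
) -> tuple[VariantTable, dict]:
    """Plant substitutions per (reference triplet, alt) at rates ``u_true``.

    For each key, the event count is Poisson(occurrences · G · N · u) — or
    the value from ``exact_counts`` when given — and positions are sampled
    uniformly without replacement among the matching reference-strand
    sites. The manifest records the exact planted per-context counts, so a
    rate recomputation downstream can be checked against M/(GWTC·G·N)
    identically.
    """
    for (triplet, alt) in u_true:
        if len(triplet) != 3 or set(triplet) - set(BASES) or alt not in BASES:
            raise ParameterError(f"invalid u_true key ({triplet!r}, {alt!r})")
        if alt == triplet[1]:
            raise ParameterError(f"alt equals ref in u_true key ({triplet}, {alt})")
    rng = stage_rng(seed, "mutations")
    sites = triplet_site_index(genome)
    GN = generations * lineages
    records: list[VariantRecord] = []
    planted_counts: dict[str, int] = {}
    for (triplet, alt) in sorted(u_true):
        positions = sites.get(triplet, np.array([], dtype=np.int64))
        occ = len(positions)
        if exact_counts is not None:
            n = int(exact_counts.get((triplet, alt), 0))
        else:
            n = int(rng.poisson(occ * GN * u_true[(triplet, alt)]))
        if n > occ:
            raise ParameterError(
                f"context {triplet}: demanded {n} mutations but only {occ} sites"
            )
        if n == 0:
            planted_counts[f"{triplet}>{alt}"] = 0
            continue
        chosen = rng.choice(positions, size=n, replace=False)
        for pos in sorted(int(p) for p in chosen):
            records.append(VariantRecord(position=pos, ref=triplet[1], alt=alt))
        planted_counts[f"{triplet}>{alt}"] = n
    records.sort(key=lambda r: (r.position, r.alt))
    records = [
        VariantRecord(position=r.position, ref=r.ref, alt=r.alt, source_line=i + 1)
        for i, r in enumerate(records)
    ]
    table = VariantTable(records=records)
    if vcf_path is not None:
        write_vcf(table, genome, vcf_path)
    if basecall_path is not None:
        write_basecall(table, basecall_path)
    manifest = {
        "seed": seed,
        "generations": generations,
        "lineages": lineages,
        "u_true": {f"{t}>{a}": u for (t, a), u in sorted(u_true.items())},
        "planted_counts": planted_counts,
        "n_total": len(records),
        "triplet_occurrences": {t: int(len(p)) for t, p in sorted(sites.items())},
    }
    return table, manifest


def write_vcf(table: VariantTable, genome: Genome, path) -> None:
    """Minimal VCF 4.2 with a contig header (readable by standard VCF
    parsers)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.id},length={genome.length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in table.records:
            fh.write(
                f"{genome.id}\t{rec.position}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\n"
            )


def write_basecall(table: VariantTable, path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("position,ref,alt\n")
        for rec in table.records:
            fh.write(f"{rec.position},{rec.ref},{rec.alt}\n")


def uniform_rate_map(u: float, contexts: Optional[Sequence[str]] = None) -> dict[tuple[str, str], float]:
    """Convenience: the same rate u for every (triplet, alt) pair (or a
    subset of triplets)."""
    triplets = contexts or [a + b + c for a in BASES for b in BASES for c in BASES]
    return {
        (t, alt): u for t in triplets for alt in BASES if alt != t[1]
    }


def random_rate_map(
    mean_rate: float, seed: int = 0, dispersion: float = 1.0
) -> dict[tuple[str, str], float]:
    """Lognormal-ish heterogeneous rate map around ``mean_rate`` — gives
    spectra with genuine context structure for correlation tests."""
    rng = stage_rng(seed, "rate_map")
    out: dict[tuple[str, str], float] = {}
    for t in (a + b + c for a in BASES for b in BASES for c in BASES):
        for alt in BASES:
            if alt == t[1]:
                continue
            out[(t, alt)] = float(mean_rate * rng.lognormal(0.0, dispersion))
    return out
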
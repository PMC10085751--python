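"""Readers and writers for the pipeline's external formats.

All file-facing coordinates are 1-based inclusive (VCF/GenBank convention).
Internal modules work 0-based half-open; the conversion happens here and in
the domain types' accessors, nowhere else.

FASTA and GenBank parsing is delegated to Biopython, VCF parsing to pysam;
the base-call CSV dialect (``position,ref,alt[,lineage]``) and all output
CSVs are handled with the standard-library ``csv`` module so that the
round-trip guarantee (write → read reproduces the in-memory table exactly)
is under this module's control.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.SeqFeature import AfterPosition, BeforePosition

from .errors import ConfigurationError, FormatError

VALID_BASES = frozenset("ACGTN")
SNV_BASES = frozenset("ACGT")

SCALING_MODES = ("default_1e-8", "mean_scaled", "custom")

#: Fixed column order of every substitution-type breakdown written to CSV.
SUBSTITUTION_TYPES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Genome:
    """A single chromosome with a circularity flag.

    ``sequence`` is uppercase over {A,C,G,T,N}; ``length`` always equals
    ``len(sequence)``.
    """

    id: str
    sequence: str
    circular: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]

    def __post_init__(self):
        if len(self.sequence) < 3:
            raise FormatError("genome shorter than 3 bases")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(f"illegal characters in genome: {sorted(bad)}")


@dataclass(frozen=True)
class Feature:
    """A GenBank feature with 1-based inclusive coordinates.

    ``parts`` carries the exon segments of join() locations in ascending
    order; for simple locations it holds the single (start, end) pair.
    """

    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str  # "CDS", "gene", "other"
    locus_tag: str = ""
    partial: bool = False
    compound: bool = False
    parts: tuple[tuple[int, int], ...] = ()

    @property
    def span_length(self) -> int:
        parts = self.parts or ((self.start, self.end),)
        return sum(e - s + 1 for s, e in parts)

    @property
    def is_complete_cds(self) -> bool:
        """Usable in codon / synonymous-site analyses."""
        return self.kind == "CDS" and not self.partial and self.span_length % 3 == 0


@dataclass
class AnnotationSet:
    features: list[Feature] = field(default_factory=list)

    def cds(self, complete_only: bool = False) -> list[Feature]:
        out = [f for f in self.features if f.kind == "CDS"]
        if complete_only:
            out = [f for f in out if f.is_complete_cds]
        return out


@dataclass(frozen=True)
class VariantRecord:
    position: int  # 1-based
    ref: str
    alt: str
    lineage: Optional[str] = None
    source_line: int = 0


@dataclass
class VariantTable:
    records: list[VariantRecord] = field(default_factory=list)
    exclusion_log: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusion_log)

    @property
    def n_candidates(self) -> int:
        return len(self.records) + self.n_excluded


@dataclass(frozen=True)
class RunParameters:
    """Experiment-scale parameters of a mutation-accumulation run.

    generations
        G, generations elapsed per lineage (estimated for non-MA data).
    lineages
        N, number of independent MA lines.
    scaling_mode
        How rates are rescaled for display: ``default_1e-8`` divides by
        1e-8, ``mean_scaled`` by the mean of non-missing rates, ``custom``
        by ``custom_factor``. Unscaled rates are always retained.
    """

    generations: float
    lineages: int
    scaling_mode: str = "default_1e-8"
    custom_factor: Optional[float] = None
    ori_override: Optional[int] = None
    ter_override: Optional[int] = None

    def __post_init__(self):
        if self.generations <= 0:
            raise ConfigurationError("generations must be positive")
        if self.lineages < 1:
            raise ConfigurationError("lineages must be >= 1")
        if self.scaling_mode not in SCALING_MODES:
            raise ConfigurationError(f"unknown scaling mode {self.scaling_mode!r}")
        if self.scaling_mode == "custom":
            if self.custom_factor is None or self.custom_factor <= 0:
                raise ConfigurationError("custom scaling requires a positive custom_factor")
        elif self.custom_factor is not None:
            raise ConfigurationError("custom_factor only valid with scaling_mode='custom'")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_fasta(path, circular: bool = True) -> Genome:
    """Read the first record of a FASTA file as an uppercased Genome.

    Multi-record files emit a warning and use record 1 (multi-chromosome
    joint analysis is out of scope: one chromosome per run).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} records; using the first ({records[0].id})",
            stacklevel=2,
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise FormatError(f"{path}: empty sequence")
    bad = set(seq) - VALID_BASES
    if bad:
        pos = min(seq.index(b) for b in bad) + 1
        raise FormatError(f"{path}: illegal character {seq[pos - 1]!r} at position {pos}")
    return Genome(id=rec.id, sequence=seq, circular=circular)


def read_genbank(path) -> AnnotationSet:
    """Parse CDS/gene features from a GenBank flat file.

    join()/complement() locations are resolved; partial (``<``/``>``)
    locations are flagged ``partial`` and thereby excluded from codon
    analyses downstream.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise FormatError(f"{path}: not parseable as GenBank ({exc})") from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records found")
    rec = records[0]
    if not rec.features:
        raise FormatError(f"{path}: missing FEATURES table")
    length = len(rec.seq)
    feats: list[Feature] = []
    for f in rec.features:
        if f.type == "source":
            continue
        kind = f.type if f.type in ("CDS", "gene") else "other"
        loc = f.location
        if loc is None:
            continue
        parts = tuple(sorted((int(p.start) + 1, int(p.end)) for p in loc.parts))
        start, end = parts[0][0], parts[-1][1]
        if length and end > length:
            raise FormatError(
                f"{path}: feature end {end} beyond LOCUS length {length}"
            )
        partial = any(
            isinstance(p.start, BeforePosition) or isinstance(p.end, AfterPosition)
            for p in loc.parts
        )
        locus = f.qualifiers.get("locus_tag", [""])[0]
        feats.append(
            Feature(
                start=start,
                end=end,
                strand="-" if loc.strand == -1 else "+",
                kind=kind,
                locus_tag=locus,
                partial=partial,
                compound=len(parts) > 1,
                parts=parts,
            )
        )
    return AnnotationSet(features=feats)


def _classify_candidate(
    position: int,
    ref: str,
    alt: str,
    genome: Optional[Genome],
    line: int,
    lineage: Optional[str],
):
    """Return a VariantRecord or an (line, reason) exclusion tuple."""
    if len(ref) != 1 or len(alt) != 1:
        return line, "not a SNV"
    ref, alt = ref.upper(), alt.upper()
    if ref not in SNV_BASES or alt not in SNV_BASES:
        return line, f"non-ACGT allele {ref}>{alt}"
    if ref == alt:
        return line, "ref equals alt"
    if genome is not None:
        if not 1 <= position <= genome.length:
            return line, f"position {position} out of range 1..{genome.length}"
        gbase = genome.base(position)
        if gbase != ref:
            return line, f"reference mismatch: genome has {gbase} at {position}, file says {ref}"
    elif position < 1:
        return line, f"position {position} out of range"
    return VariantRecord(position=position, ref=ref, alt=alt, lineage=lineage, source_line=line)


def _iter_vcf_candidates(path: Path) -> Iterator[tuple[int, str, str, Optional[str], int]]:
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not parseable as VCF ({exc})") from exc
    with vf:
        for i, rec in enumerate(vf, start=1):
            alts = rec.alts or ()
            for alt in alts:
                yield rec.pos, rec.ref or "", alt or "", None, i


def _iter_basecall_candidates(path: Path) -> Iterator[tuple[int, str, str, Optional[str], int]]:
    with open(path, newline="") as fh:
        first = fh.readline()
        if first.startswith("##fileformat=VCF") or first.startswith("#CHROM"):
            raise FormatError(f"{path}: looks like VCF, not a base-call CSV")
        fh.seek(0)
        reader = csv.reader(fh)
        for i, row in enumerate(reader, start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            cells = [c.strip() for c in row]
            if i == 1 and not cells[0].lstrip("-").isdigit():
                continue  # header row, detected by non-numeric first field
            if len(cells) < 3:
                raise FormatError(f"{path} line {i}: expected position,ref,alt")
            try:
                pos = int(cells[0])
            except ValueError as exc:
                raise FormatError(f"{path} line {i}: bad position {cells[0]!r}") from exc
            lineage = cells[3] if len(cells) > 3 and cells[3] else None
            yield pos, cells[1], cells[2], lineage, i


def read_variants(path, dialect: str, genome: Optional[Genome] = None) -> VariantTable:
    """Load SNVs from a VCF or base-call CSV into a VariantTable.

    Only single-nucleotide substitutions are retained; anything else
    (indels, symbolic alleles, ref==alt, reference mismatches against
    ``genome``, out-of-range positions) lands in ``exclusion_log`` with a
    reason. Multi-allelic VCF ALT fields are split into one candidate per
    alt, so retained + excluded always equals the candidate count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"variant file not found: {path}")
    if dialect == "vcf":
        candidates = _iter_vcf_candidates(path)
    elif dialect == "basecall":
        candidates = _iter_basecall_candidates(path)
    else:
        raise ConfigurationError(f"unknown variant dialect {dialect!r}")
    table = VariantTable()
    for pos, ref, alt, lineage, line in candidates:
        result = _classify_candidate(pos, ref, alt, genome, line, lineage)
        if isinstance(result, VariantRecord):
            table.records.append(result)
        else:
            table.exclusion_log.append(result)
    return table


# ---------------------------------------------------------------------------
# CSV / JSON writers and their matching readers (round-trip exact)
# ---------------------------------------------------------------------------


def _fmt_float(x: Optional[float]) -> str:
    return "" if x is None else repr(float(x))


def _parse_float(s: str) -> Optional[float]:
    return None if s == "" else float(s)


def write_counts_csv(table, path) -> None:
    """Write a ContextCountTable as ``context,count`` with a metadata line."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# k={table.k},region={table.region},strand={table.strand},"
            f"n_skipped={table.n_skipped}\n"
        )
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["context", "count"])
        for ctx in sorted(table.counts):
            w.writerow([ctx, table.counts[ctx]])


def read_counts_csv(path):
    from .context_counting import ContextCountTable

    path = Path(path)
    with open(path, newline="") as fh:
        meta_line = fh.readline().strip()
        if not meta_line.startswith("# "):
            raise FormatError(f"{path}: missing metadata line")
        meta = dict(kv.split("=", 1) for kv in meta_line[2:].split(","))
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["context", "count"]:
            raise FormatError(f"{path}: unexpected header {header}")
        counts = {row[0]: int(row[1]) for row in reader if row}
    return ContextCountTable(
        k=int(meta["k"]),
        region=meta["region"],
        strand=meta["strand"],
        counts=counts,
        n_skipped=int(meta["n_skipped"]),
    )


RATES_COLUMNS = ["up", "ref", "alt", "down", "region", "M", "denominator", "rate", "scaled_rate"]


def write_rates_csv(matrix, path) -> None:
    """Write a ContextRateMatrix: 192 data rows, fixed column order.

    Missing rates (denominator 0) are written as empty fields, never 0,
    so "unobservable" and "observed none" stay distinguishable on disk.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# region={matrix.region},convention={matrix.strand_convention},"
            f"G={_fmt_float(matrix.generations)},N={matrix.lineages},"
            f"scale={_fmt_float(matrix.scale_applied)}\n"
        )
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(RATES_COLUMNS)
        for key in matrix.canonical_keys():
            e = matrix.entries[key]
            up, ref, alt, down = key
            w.writerow(
                [up, ref, alt, down, matrix.region, e.M, e.denominator,
                 _fmt_float(e.rate), _fmt_float(e.scaled)]
            )


def read_rates_csv(path):
    from .rate_engine import ContextRateMatrix, RateEntry

    path = Path(path)
    with open(path, newline="") as fh:
        meta_line = fh.readline().strip()
        if not meta_line.startswith("# "):
            raise FormatError(f"{path}: missing metadata line")
        meta = dict(kv.split("=", 1) for kv in meta_line[2:].split(","))
        reader = csv.reader(fh)
        header = next(reader)
        if header != RATES_COLUMNS:
            raise FormatError(f"{path}: unexpected header {header}")
        entries = {}
        region = meta["region"]
        for row in reader:
            if not row:
                continue
            up, ref, alt, down = row[0], row[1], row[2], row[3]
            entries[(up, ref, alt, down)] = RateEntry(
                M=int(row[5]),
                denominator=int(row[6]),
                rate=_parse_float(row[7]),
                scaled=_parse_float(row[8]),
            )
    return ContextRateMatrix(
        entries=entries,
        region=region,
        strand_convention=meta["convention"],
        generations=float(meta["G"]),
        lineages=int(meta["N"]),
        scale_applied=_parse_float(meta["scale"]),
    )


def write_bins_csv(table, path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# n_bins={table.n_bins},genome_length={table.genome_length}\n")
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            ["bin", "start_offset", "end_offset", "mutation_count", "mutation_rate_per_site"]
            + list(SUBSTITUTION_TYPES)
        )
        for b in table.bins:
            w.writerow(
                [b.index, b.start_offset, b.end_offset, b.mutation_count,
                 _fmt_float(b.mutation_rate_per_site)]
                + [b.type_breakdown.get(t, 0) for t in SUBSTITUTION_TYPES]
            )


def read_bins_csv(path):
    from .binning_export import Bin, BinTable

    path = Path(path)
    with open(path, newline="") as fh:
        meta_line = fh.readline().strip()
        meta = dict(kv.split("=", 1) for kv in meta_line[2:].split(","))
        reader = csv.reader(fh)
        header = next(reader)
        bins = []
        for row in reader:
            if not row:
                continue
            breakdown = {
                t: int(v) for t, v in zip(SUBSTITUTION_TYPES, row[5:]) if int(v) > 0
            }
            bins.append(
                Bin(
                    index=int(row[0]),
                    start_offset=int(row[1]),
                    end_offset=int(row[2]),
                    mutation_count=int(row[3]),
                    mutation_rate_per_site=_parse_float(row[4]),
                    type_breakdown=breakdown,
                )
            )
    return BinTable(
        n_bins=int(meta["n_bins"]), genome_length=int(meta["genome_length"]), bins=bins
    )


def write_codon_csv(table, path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# region={table.region}\n")
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["codon", "count"])
        for codon in sorted(table.counts):
            w.writerow([codon, table.counts[codon]])


def read_codon_csv(path):
    from .context_counting import CodonUsageTable

    path = Path(path)
    with open(path, newline="") as fh:
        meta_line = fh.readline().strip()
        meta = dict(kv.split("=", 1) for kv in meta_line[2:].split(","))
        reader = csv.reader(fh)
        next(reader)  # header
        counts = {row[0]: int(row[1]) for row in reader if row}
    return CodonUsageTable(region=meta["region"], counts=counts)


def write_skew_csv(profile, path) -> None:
    """Two-column (position, cumulative) skew profile for plotting."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["position", "cumulative"])
        for pos, cum in zip(profile.positions, profile.cumulative):
            w.writerow([int(pos), int(cum)])


_RUN_ID_RE = re.compile(r"^[A-Za-z0-9._-]+$")

OUTPUT_SUBDIRS = ("counts", "rates", "correlation", "bins", "figures")


def prepare_run_directory(out_root, run_id: str, overwrite: bool = False) -> Path:
    """Create ``<out_root>/<run_id>/{counts,rates,correlation,bins,figures}``.

    Refuses an existing run_id unless ``overwrite`` is set.
    """
    if not _RUN_ID_RE.match(run_id):
        raise ConfigurationError(f"run_id {run_id!r} is not filesystem-safe")
    run_dir = Path(out_root) / run_id
    if run_dir.exists():
        if not overwrite:
            raise FileExistsError(
                f"run directory {run_dir} exists; pass overwrite=True to replace"
            )
    run_dir.mkdir(parents=True, exist_ok=True)
    for sub in OUTPUT_SUBDIRS:
        (run_dir / sub).mkdir(exist_ok=True)
    return run_dir


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
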
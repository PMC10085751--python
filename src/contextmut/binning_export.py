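"""ORI-anchored spatial binning of mutations and JSON export.

For circular display, every mutation is rotated to its 0-based offset from
the replication origin and dropped into one of n equal bins (bin 1 starts
at the ORI). Bin width is the real value L/n with floor indexing — no
remainder bin — so with 25 bins on a chromosome whose terminus sits at
exactly L/2 the terminus lands in bin 13. Integer bin boundaries are
ceil(i·L/n), which tile [0, L) exactly and agree with the floor rule for
every integer offset.

The JSON export bundles one or more runs (bins, triplet rates, conditional
rates) into a frozen, versioned schema with deterministic key order, for
consumption by external circular-genome viewers.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ConfigurationError, DomainError
from .io_formats import RunParameters, VariantTable, write_json
from .replication import ReplicationFrame, rotate_to_ori

SCHEMA_VERSION = "1.0"
STANDARD_BIN_COUNTS = (25, 50, 75)


@dataclass
class Bin:
    index: int  # 1-based
    start_offset: int  # 0-based half-open offsets from ORI
    end_offset: int
    mutation_count: int = 0
    mutation_rate_per_site: Optional[float] = None
    type_breakdown: dict[str, int] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.end_offset - self.start_offset


@dataclass
class BinTable:
    n_bins: int
    genome_length: int
    bins: list[Bin] = field(default_factory=list)

    @property
    def total_mutations(self) -> int:
        return sum(b.mutation_count for b in self.bins)


def bin_index(offset: int, genome_length: int, n_bins: int) -> int:
    """1-based bin of a 0-based ORI offset under real-valued width L/n."""
    if not 0 <= offset < genome_length:
        raise DomainError(f"offset {offset} outside 0..{genome_length - 1}")
    idx = int(offset * n_bins // genome_length) + 1  # == floor(offset/(L/n)) + 1
    return min(idx, n_bins)


def bin_boundaries(genome_length: int, n_bins: int) -> list[tuple[int, int]]:
    """Integer half-open [start, end) offsets tiling [0, L) with widths
    differing by at most one base."""
    edges = [math.ceil(i * genome_length / n_bins) for i in range(n_bins + 1)]
    return [(edges[i], edges[i + 1]) for i in range(n_bins)]


def bin_mutations(
    variants: VariantTable,
    frame: ReplicationFrame,
    n_bins: int,
    params: RunParameters,
) -> BinTable:
    """Map each retained variant to its ORI-offset bin and tally density
    and substitution-type breakdown per bin."""
    L = frame.genome_length
    if n_bins < 1 or n_bins > L:
        raise DomainError(f"n_bins={n_bins} infeasible for genome length {L}")
    if n_bins not in STANDARD_BIN_COUNTS:
        warnings.warn(
            f"n_bins={n_bins} is nonstandard (usual choices: {STANDARD_BIN_COUNTS})",
            stacklevel=2,
        )
    GN = params.generations * params.lineages
    bins = [
        Bin(index=i + 1, start_offset=s, end_offset=e)
        for i, (s, e) in enumerate(bin_boundaries(L, n_bins))
    ]
    for rec in variants.records:
        offset = rotate_to_ori(frame, rec.position)
        b = bins[bin_index(offset, L, n_bins) - 1]
        b.mutation_count += 1
        key = f"{rec.ref}>{rec.alt}"
        b.type_breakdown[key] = b.type_breakdown.get(key, 0) + 1
    for b in bins:
        b.mutation_rate_per_site = b.mutation_count / (b.width * GN)
    return BinTable(n_bins=n_bins, genome_length=L, bins=bins)


def _bin_payload(b: Bin) -> dict:
    return {
        "index": b.index,
        "start_offset": b.start_offset,
        "end_offset": b.end_offset,
        "mutation_count": b.mutation_count,
        "mutation_rate_per_site": b.mutation_rate_per_site,
        "type_breakdown": dict(sorted(b.type_breakdown.items())),
    }


def build_viz_document(runs: Sequence[dict]) -> dict:
    """Assemble the multi-organism visualization document.

    Each run is a mapping with keys: run_id, frame (ReplicationFrame),
    bin_table (BinTable), triplet_rates (64-key mapping), and
    conditional_rates (64-key mapping). All runs must share n_bins so
    stacked circular tracks align.
    """
    if not runs:
        raise ConfigurationError("need at least one run to export")
    n_bins_set = {r["bin_table"].n_bins for r in runs}
    if len(n_bins_set) > 1:
        raise ConfigurationError(
            f"mixed bin counts across runs: {sorted(n_bins_set)}; bins must align"
        )
    organisms = []
    for r in runs:
        frame: ReplicationFrame = r["frame"]
        bt: BinTable = r["bin_table"]
        organisms.append(
            {
                "id": r["run_id"],
                "genome_length": frame.genome_length,
                "ori": frame.ori,
                "ter": frame.ter,
                "n_bins": bt.n_bins,
                "bins": [_bin_payload(b) for b in bt.bins],
                "triplet_rates": dict(sorted(r["triplet_rates"].items())),
                "conditional_rates": dict(sorted(r["conditional_rates"].items())),
            }
        )
    return {"schema_version": SCHEMA_VERSION, "organisms": organisms}


def export_viz_json(runs: Sequence[dict], path) -> dict:
    """Validate, assemble, and write the visualization JSON; returns the
    document. Writing is deterministic (sorted keys), so write→read→write
    is byte-identical."""
    doc = build_viz_document(runs)
    write_json(doc, path)
    return doc


def read_viz_json(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ConfigurationError(
            f"unsupported schema version {doc.get('schema_version')!r}"
        )
    for org in doc.get("organisms", []):
        total = sum(b["mutation_count"] for b in org["bins"])
        if len(org["bins"]) != org["n_bins"]:
            raise ConfigurationError(f"organism {org['id']}: bin count mismatch")
        org["_total_mutations"] = total
    return doc
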
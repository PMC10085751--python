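"""Cross-organism comparison of context-dependent mutation spectra.

Each completed single-organism run is summarized as an ordered 192-vector
of unscaled rates (canonical lexicographic key order) plus its GC content.
Comparisons are one-to-many Pearson correlations on pairwise-complete
entries, and the resulting matrix is displayed AT-rich → GC-rich along
rows and GC-rich → AT-rich along columns, which makes GC-driven blocks of
similar spectra visually contiguous.

Correlations are always computed on unscaled rates, so display scaling can
never change them. Pearson on raw (not log) rates is the default; a log10
option exists for heavy-tailed spectra but is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .context_counting import BASES
from .errors import ConfigurationError
from .io_formats import AnnotationSet, Genome


@dataclass
class OrganismRunSummary:
    run_id: str
    gc_content_coding: float
    gc_content_genome: float
    rate_vector: np.ndarray  # 192 unscaled rates, NaN = missing
    basis: str = "chromosome"  # chromosome | strand | replichore tag
    strand_convention: str = "as_reference"

    def __post_init__(self):
        self.rate_vector = np.asarray(self.rate_vector, dtype=float)
        if self.rate_vector.shape != (192,):
            raise ConfigurationError(
                f"rate vector must have length 192, got {self.rate_vector.shape}"
            )


@dataclass
class CorrelationTable:
    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    n_complete: dict[tuple[str, str], int] = field(default_factory=dict)
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)


def genome_gc(genome: Genome) -> float:
    seq = genome.sequence
    acgt = sum(seq.count(b) for b in BASES)
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def coding_gc(genome: Genome, annotations: AnnotationSet) -> float:
    """GC fraction over the union of CDS spans (strand-invariant).

    Falls back to genome-wide GC with a warning when no CDS exist."""
    covered: set[int] = set()
    for cds in annotations.cds():
        for s, e in cds.parts or ((cds.start, cds.end),):
            covered.update(range(s, e + 1))
    if not covered:
        warnings.warn("no CDS features; falling back to genome-wide GC", stacklevel=2)
        return genome_gc(genome)
    tallies = {b: 0 for b in "ACGTN"}
    seq = genome.sequence
    for pos in covered:
        tallies[seq[pos - 1]] += 1
    acgt = sum(tallies[b] for b in BASES)
    return (tallies["G"] + tallies["C"]) / acgt if acgt else float("nan")


def _pair_r(a: np.ndarray, b: np.ndarray, log10: bool) -> tuple[float, int]:
    mask = np.isfinite(a) & np.isfinite(b)
    if log10:
        mask &= (a > 0) & (b > 0)
    n = int(mask.sum())
    if n < 3:
        return float("nan"), n
    x, y = a[mask], b[mask]
    if log10:
        x, y = np.log10(x), np.log10(y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant rate vector; correlation undefined", stacklevel=3)
        return float("nan"), n
    r = stats.pearsonr(x, y).statistic
    return float(r), n


def one_to_many_correlation(
    focal: OrganismRunSummary,
    others: Sequence[OrganismRunSummary],
    log10: bool = False,
) -> CorrelationTable:
    """Pearson r of the focal run against itself and each other run.

    Entries missing in either vector are dropped pairwise; pairs with
    fewer than 3 complete entries, or a constant vector, get a missing r.
    Both (focal, other) and (other, focal) keys are populated (r is
    symmetric)."""
    if not others:
        raise ConfigurationError("need at least one other run to correlate against")
    for o in others:
        if o.basis != focal.basis:
            raise ConfigurationError(
                f"basis mismatch: {focal.run_id}={focal.basis!r} vs {o.run_id}={o.basis!r}"
            )
    table = CorrelationTable()
    ids = [focal.run_id] + [o.run_id for o in others if o.run_id != focal.run_id]
    table.row_order = list(ids)
    table.col_order = list(ids)
    for other in [focal, *others]:
        r, n = _pair_r(focal.rate_vector, other.rate_vector, log10)
        for key in ((focal.run_id, other.run_id), (other.run_id, focal.run_id)):
            table.pairs[key] = r
            table.n_complete[key] = n
    return table


def all_pairs_correlation(
    summaries: Sequence[OrganismRunSummary], log10: bool = False
) -> CorrelationTable:
    """Full correlation table: one-to-many applied sequentially with each
    run as the focal organism."""
    if len(summaries) < 2:
        raise ConfigurationError("need at least 2 runs for multi-organism analysis")
    table = CorrelationTable()
    ids = [s.run_id for s in summaries]
    table.row_order = list(ids)
    table.col_order = list(ids)
    for i, focal in enumerate(summaries):
        sub = one_to_many_correlation(focal, summaries, log10=log10)
        table.pairs.update(sub.pairs)
        table.n_complete.update(sub.n_complete)
    return table


def order_by_gc(
    table: CorrelationTable, summaries: Sequence[OrganismRunSummary]
) -> CorrelationTable:
    """Sort rows AT-rich → GC-rich (ascending coding GC) and columns
    GC-rich → AT-rich (descending), ties broken by run_id."""
    gc = {s.run_id: s.gc_content_coding for s in summaries}
    missing = [rid for rid in table.row_order if rid not in gc]
    if missing:
        raise ConfigurationError(f"GC content unknown for runs: {missing}")
    rows = sorted(table.row_order, key=lambda rid: (gc[rid], rid))
    cols = sorted(table.col_order, key=lambda rid: (-gc[rid], rid))
    return CorrelationTable(
        pairs=dict(table.pairs),
        n_complete=dict(table.n_complete),
        row_order=rows,
        col_order=cols,
    )
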
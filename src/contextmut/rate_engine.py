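"""Context-dependent base-substitution mutation rates.

The central estimator of the package. For a triplet context u·X·d (5'
neighbor u, mutable base X, 3' neighbor d) and alternative base a, the
per-site per-generation rate in a mutation-accumulation design is

    rate(u, X→a, d) = M / (C · G · N)

where M is the number of observed X→a substitutions in that context within
the region, C the occurrence count of the triplet u·X·d in the region
(genome-wide GWTC or replichore-wide RWTC, on the strand matching the
orientation convention), G the generations elapsed per lineage and N the
number of lineages. The 192-entry (4 up × 4 ref × 3 alt × 4 down) matrix
is the canonical store; the 64-triplet view is an aggregation over alts.

Missing vs zero: a context absent from the region (denominator 0) has a
*missing* rate, while M=0 with a positive denominator is a true observed
zero. An entry with denominator 0 but M>0 is flagged inconsistent (it
means the variant orientation and the count table disagree) and the run
continues with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .context_counting import BASES, ContextCountTable, ContextualVariant
from .errors import ConfigurationError, ScalingError
from .io_formats import RunParameters

#: Canonical key order: lexicographic over (up, ref, alt, down), alt != ref.
CANONICAL_KEYS: tuple[tuple[str, str, str, str], ...] = tuple(
    (u, r, a, d)
    for u in BASES
    for r in BASES
    for a in BASES
    if a != r
    for d in BASES
)

TRIPLETS: tuple[str, ...] = tuple(u + r + d for u in BASES for r in BASES for d in BASES)


@dataclass
class RateEntry:
    M: int = 0
    denominator: int = 0
    rate: Optional[float] = None  # None = missing (unobservable), never 0
    scaled: Optional[float] = None
    inconsistent: bool = False


@dataclass
class ContextRateMatrix:
    """Per-(5' base, ref→alt, 3' base) mutation counts and rates for one
    region under one strand convention."""

    entries: dict[tuple[str, str, str, str], RateEntry]
    region: str
    strand_convention: str
    generations: float
    lineages: int
    scale_applied: Optional[float] = None

    @staticmethod
    def canonical_keys() -> tuple[tuple[str, str, str, str], ...]:
        return CANONICAL_KEYS

    @property
    def total_mutations(self) -> int:
        return sum(e.M for e in self.entries.values())

    def rate_vector(self) -> np.ndarray:
        """192-vector of unscaled rates in canonical key order; NaN where
        missing. This is the object cross-organism correlations run on."""
        return np.array(
            [
                np.nan if self.entries[k].rate is None else self.entries[k].rate
                for k in CANONICAL_KEYS
            ]
        )


def compute_rates(
    variants: Sequence[ContextualVariant],
    counts: ContextCountTable,
    params: RunParameters,
    region: str,
    strand_convention: str = "as_reference",
) -> ContextRateMatrix:
    """Tally oriented variants per (up, ref→alt, down) and divide by the
    matching triplet counts and G·N.

    ``variants`` must already be filtered to ``region`` and oriented under
    the same strand convention as ``counts`` (the caller wires e.g. right
    replichore + lagging-template orientation to the right-replichore
    complement-strand count table).
    """
    if counts.k != 3:
        raise ConfigurationError(f"rate denominators need k=3 counts, got k={counts.k}")
    if counts.region != region:
        raise ConfigurationError(
            f"count table region {counts.region!r} does not match {region!r}"
        )
    G, N = params.generations, params.lineages
    tallies: dict[tuple[str, str, str, str], int] = {}
    for v in variants:
        key = (v.oriented_triplet[0], v.oriented_ref, v.oriented_alt, v.oriented_triplet[2])
        tallies[key] = tallies.get(key, 0) + 1
    entries: dict[tuple[str, str, str, str], RateEntry] = {}
    n_inconsistent = 0
    for key in CANONICAL_KEYS:
        up, ref, alt, down = key
        M = tallies.get(key, 0)
        denom = counts.counts.get(up + ref + down, 0)
        if denom > 0:
            entry = RateEntry(M=M, denominator=denom, rate=M / (denom * G * N))
        elif M > 0:
            entry = RateEntry(M=M, denominator=0, rate=None, inconsistent=True)
            n_inconsistent += 1
        else:
            entry = RateEntry(M=0, denominator=0, rate=None)
        entries[key] = entry
    if n_inconsistent:
        warnings.warn(
            f"{n_inconsistent} context(s) have mutations but a zero denominator; "
            "flagged inconsistent",
            stacklevel=2,
        )
    return ContextRateMatrix(
        entries=entries,
        region=region,
        strand_convention=strand_convention,
        generations=G,
        lineages=N,
    )


def aggregate_to_triplets(
    matrix: ContextRateMatrix,
) -> dict[str, tuple[int, Optional[float]]]:
    """Collapse the 192 entries to the 64 triplets: sum of M and of
    non-missing rates over the 3 alternative bases. A triplet whose three
    entries are all missing gets a missing rate."""
    out: dict[str, tuple[int, Optional[float]]] = {}
    for t in TRIPLETS:
        up, ref, down = t[0], t[1], t[2]
        m_total = 0
        rate_total: Optional[float] = None
        for alt in BASES:
            if alt == ref:
                continue
            e = matrix.entries[(up, ref, alt, down)]
            m_total += e.M
            if e.rate is not None:
                rate_total = (rate_total or 0.0) + e.rate
        out[t] = (m_total, rate_total)
    return out


def conditional_rates(
    matrix: ContextRateMatrix,
    genome_base_counts: dict[str, int],
) -> dict[str, Optional[float]]:
    """Rate per occurrence of the mutable (center) nucleotide.

    conditional(t) = M_total(t) / (count of center base of t · G · N),
    normalizing each triplet's mutation load to genome-wide nucleotide
    content rather than triplet content; missing where the center base is
    absent."""
    G, N = matrix.generations, matrix.lineages
    agg = aggregate_to_triplets(matrix)
    out: dict[str, Optional[float]] = {}
    for t, (m_total, _) in agg.items():
        center_count = genome_base_counts.get(t[1], 0)
        out[t] = None if center_count == 0 else m_total / (center_count * G * N)
    return out


def apply_scaling(matrix: ContextRateMatrix, params: RunParameters) -> ContextRateMatrix:
    """Fill each entry's scaled display value per the run's scaling mode.

    default_1e-8 divides by 1e-8 (so a rate of 3e-8 displays as 3.0);
    mean_scaled divides by the mean of non-missing rates; custom divides
    by ``params.custom_factor``. Unscaled rates are untouched and remain
    the basis of all statistics.
    """
    mode = params.scaling_mode
    if mode == "default_1e-8":
        factor = 1e-8
    elif mode == "custom":
        factor = params.custom_factor
    elif mode == "mean_scaled":
        rates = [e.rate for e in matrix.entries.values() if e.rate is not None]
        if not rates or float(np.mean(rates)) == 0.0:
            raise ScalingError("mean of rates is zero; cannot mean-scale")
        factor = float(np.mean(rates))
    else:  # pragma: no cover - RunParameters already validates
        raise ScalingError(f"unknown scaling mode {mode!r}")
    entries = {
        k: replace(e, scaled=None if e.rate is None else e.rate / factor)
        for k, e in matrix.entries.items()
    }
    return ContextRateMatrix(
        entries=entries,
        region=matrix.region,
        strand_convention=matrix.strand_convention,
        generations=matrix.generations,
        lineages=matrix.lineages,
        scale_applied=factor,
    )
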
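"""Static figures: rate heatmaps, correlation heatmaps, triplet stacks.

Rendering is deliberately split in two layers. The ``build_*`` functions
produce the numeric value grid plus row/column labels — pure functions of
their input tables, bit-identical across calls — and are what the tests
exercise. The ``render_*`` functions paint a grid with matplotlib and
write the image; they are only smoke-tested, so no result ever depends on
pixel comparison.

Missing rates (contexts absent from a region) are carried as NaN and
painted in a distinct "bad" color, never conflated with an observed zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .context_counting import BASES
from .errors import ConfigurationError
from .multi_organism import CorrelationTable
from .rate_engine import ContextRateMatrix, TRIPLETS


@dataclass
class FigureSpec:
    kind: str
    out_path: str
    dpi: int = 150
    vmin: Optional[float] = None
    vmax: Optional[float] = None
    title: str = ""


#: Row order of rate heatmaps: triplets grouped by mutable (center) base,
#: lexicographic within each group — the Fig-2-style layout.
HEATMAP_TRIPLET_ORDER: tuple[str, ...] = tuple(
    sorted(TRIPLETS, key=lambda t: (t[1], t[0], t[2]))
)


def build_rate_grid(matrix: ContextRateMatrix, use_scaled: bool = True):
    """64x3 grid: one row per triplet (grouped by center base), one column
    per alternative base in lexicographic order. NaN marks missing."""
    grid = np.full((64, 3), np.nan)
    row_labels = list(HEATMAP_TRIPLET_ORDER)
    col_labels = []
    for i, t in enumerate(HEATMAP_TRIPLET_ORDER):
        up, ref, down = t[0], t[1], t[2]
        alts = [a for a in BASES if a != ref]
        col_labels.append([f"{ref}>{a}" for a in alts])
        for j, alt in enumerate(alts):
            e = matrix.entries[(up, ref, alt, down)]
            val = e.scaled if use_scaled else e.rate
            if val is not None:
                grid[i, j] = val
    return grid, row_labels, col_labels


def render_rate_heatmap(
    matrices: Sequence[ContextRateMatrix], spec: FigureSpec
) -> str:
    """One panel per region (e.g. left/right replichore), 64 triplet rows
    each."""
    if not matrices:
        raise ConfigurationError("no matrices to render")
    grids = []
    for m in matrices:
        grid, rows, _ = build_rate_grid(m, use_scaled=m.scale_applied is not None)
        grids.append((m.region, grid, rows))
    if all(np.isnan(g).all() for _, g, _ in grids):
        raise ConfigurationError("all rates missing; nothing to render")
    fig, axes = plt.subplots(
        1, len(grids), figsize=(3.2 * len(grids) + 1.5, 11), squeeze=False
    )
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("#d0d0d0")
    for ax, (region, grid, rows) in zip(axes[0], grids):
        im = ax.imshow(
            np.ma.masked_invalid(grid),
            aspect="auto",
            cmap=cmap,
            vmin=spec.vmin,
            vmax=spec.vmax,
        )
        ax.set_title(region)
        ax.set_xticks(range(3))
        ax.set_xticklabels(["alt 1", "alt 2", "alt 3"], fontsize=6)
        ax.set_yticks(range(64))
        ax.set_yticklabels(rows, fontsize=4)
        fig.colorbar(im, ax=ax, shrink=0.6)
    if spec.title:
        fig.suptitle(spec.title)
    fig.tight_layout()
    fig.savefig(spec.out_path, dpi=spec.dpi)
    plt.close(fig)
    return spec.out_path


def build_correlation_grid(table: CorrelationTable):
    """len(rows) x len(cols) grid of Pearson r in the table's display
    order."""
    grid = np.full((len(table.row_order), len(table.col_order)), np.nan)
    for i, a in enumerate(table.row_order):
        for j, b in enumerate(table.col_order):
            grid[i, j] = table.pairs.get((a, b), np.nan)
    return grid, list(table.row_order), list(table.col_order)


def render_correlation_heatmap(table: CorrelationTable, spec: FigureSpec) -> str:
    grid, rows, cols = build_correlation_grid(table)
    finite = grid[np.isfinite(grid)]
    vmin = spec.vmin if spec.vmin is not None else (finite.min() if finite.size else -1)
    vmax = spec.vmax if spec.vmax is not None else (finite.max() if finite.size else 1)
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(cols), 1 + 0.6 * len(rows)))
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("#d0d0d0")
    im = ax.imshow(np.ma.masked_invalid(grid), cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels(cols, rotation=90, fontsize=7)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels(rows, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    if spec.title:
        ax.set_title(spec.title)
    fig.tight_layout()
    fig.savefig(spec.out_path, dpi=spec.dpi)
    plt.close(fig)
    return spec.out_path


def build_triplet_series(
    runs: Sequence[tuple[str, dict]], mode: str = "rate"
) -> tuple[np.ndarray, list[str], list[str]]:
    """(n_runs, 64) value array over the canonical triplet axis.

    Each run is (run_id, mapping); the mapping carries per-triplet values:
    (M, rate) tuples from triplet aggregation, or scalars for conditional
    rates. ``mode`` selects rate, raw_counts, or conditional."""
    if not runs:
        raise ConfigurationError("no runs to plot")
    if mode not in ("rate", "raw_counts", "conditional"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    run_ids = [rid for rid, _ in runs]
    values = np.zeros((len(runs), 64))
    for i, (_, mapping) in enumerate(runs):
        if set(mapping) != set(TRIPLETS):
            raise ConfigurationError("run tables must cover exactly the 64 triplets")
        for j, t in enumerate(TRIPLETS):
            v = mapping[t]
            if isinstance(v, tuple):
                v = v[0] if mode == "raw_counts" else v[1]
            values[i, j] = np.nan if v is None else v
    return values, run_ids, list(TRIPLETS)


def render_triplet_stack(
    runs: Sequence[tuple[str, dict]], mode: str, spec: FigureSpec
) -> str:
    values, run_ids, triplets = build_triplet_series(runs, mode)
    x = np.arange(64)
    fig, ax = plt.subplots(figsize=(14, 4))
    bottom = np.zeros(64)
    for i, rid in enumerate(run_ids):
        vals = np.nan_to_num(values[i])
        ax.bar(x, vals, bottom=bottom, label=rid)
        bottom += vals
    ax.set_xticks(x)
    ax.set_xticklabels(triplets, rotation=90, fontsize=5)
    ax.set_ylabel(mode)
    ax.legend(fontsize=7)
    if spec.title:
        ax.set_title(spec.title)
    fig.tight_layout()
    fig.savefig(spec.out_path, dpi=spec.dpi)
    plt.close(fig)
    return spec.out_path


def render_skew_profile(profile, frame, spec: FigureSpec) -> str:
    """Cumulative skew line with ORI/TER markers."""
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(profile.positions, profile.cumulative, lw=0.8)
    ax.axvline(frame.ori, color="tab:green", ls="--", label=f"ORI ({frame.ori})")
    ax.axvline(frame.ter, color="tab:red", ls="--", label=f"TER ({frame.ter})")
    ax.set_xlabel("position")
    ax.set_ylabel("cumulative GC skew")
    ax.legend(fontsize=7)
    if spec.title:
        ax.set_title(spec.title)
    fig.tight_layout()
    fig.savefig(spec.out_path, dpi=spec.dpi)
    plt.close(fig)
    return spec.out_path
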
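# Methods

## Model and procedure

`contextmut` estimates context-dependent base-substitution rates from a
mutation-accumulation (MA) design: `N` lineages bottlenecked each
generation for `G` generations, so that nearly all non-lethal mutations fix
independently of selection and observed substitutions are a direct sample
of the mutation process. For a triplet context `u·X·d` and alternative base
`a`,

    rate(u, X→a, d) = M / (C · G · N)

with `M` the substitution count in that context over the region and `C`
the region's occurrence count of the triplet (GWTC for the chromosome,
RWTC per replichore). The estimator is a per-context Poisson-rate MLE; no
confidence intervals are reported (point estimates only, matching the
scope of the tool). `G` is assumed uniform across lineages; heterogeneous
per-lineage generation counts are out of scope. For non-MA data (e.g. two
closely related strains) `G` must be supplied as a divergence-time
estimate and the output is interpretable only up to that calibration.

The pipeline per organism: read inputs → fix the replication frame
(manual or skew-detected) → partition into replichores → tabulate context
counts (genome + both replichores, reference + complement strands) →
orient each variant's context → compute, aggregate, and scale rates → bin
mutations along the ORI-rotated chromosome → write CSV/JSON/figures.

## Coordinates and conventions

* File-facing coordinates are 1-based inclusive (VCF/GenBank convention);
  internal computation is 0-based half-open. Conversion is confined to the
  I/O layer.
* The *right* replichore is the half-open arc `[ORI, TER)` in increasing
  coordinates mod L; ORI itself is right, TER is left. The same modular
  rule is applied to linear genomes (the two arcs still partition every
  position exactly once).
* Windows are keyed by their mutable base: the center for odd k, the
  left-of-center base for even k. A window belongs to a replichore iff its
  key base does — rates are per mutable site, so the mutable base decides
  membership. Circular genomes wrap windows across the junction (exactly L
  windows of every width); the wrap is this package's choice and is what
  makes the conservation law Σ counts + n_skipped = L exact.
* Under the `lagging_template_revcomp` convention, right-replichore
  variant contexts (triplet, ref, alt, extended flanks) are reverse
  complemented so both replichores read in synthesis orientation; the
  matching rate denominators are then the right-replichore counts on the
  *complement* strand. This wiring is what keeps ΣM(genome) =
  ΣM(left) + ΣM(right) exact and the two replichore panels directly
  comparable.
* The "5-mer frame" is exposed three ways: k=4 tables anchored at the
  left-of-center base (one upstream/two downstream neighbors), plus a full
  k=5 table, plus the primary k=3 path. Rates are computed on triplets;
  wider tables are counts only.

## Origin/terminus detection

ORI is placed at the global minimum and TER at the global maximum of the
cumulative GC skew (+1 per G, −1 per C, accumulated in coordinate order),
encoding the leading-strand-G-rich convention; a switch flips the
convention for genomes with inverted skew, and ties break toward the
smallest coordinate. A `synonymous_third_codon` site restriction (third
codon positions of complete CDS, complement base for minus-strand CDS) is
available to suppress coding-sequence composition bias.

This is deliberately simpler than segmented-regression skew fitting
(OriLoc-style): global extrema of the cumulative profile. Two consequences:
(1) detection is only well posed when the two arcs are roughly balanced —
on a heavily rotated coordinate system or a strongly asymmetric skew, an
extremum can land at the sequence end rather than a true switch point; the
manual `--ori/--ter` override (ORI entered as 0 normalizes to position 1)
is the supported path for such genomes, as it is for multi-origin
(eukaryotic/archaeal) chromosomes. (2) On clean profiles the extremum sits
within one site of the switch point, which is the tolerance the tests
enforce.

## Missing vs zero, scaling

A context absent from a region (denominator 0) has a *missing* rate,
written as an empty CSV field and NaN in vectors — never 0, which is
reserved for "observed none at a positive denominator". An entry with
M > 0 but denominator 0 indicates an orientation/count mismatch and is
flagged inconsistent with a warning rather than aborting the run.

Display scaling (mode 0: ÷10⁻⁸; mode 1: ÷mean of non-missing rates;
mode 2: ÷custom factor) fills a separate `scaled_rate` column; unscaled
rates are always retained and are the basis of every statistic. Scaling is
rank-preserving and cannot affect correlations, which are computed on
unscaled vectors.

## Cross-organism correlation

Each run is summarized as the 192-vector of unscaled rates in canonical
lexicographic (up, ref, alt, down) order. Pearson r is computed on
pairwise-complete entries (entries missing in either vector dropped);
pairs with fewer than 3 complete entries or a constant vector yield a
missing r with a warning. Raw (not log) rates are correlated by default; a
log10 option exists for heavy-tailed spectra. Rows sort ascending by
coding-region GC (AT-rich on top), columns descending, ties broken by run
id. The replichore/strand bases expose the left/right replichore vectors
and the complement-strand re-keying of the chromosome matrix.

## Spatial binning

Each variant maps to offset (position − ORI) mod L and to bin
⌊offset·n/L⌋ + 1 — real-valued width L/n with floor indexing, no remainder
bin — so bin 1 starts at the ORI and a terminus at exactly L/2 falls in
bin 13 of 25. Integer bin boundaries are ⌈i·L/n⌉, which tile [0, L)
exactly, differ in width by at most one base, and agree with the floor
rule for every integer offset. The multi-run JSON export (schema version
1.0, deterministic key order) requires a common bin count so stacked
circular tracks align.

## Synthetic fixtures

The generator emulates the structure of a bacterial MA dataset:

* **Genome**: i.i.d. bases at a target GC (default 0.45, mid-range for
  bacteria). With planted skew, G/C sites on the ORI→TER arc are G with
  probability (1+s)/2 and the complementary arc mirrors it; at the default
  s = 1.0 every G/C site is fully polarized and the four bases flanking
  the switch points are pinned (C|G at ORI, G|C at TER), making the
  cumulative-skew extrema deterministic at the planted coordinates ±1.
  Fractional s gives lifelike noisy profiles whose extrema wander by
  O(√L/s) sites and is not used where ±1 recovery is asserted.
* **Annotations**: non-overlapping CDS with length divisible by 3, random
  strand, optional two-exon join(), written as a valid GenBank file.
* **Mutations**: for each (triplet, alt) key, the event count is drawn
  Poisson(occurrences · G · N · u) — the MA sampling process — and
  positions are sampled uniformly without replacement among matching
  reference-strand sites; an exact-count mode bypasses the Poisson draw
  for deterministic tests. Demanding more events than matching sites is a
  hard error, so rate maps must respect u · G · N ≤ 1 per context. The
  manifest stores exact per-context counts, making downstream recovery
  checkable to equality.

Every stage draws from its own named PRNG substream derived from
(seed, stage name): adding a stage never perturbs earlier draws, and all
outputs are bit-reproducible per seed.

What the fixtures do **not** emulate: indels and structural variants,
selection, mutational hotspot clustering beyond the context map,
methylation- or repair-tract-dependent effects, multi-replicon genomes,
and reference/strain offsets. Passing tests therefore demonstrate the
correctness of the counting, orientation, rate arithmetic, and export
machinery under the stated sampling model — not robustness to the
artifacts of real MA sequencing data (those enter via the variant-file
exclusion rules: non-SNVs, reference mismatches, out-of-range and
ambiguous-context records are logged and excluded, never silently
dropped).

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| G (generations) | required | generations/lineage | experiment-specific; worked examples use 5077 |
| N (lineages) | required | count | worked examples use 50 |
| scaling mode | ÷10⁻⁸ | — | typical bacterial per-site rates are O(10⁻⁸–10⁻¹⁰); division lands display values near 1 |
| strand convention | lagging-template revcomp | — | makes replichore panels strand-comparable |
| k set | {3} | bases | triplet path is primary; 4/5 available |
| n_bins | 25 | bins | standard choices 25/50/75; nonstandard warns |
| circular | true | — | bacterial chromosomes; linear drops terminal contexts with a logged reason |
| fixture GC | 0.45 | fraction | mid-range bacterial composition |
| fixture u | ~10⁻⁸ | /site/generation | MA-regime mutation rates |

Test and acceptance problem sizes (3–500 kb genomes, 10–60 CDS, 20–50
seeds) are chosen so expected per-context counts span the O(1)–O(100)
regime that exercises both sparse and dense spectra while the full suite
runs in seconds.

## Numerical choices

* Rates are exact IEEE quotients M/(C·G·N); the inversion
  rate·C·G·N = M holds to ~1 ulp and tests assert 10⁻¹² relative.
* CSV floats are written with `repr`, which round-trips doubles exactly;
  every writer has a matching reader and write→read is an identity.
* JSON output uses sorted keys and fixed separators, so identical runs are
  byte-identical (the determinism guarantee covers all CSV and JSON
  outputs; figures are excluded — image metadata is not contract).
* Skew and count tabulation are vectorized (base-4 window encoding +
  bincount); brute-force string-slicing oracles in the test suite pin the
  semantics.
* Tie-breaks: skew extrema → smallest coordinate; GC-order ties → run id.

## Known limitations

* One chromosome per run: multi-record FASTA uses record 1 with a warning;
  plasmids/chromids require separate runs.
* Global-extrema origin detection (see above); no multi-origin inference.
* No indel rates, no significance tests on correlations, no clustering of
  the correlation matrix.
* The conditional rate conditions on genome-wide center-base content; other
  conditionings (e.g. strand-resolved base content) are not implemented.
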
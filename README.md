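# contextmut

Context-dependent mutation rate analysis for bacterial mutation-accumulation
(MA) experiments — and, more generally, for any set of single-nucleotide
variants called against a reference chromosome.

The rate at which a nucleotide mutates depends strongly on its immediate
5′ and 3′ neighbors (up to orders of magnitude between triplet contexts),
and on which replichore — hence which replication strand — the site sits
on. `contextmut` takes a reference genome (FASTA), an annotation (GenBank),
and a variant list (VCF or a minimal `position,ref,alt` CSV), and computes
genome-wide and replichore-specific context-dependent base-substitution
rates, compares the resulting spectra across organisms, and exports binned
spatial mutation data for circular-genome visualization.

## The estimator

For a triplet context `u·X·d` (5′ neighbor `u`, mutable base `X`, 3′
neighbor `d`) and alternative base `a`, the per-site per-generation rate in
an MA design with `N` lineages propagated for `G` generations each is

    rate(u, X→a, d) = M / (C · G · N)

where `M` is the number of observed `X→a` substitutions in that context
within the region and `C` is the occurrence count of the triplet `u·X·d` in
the region: the genome-wide triplet count (GWTC) for chromosome-wide rates,
or the replichore-wide triplet count (RWTC) for replichore-specific rates.
The full store is the 192-class matrix (4 × 4 × 3 × 4 over up/ref/alt/down);
the 64-triplet spectrum is its aggregation over alternative bases. A
*conditional* rate normalizes each triplet's mutation load to genome-wide
content of the mutable center base instead of the triplet count.

Replichores are defined from the replication origin and terminus, located
at the global minimum and maximum of the cumulative GC skew (leading strand
G-rich convention) or supplied manually. Under the lagging-template
convention, right-replichore contexts are reverse-complemented so that both
replichores are read in their synthesis orientation, making leading/lagging
strand asymmetries directly comparable.

Cross-organism comparison is a one-to-many Pearson correlation over the
192-entry unscaled rate vectors (pairwise-complete), displayed AT-rich →
GC-rich by coding-region GC content.

A synthetic-fixture module generates genomes (optionally with planted
replication skew), GenBank annotations, and Poisson-planted variant sets
with exact per-context manifests, so the entire pipeline is testable with
known ground truth and no downloads.

## Worked example

```python
import contextmut as cm
from contextmut import synthetic as syn

# a 50 kb circular chromosome with planted skew switch points, 40 CDS,
# and mutations planted at heterogeneous context rates around 1e-8
genome, _ = syn.generate_genome(50000, 0.43, skew=(6000, 31000, 1.0),
                                seed=7, genome_id="demo")
frame_true = cm.make_frame(6000, 31000, genome.length)
syn.write_fasta(genome, "demo.fasta")
syn.generate_annotations(genome, 40, seed=7, path="demo.gbk")
variants, manifest = syn.plant_mutations(
    genome, frame_true, syn.random_rate_map(1e-8, seed=7), 5077, 50,
    seed=7, basecall_path="demo.csv")

config = cm.RunConfig(
    fasta="demo.fasta", genbank="demo.gbk", variants="demo.csv",
    dialect="basecall", run_id="demo", out_root="output",
    params=cm.RunParameters(generations=5077, lineages=50))
run_dir = cm.run_soa(config)
```

which prints (via the snippet in the repo's test/demo code):

```
planted mutations: 650
detected ORI=5999, TER=30999 (planted 6000/31000)
hottest context: A[C>T]C  M=32  GWTC=1314  rate=9.594e-08 /site/gen (scaled 9.59)
mutations genome/left/right: 650/321/329
```

Reading the numbers: skew-based detection recovered both planted switch
points within one base; the hottest context saw 32 C→T events over 1314
A·C·C sites × 5077 generations × 50 lineages, i.e. 9.6 × 10⁻⁸ per site per
generation (9.59 after the default ÷10⁻⁸ display scaling); and the genome
total splits exactly across the two replichores (650 = 321 + 329). The run
directory contains `counts/` (GWTC/RWTC, codon usage, skew profile),
`rates/` (192-row CSVs per region), `bins/` (25-bin spatial table + JSON
export), `figures/`, and a machine-readable `run_log.json`.

The same run is available from the shell:

```bash
contextmut soa --fasta demo.fasta --genbank demo.gbk --variants demo.csv \
    --dialect basecall -g 5077 -n 50 --auto-ori \
    --out output --run-id demo
contextmut moa --root output        # after >= 2 runs: GC-sorted Pearson table
```

(`--auto-ori` detects the frame from cumulative GC skew; `--ori/--ter` set
it manually, with `--ori 0` meaning the first base; `--interactive` walks
through the same questions as prompts instead.)

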
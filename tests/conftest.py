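import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import contextmut as cm
from contextmut import synthetic as syn

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome():
    """20 kb unskewed circular genome with a user frame at the midpoint."""
    genome, manifest = syn.generate_genome(20000, 0.45, seed=11, genome_id="fix20k")
    frame = cm.make_frame(1, 10001, genome.length)
    return genome, frame, manifest


@pytest.fixture(scope="session")
def planted_run(small_genome):
    """Genome + Poisson-planted variants at MA-like scale (G=5077, N=50)."""
    genome, frame, _ = small_genome
    params = cm.RunParameters(generations=5077, lineages=50)
    table, manifest = syn.plant_mutations(
        genome, frame, syn.uniform_rate_map(1e-8), params.generations,
        params.lineages, seed=23,
    )
    return genome, frame, params, table, manifest


@pytest.fixture()
def soa_fixture_dir(tmp_path):
    """Write FASTA/GenBank/variants for one organism into tmp_path."""

    def _make(seed=5, length=12000, gc=0.45, rate_seed=5, run_prefix="org"):
        genome, _ = syn.generate_genome(length, gc, seed=seed, genome_id=f"{run_prefix}{seed}")
        frame = cm.make_frame(1, length // 2 + 1, genome.length)
        fasta = tmp_path / f"{run_prefix}{seed}.fasta"
        gbk = tmp_path / f"{run_prefix}{seed}.gbk"
        csv = tmp_path / f"{run_prefix}{seed}.csv"
        syn.write_fasta(genome, fasta)
        syn.generate_annotations(genome, 10, seed=seed, path=gbk)
        table, manifest = syn.plant_mutations(
            genome, frame, syn.random_rate_map(1e-8, seed=rate_seed),
            5077, 50, seed=seed, basecall_path=csv,
        )
        return {
            "genome": genome, "frame": frame, "fasta": fasta, "gbk": gbk,
            "csv": csv, "manifest": manifest, "table": table,
        }

    return _make
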
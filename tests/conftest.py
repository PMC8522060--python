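import numpy as np
import pytest

from glycomet import (ThresholdGrid, build_benchmark, evaluate_grid,
                      search_reads, synth_genome, synth_reference_db)


@pytest.fixture(scope="session")
def small_refdb():
    """A compact random reference DB for unit tests."""
    return synth_reference_db(n_proteins=40, length_range=(60, 120), seed=11)


@pytest.fixture(scope="session")
def standard_benchmark():
    """The standard synthetic calibration benchmark, searched once.

    Reference of 200 random proteins; five genomes each mixing 30 exact
    back-translated CAZyme genes, 50 random decoys and 20 near-homolog decoys
    at 60-85% amino-acid identity; 100-nt reads, up to 3 per gene.
    """
    refdb = synth_reference_db(n_proteins=200, seed=7)
    best_hits, truth, genome_of = {}, {}, {}
    for g in range(5):
        genome = synth_genome(refdb, n_true=30, n_decoy_random=50,
                              n_decoy_homolog=20,
                              homolog_identity_range=(0.60, 0.85),
                              seed=100 + g, genome_id=f"g{g}")
        bench = build_benchmark(genome, read_len=100, k=3, seed=200 + g)
        reads = [(f.read_id, f.dna) for f in bench.fragments]
        best_hits.update(search_reads(reads, refdb))
        for f in bench.fragments:
            truth[f.read_id] = f.truth_label
            genome_of[f.read_id] = bench.genome_id
    surface = evaluate_grid(best_hits, truth, ThresholdGrid(), genome_of)
    return dict(refdb=refdb, best_hits=best_hits, truth=truth,
                genome_of=genome_of, surface=surface)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
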
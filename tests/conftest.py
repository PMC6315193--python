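import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from genotax.simulate import SimulationParams, simulate_clade_set


@pytest.fixture(scope="session")
def small_clade_set():
    """A desk-scale planted taxonomy reused across tests: 2 genera x 2
    species x 2 genomes, 30-kb genomes, 200 genes of 200 aa."""
    params = SimulationParams(
        seed=11,
        n_genera=2,
        species_per_genus=2,
        genomes_per_species=2,
        genome_length=30_000,
        n_genes=200,
        gene_length_aa=200,
    )
    return simulate_clade_set(params)


@pytest.fixture(scope="session")
def small_results(small_clade_set):
    from genotax.indexes import all_pairwise

    genomes, proteomes, _ = small_clade_set
    return all_pairwise(genomes, proteomes)


@pytest.fixture(scope="session")
def small_support_tree(small_results):
    from genotax.phylo import infer_tree, map_support, pseudo_bootstrap

    tree = infer_tree(small_results.distance_matrix())
    reps = pseudo_bootstrap(small_results, replicates=50, seed=4)
    return map_support(tree, [infer_tree(m) for m in reps])
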
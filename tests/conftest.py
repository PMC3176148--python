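import numpy as np
import pytest

from teclass.jtt import EvolutionaryDistanceMatrix, distance_matrix
from teclass.synthetic import (
    ProfileSimSpec,
    SequenceSimSpec,
    simulate_profiles,
    simulate_subfamily_alignment,
    species_map,
)
from teclass.trees import BootstrapConfig, bootstrap_supports


@pytest.fixture(scope="session")
def three_clade_sim():
    """A fixed three-subfamily simulation with distances and supported tree."""
    spec = SequenceSimSpec(seed=11)
    aln, truth, true_tree = simulate_subfamily_alignment(spec)
    D = distance_matrix(aln)
    tree = bootstrap_supports(aln, cfg=BootstrapConfig(replicates=25, seed=3))
    return {
        "aln": aln,
        "truth": truth,
        "true_tree": true_tree,
        "D": D,
        "tree": tree,
        "species": species_map(aln),
    }


@pytest.fixture(scope="session")
def profile_sim():
    """A fixed three-class specificity simulation (default conditions)."""
    spec = ProfileSimSpec(seed=7)
    return spec, simulate_profiles(spec)


def additive_matrix(tree_lengths: dict[frozenset, float], ids: list[str]):
    """Distance matrix from explicit split lengths (test helper)."""
    n = len(ids)
    d = np.zeros((n, n))
    for split, length in tree_lengths.items():
        for i in range(n):
            for j in range(n):
                if (ids[i] in split) != (ids[j] in split):
                    d[i, j] += length
    return EvolutionaryDistanceMatrix(
        ids, d, np.zeros((n, n), dtype=int), {}
    )
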
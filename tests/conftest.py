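import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fviiirin import (GeneratorSpec, build_rin, compute_centralities,
                      generate_structure)


@pytest.fixture(scope="session")
def helix30():
    """A 30-residue ideal helix: structure, network and centrality table."""
    spec = GeneratorSpec(seed=1, n_residues=30, fold="helix")
    structure, pdb_text = generate_structure(spec)
    graph = build_rin(structure)
    table = compute_centralities(graph)
    return {"spec": spec, "structure": structure, "pdb_text": pdb_text,
            "graph": graph, "table": table}


@pytest.fixture(scope="session")
def helix_pdb_file(tmp_path_factory):
    """The helix fixture written to disk for parser round-trips."""
    path = tmp_path_factory.mktemp("pdb") / "helix30.pdb"
    generate_structure(GeneratorSpec(seed=1, n_residues=30), path=path)
    return path


def seeded_er_graph(seed: int, n: int = 25, p: float = 0.15) -> nx.Graph:
    """Erdős–Rényi graph with integer node labels 0..n-1."""
    return nx.gnp_random_graph(n, p, seed=seed)


@pytest.fixture
def er25():
    return seeded_er_graph(7)
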
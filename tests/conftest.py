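import numpy as np
import pytest

from rbdscope.io import AMINO_ACIDS, Msa, SequenceRecord, load_substitution_matrix


@pytest.fixture(scope="session")
def blosum62():
    return load_substitution_matrix("BLOSUM62")


def random_msa(
    rng: np.random.Generator,
    n_records: int,
    width: int,
    gap_prob: float = 0.1,
    x_prob: float = 0.02,
) -> Msa:
    """Random gapped alignment for oracle and property tests."""
    alphabet = list(AMINO_ACIDS)
    records = []
    for i in range(n_records):
        chars = []
        for _ in range(width):
            u = rng.random()
            if u < gap_prob:
                chars.append("-")
            elif u < gap_prob + x_prob:
                chars.append("X")
            else:
                chars.append(alphabet[int(rng.integers(20))])
        residues = "".join(chars)
        if set(residues) == {"-"}:  # keep records non-degenerate
            residues = "A" + residues[1:]
        records.append(SequenceRecord(id=f"r{i}", residues=residues))
    return Msa(records)


def random_additive_matrix(rng: np.random.Generator, n_leaves: int):
    """Distances induced by a random binary tree with positive branch lengths.

    Returns (labels, values) where values[i, j] is the exact path length
    between leaves i and j in the generating tree.
    """
    # grow a random topology by splitting edges
    nodes = {0: []}  # node -> children (id, length)
    parent_edges = {}
    next_id = 1
    leaves = [0]
    while len(leaves) < n_leaves:
        leaf = leaves[int(rng.integers(len(leaves)))]
        left, right = next_id, next_id + 1
        next_id += 2
        nodes[leaf] = [
            (left, float(rng.uniform(0.05, 1.0))),
            (right, float(rng.uniform(0.05, 1.0))),
        ]
        nodes[left] = []
        nodes[right] = []
        leaves.remove(leaf)
        leaves.extend([left, right])

    # path lengths between all leaf pairs via DFS from each leaf
    adjacency: dict[int, list[tuple[int, float]]] = {k: [] for k in nodes}
    for parent, children in nodes.items():
        for child, length in children:
            adjacency[parent].append((child, length))
            adjacency[child].append((parent, length))
    leaves = sorted(leaves)
    index = {leaf: i for i, leaf in enumerate(leaves)}
    values = np.zeros((n_leaves, n_leaves))
    for src in leaves:
        stack = [(src, -1, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            if node in index and node != src:
                values[index[src], index[node]] = dist
            for nbr, length in adjacency[node]:
                if nbr != prev:
                    stack.append((nbr, node, dist + length))
    values = (values + values.T) / 2  # exact symmetry despite float summation order
    labels = [(f"t{chr(ord('a') + i)}", i) for i in range(n_leaves)]
    return labels, values
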
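import numpy as np
import pytest

from conet.counts import CountTable, Lineage
from conet.network import AssociationNetwork


@pytest.fixture
def small_table() -> CountTable:
    """4 features x 5 samples with hand-written counts and lineages."""
    counts = np.array(
        [
            [10, 0, 5, 2, 8],
            [0, 0, 0, 0, 0],
            [3, 4, 1, 2, 3],
            [1, 2, 1, 0, 1],
        ],
        dtype=float,
    )
    lineages = [
        Lineage.from_string("Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus"),
        Lineage.from_string("Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Pediococcus"),
        Lineage.from_string("Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae"),
        Lineage.from_string("Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Bacteroidaceae;Bacteroides"),
    ]
    return CountTable(counts, ["f1", "f2", "f3", "f4"], list("abcde"), lineages)


def random_network(
    rng: np.random.Generator,
    nodes,
    method: str = "m",
    density: float = 0.4,
    with_pvalues: bool = False,
) -> AssociationNetwork:
    """Random symmetric signed network over the given nodes."""
    q = len(nodes)
    w = np.zeros((q, q))
    iu = np.triu_indices(q, 1)
    mask = rng.random(iu[0].size) < density
    vals = rng.uniform(-1, 1, iu[0].size) * mask
    w[iu] = vals
    w = w + w.T
    p = None
    if with_pvalues:
        p = np.ones((q, q))
        pv = rng.uniform(0, 1, iu[0].size)
        p[iu] = pv
        p[(iu[1], iu[0])] = pv
    return AssociationNetwork(method, nodes, w, p)
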
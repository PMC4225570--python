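import numpy as np
import pytest

from specseg import synth
from specseg.hclust import TruncatedDendrogram


@pytest.fixture(scope="session")
def small_phantom():
    """A 5-class, well-separated phantom small enough for every module."""
    spec = synth.PhantomSpec(K=5, B=60, H=24, W=24, separability=10, seed=3)
    img, gt = synth.generate_image(spec)
    return spec, img, gt


@pytest.fixture
def four_leaf_tree():
    """The balanced tree ((0,1),(2,3)) with the top merge highest."""
    from specseg.hclust import Dendrogram

    Z = np.array(
        [
            [0, 1, 1.0, 2],
            [2, 3, 1.5, 2],
            [4, 5, 4.0, 4],
        ]
    )
    return Dendrogram(Z)


def random_truncated_tree(rng, n_leaves):
    """A random binary merge tree over ``n_leaves`` items, untruncated."""
    from specseg.hclust import Dendrogram, truncate_topmost

    active = list(range(n_leaves))
    Z = np.zeros((n_leaves - 1, 1))
    rows = []
    sizes = {i: 1 for i in range(n_leaves)}
    h = 0.0
    nxt = n_leaves
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]
        del active[j], active[i]
        h += float(rng.uniform(0.1, 1.0))
        sizes[nxt] = sizes[a] + sizes[b]
        rows.append([min(a, b), max(a, b), h, sizes[nxt]])
        active.append(nxt)
        nxt += 1
    d = Dendrogram(np.array(rows))
    return d, truncate_topmost(d, V=2 * n_leaves - 1)
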
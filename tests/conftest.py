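import numpy as np
import pytest

from markerkit.io import BandMatrix, Locus


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_band_matrix(rng, n_taxa=4, n_loci=10, primer="P1"):
    """Random valid matrix: every locus present in >= 1 taxon."""
    values = rng.integers(0, 2, size=(n_taxa, n_loci)).astype(np.int8)
    for j in range(n_loci):
        if not values[:, j].any():
            values[rng.integers(n_taxa), j] = 1
    return BandMatrix(
        taxa=[f"T{i}" for i in range(n_taxa)],
        loci=[Locus(primer, f"b{j}") for j in range(n_loci)],
        values=values,
    )


@pytest.fixture
def sr14_like_matrix():
    """7 bands over 4 taxa: four at f=0.5, three at f=0.25."""
    cols = (
        [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1], [1, 0, 0, 1]]
        + [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1]]
    )
    return BandMatrix(
        taxa=["A_annua", "A_herba-alba", "A_monosperma", "A_judaica"],
        loci=[Locus("SR-14", f"b{j}") for j in range(7)],
        values=np.array(cols).T,
    )
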
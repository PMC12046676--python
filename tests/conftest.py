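import numpy as np
import pandas as pd
import pytest

from spotcna.simulate import make_genome
from spotcna.types import GenePositions, SpatialExpression


@pytest.fixture
def tiny_genome() -> GenePositions:
    """Two chromosomes, 6 genes each, centromere at the midpoint."""
    gp, _ = make_genome(n_genes=12, n_chromosomes=2)
    return gp


def build_se(counts: np.ndarray, bead_type=None, coords=None) -> SpatialExpression:
    """Small SpatialExpression from a dense array (beads x genes)."""
    counts = np.asarray(counts)
    n, g = counts.shape
    beads = [f"b{i}" for i in range(n)]
    genes = [f"G{j:02d}" for j in range(g)]
    if coords is None:
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    if bead_type is None:
        bead_type = ["reference"] * (n // 2) + ["malignant"] * (n - n // 2)
    return SpatialExpression(
        pd.DataFrame(counts, index=beads, columns=genes),
        pd.DataFrame(coords, index=beads, columns=["x", "y"]),
        pd.Series(list(bead_type), index=beads),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
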
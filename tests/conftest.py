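import warnings

import numpy as np
import pandas as pd
import pytest

from sgribo import simdata

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_field():
    """One rendered 20-cell field with truth tables (session-cached)."""
    return simdata.generate_field(simdata.FieldSpec(), seed=0)


@pytest.fixture(scope="session")
def null_counts():
    """Global-null paired RNA/Ribo counts, 3 vs 3, dispersion 0.1."""
    design = simdata.CountDesign(n_genes=1000, dispersion=0.1,
                                 class_fractions={}, seed=7)
    return simdata.generate_counts(design)


@pytest.fixture(scope="session")
def planted_counts():
    """Counts with planted TE/buffering/RNA-abundance classes at LFC 2."""
    design = simdata.CountDesign(
        n_genes=2000, dispersion=0.05, effect_lfc=2.0, seed=11,
        baseline_mean=(np.log(200.0), 0.0))
    return simdata.generate_counts(design)


def rasterize_ellipse(a: float, b: float, pad: int = 4) -> np.ndarray:
    """Boolean mask of an axis-aligned filled ellipse, for geometry oracles."""
    n = int(np.ceil(a)) * 2 + 2 * pad + 1
    c = n // 2
    rr, cc = np.ogrid[:n, :n]
    return ((cc - c) / a) ** 2 + ((rr - c) / b) ** 2 <= 1.0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
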
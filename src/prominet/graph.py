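"""Graph-level primitives: averaging, thresholding, density, components.

Thresholding is on the correlation magnitude ``|a_uv|`` by default, with the
edge retained when ``|a_uv| >= tau`` (so grid endpoints are reproducible) and
exact zeros always dropped. A ``signed=True`` variant retains only
``a_uv >= tau`` for users who want positive-only edges.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from .io import ConnectomeMatrix, CohortStack, ConnectomeError, Graph


def group_average(stack: CohortStack) -> ConnectomeMatrix:
    """Entrywise arithmetic mean of the cohort's connectomes (the GA FC)."""
    mean = np.mean([m.values for m in stack.matrices], axis=0)
    mean = (mean + mean.T) / 2.0
    np.fill_diagonal(mean, 0.0)
    return ConnectomeMatrix(mean, label="GA")


def _retained_mask(fc: ConnectomeMatrix, tau: float, signed: bool) -> np.ndarray:
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold tau must be in [0, 1], got {tau}")
    a = fc.values
    if signed:
        mask = (a >= tau) & (a > 0)
    else:
        mask = (np.abs(a) >= tau) & (a != 0)
    np.fill_diagonal(mask, False)
    return mask


def threshold_binarize(fc: ConnectomeMatrix, tau: float, signed: bool = False) -> Graph:
    """Binarize: edge u-v present iff ``|a_uv| >= tau`` (masked GA graph)."""
    return Graph("binary", _retained_mask(fc, tau, signed).astype(float), label=fc.label)


def threshold_weighted(fc: ConnectomeMatrix, tau: float, signed: bool = False) -> Graph:
    """Threshold keeping absolute weights: retained entries carry ``|a_uv|``."""
    mask = _retained_mask(fc, tau, signed)
    return Graph("weighted", np.where(mask, np.abs(fc.values), 0.0), label=fc.label)


def edge_density(g: Graph) -> float:
    """Fraction of realized unordered node pairs, ``m / (n(n-1)/2)``."""
    if g.n < 2:
        raise ValueError("edge density needs at least 2 nodes")
    return g.m / (g.n * (g.n - 1) / 2)


def count_components(g: Graph) -> int:
    """Number of connected components; isolated nodes count individually."""
    if g.n == 0:
        return 0
    ncomp, _ = connected_components(csr_array(g.values), directed=False)
    return int(ncomp)
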
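"""Seeded generators for planted-partition graphs and FC-like cohorts.

These emulate the structure the pipeline is designed to detect — a fixed
a priori partition whose blocks have contrasting connectivity — without any
imaging data. FC emulation samples block-conditional Gaussian entries
directly (not latent time series plus Pearson), which keeps the within /
between contrast analytically controlled; per-subject heterogeneity is a
Gaussian jitter on the block means, mimicking individual differences in
functional-coupling strength.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .io import CohortStack, ConnectomeMatrix, Graph, Partition

#: clipping bound keeping synthetic correlations away from |r| = 1.
CLIP = 0.999


def _planted_sigma(sizes: Sequence[int]) -> Partition:
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size == 0 or sizes.min() < 1:
        raise ValueError("block sizes must be positive")
    return Partition(np.repeat(np.arange(1, sizes.size + 1), sizes))


def sample_sbm(
    sizes: Sequence[int],
    w: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> tuple[Graph, Partition]:
    """Sample a planted-partition (SBM) binary graph.

    Each unordered pair {u, v} is an edge independently with probability
    ``w[sigma_u - 1, sigma_v - 1]``. Returns the graph and its planted
    partition; reproducible given the seed.
    """
    part = _planted_sigma(sizes)
    w = np.asarray(w, dtype=float)
    k = part.k
    if w.shape != (k, k):
        raise ValueError(f"w must be {k}x{k}, got {w.shape}")
    if np.abs(w - w.T).max(initial=0.0) > 1e-12:
        raise ValueError("w must be symmetric")
    if w.min() < 0 or w.max() > 1:
        raise ValueError("w entries must be probabilities in [0, 1]")
    rng = np.random.default_rng(seed)
    n = part.n
    prob = w[np.ix_(part.sigma - 1, part.sigma - 1)]
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    adj = (upper | upper.T).astype(float)
    return Graph("binary", adj, label="sbm"), part


def sample_fc(
    sizes: Sequence[int],
    mu_within: float = 0.6,
    mu_between: float = 0.1,
    sd: float = 0.02,
    seed: int | np.random.Generator = 0,
    label: str = "synthetic",
) -> ConnectomeMatrix:
    """Sample an FC-like matrix with planted block structure.

    Entry (u, v) is Normal(mu_within, sd) when u, v share a block and
    Normal(mu_between, sd) otherwise, clipped to [-0.999, 0.999];
    symmetric with zero diagonal.
    """
    part = _planted_sigma(sizes)
    n = part.n
    rng = np.random.default_rng(seed)
    same = part.sigma[:, None] == part.sigma[None, :]
    mean = np.where(same, mu_within, mu_between)
    noise = rng.normal(0.0, sd, size=(n, n)) if sd > 0 else np.zeros((n, n))
    a = mean + noise
    a = np.triu(a, k=1)
    a = a + a.T
    np.clip(a, -CLIP, CLIP, out=a)
    np.fill_diagonal(a, 0.0)
    return ConnectomeMatrix(a, label=label)


def planted_partition(sizes: Sequence[int]) -> Partition:
    """The ground-truth partition for block sizes as generated above."""
    return _planted_sigma(sizes)


def sample_cohort(
    gamma: int,
    sizes: Sequence[int],
    mu_within: float = 0.6,
    mu_between: float = 0.1,
    sd: float = 0.02,
    subject_sd: float = 0.05,
    seed: int = 0,
) -> CohortStack:
    """Sample a cohort of Gamma FC-like matrices with subject-level jitter.

    Subject ``i`` uses the derived seed ``seed + i``; its block means are
    first jittered by Normal(0, subject_sd) — one draw per (within, between)
    pair — before entry sampling, so each subject has its own coupling
    strength and hence its own optimal threshold.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    mats = []
    for i in range(gamma):
        rng = np.random.default_rng(seed + i)
        d_w, d_b = (rng.normal(0.0, subject_sd, size=2) if subject_sd > 0 else (0.0, 0.0))
        mats.append(
            sample_fc(
                sizes,
                mu_within=mu_within + d_w,
                mu_between=mu_between + d_b,
                sd=sd,
                seed=rng,
                label=f"subj_{i:03d}",
            )
        )
    return CohortStack(mats)


def closed_form_snr(a: float, b: float) -> float:
    """Exact SNR of the symmetric two-equal-block SBM, (a-b)^2 / (2(a+b)).

    With p = (1/2, 1/2) and W = (1/n) [[a, b], [b, a]], the community
    profile matrix is PQ = [[a/2, b/2], [b/2, a/2]] with eigenvalues
    (a+b)/2 and (a-b)/2, giving SNR = lambda_2^2 / lambda_1 =
    (a-b)^2 / (2(a+b)). Used as the analytic oracle for the inference +
    eigensolve path. a = b collapses to an ER graph (SNR = 0).
    """
    if a < 0 or b < 0:
        raise ValueError("degree parameters must be nonnegative")
    if a + b == 0:
        raise ValueError("a + b must be positive")
    return (a - b) ** 2 / (2.0 * (a + b))


def graph_to_connectome(g: Graph, label: str | None = None) -> ConnectomeMatrix:
    """View a binary/weighted graph as a ConnectomeMatrix (entries <= 1)."""
    if g.values.max(initial=0.0) > 1.0:
        raise ValueError("graph weights exceed 1; not representable as an FC")
    return ConnectomeMatrix(g.values.copy(), label=label if label is not None else g.label)
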
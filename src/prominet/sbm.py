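"""SBM parameter inference and the SNR weak-recovery statistic.

Given a graph ``G`` and an a priori partition ``sigma`` (both observed), the
stochastic-block-model parameters are inferred in closed form:

* ``p_i = Omega_i / n`` — community occupancy probabilities (law of large
  numbers);
* ``W = C / C_max`` — per-block-pair edge probability (binary mode: edge
  counts over available pairs) or mean absolute edge weight (weighted mode);
* ``Q = n W`` and the community profile matrix ``PQ = n P W``, whose entry
  (i, j) is the expected number of neighbors a community-i node has in
  community j (degree-scaling factor s_t = 1, the constant-degree regime).

The prominence statistic is ``SNR = lambda_2^2 / lambda_1`` over the
eigenvalues of PQ ordered by descending magnitude. ``SNR > 1`` (strictly) is
the Kesten-Stigum condition under which weak recovery of the partition is
efficiently solvable; below it the partition is information-theoretically
indistinct from noise at that graph scale.

PQ = nPW is similar to the symmetric matrix ``S = n P^{1/2} W P^{1/2}``
(conjugation by P^{1/2}), so its spectrum is real; eigenvalues are computed
on S to avoid nonsymmetric-solver noise. A direct dense eigensolve of PQ is
kept as an independent cross-check in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Graph, Partition

logger = logging.getLogger(__name__)

#: lambda_1 below this is treated as a degenerate (empty/ER) spectrum.
LAMBDA_TOL = 1e-12


@dataclass
class BlockCounts:
    """Per-block-pair edge statistics for one graph + partition.

    ``c[i, j]`` sums over unordered node pairs {u, v} with block labels
    {i+1, j+1}: the pair count in binary mode, the absolute-weight sum in
    weighted mode. ``c_max`` is the number of available pairs per block pair.
    """

    c: np.ndarray
    c_max: np.ndarray
    omega: np.ndarray
    mode: str


@dataclass
class SBMParams:
    """Inferred block-model quantities for one graph + partition + mode."""

    p: np.ndarray        # length-k occupancy probabilities, sums to 1
    w: np.ndarray        # k x k edge probability / mean |weight| matrix
    q: np.ndarray        # n * w, expected-degree contributions
    pq: np.ndarray       # community profile matrix n * diag(p) @ w
    n: int
    mode: str
    st: int = 1          # degree-scaling factor; 1 in the weak-recovery regime

    @property
    def k(self) -> int:
        return self.p.size

    @property
    def p_diag(self) -> np.ndarray:
        return np.diag(self.p)


@dataclass
class SNRValue:
    """The SNR statistic with its two leading eigenvalues."""

    snr: float
    lambda1: float
    lambda2: float

    @property
    def weakly_recoverable(self) -> bool:
        return self.snr > 1.0


def block_counts(g: Graph, part: Partition, cmax: str = "pairs") -> BlockCounts:
    """Accumulate per-block edge counts (binary) or |weight| sums (weighted).

    Parameters
    ----------
    cmax : {"pairs", "outer"}
        Pair-availability convention. ``"pairs"`` (default) excludes
        self-pairs: diagonal ``Omega_i (Omega_i - 1) / 2``, off-diagonal
        ``Omega_i Omega_j``, with ``c`` counting unordered pairs — the exact
        convention for simple graphs. ``"outer"`` uses the literal outer
        product ``Omega Omega^T`` with ordered-pair sums in ``c``; the two
        differ only in the diagonal by a self-pair term of order 1/Omega_i.
    """
    if g.n != part.n:
        raise ValueError(f"size mismatch: graph n={g.n}, partition n={part.n}")
    if cmax not in ("pairs", "outer"):
        raise ValueError(f"unknown cmax convention {cmax!r}")
    k = part.k
    omega = part.omega.astype(float)
    # indicator matrix: S[u, i] = 1 iff node u is in block i+1
    ind = np.zeros((g.n, k))
    ind[np.arange(g.n), part.sigma - 1] = 1.0
    ordered = ind.T @ g.values @ ind          # ordered-pair sums; diag = 2 * within
    if cmax == "pairs":
        c = ordered.copy()
        c[np.diag_indices(k)] /= 2.0          # unordered within-pairs
        c_max = np.outer(omega, omega)
        c_max[np.diag_indices(k)] = omega * (omega - 1) / 2.0
    else:
        c = ordered
        c = (c + c.T) / 2.0                   # symmetrize float noise
        c_max = np.outer(omega, omega)
    return BlockCounts(c=c, c_max=c_max, omega=part.omega.copy(), mode=g.mode)


def infer_sbm(counts: BlockCounts, n: int, mode: str | None = None) -> SBMParams:
    """Infer (P, W, Q, PQ) from block counts via the closed-form recipe.

    ``p = Omega / n``; ``W = C / C_max`` elementwise (block pairs with no
    available pairs, i.e. singleton-block diagonals, get W = 0); ``Q = n W``;
    ``PQ = n diag(p) W``.
    """
    if mode is None:
        mode = counts.mode
    omega = counts.omega
    if omega.min(initial=1) < 1 or omega.size == 0:
        raise ValueError("degenerate partition: empty community")
    p = omega / n
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(counts.c_max > 0, counts.c / np.where(counts.c_max > 0, counts.c_max, 1.0), 0.0)
    w = (w + w.T) / 2.0
    q = n * w
    pq = n * (p[:, None] * w)
    return SBMParams(p=p, w=w, q=q, pq=pq, n=n, mode=mode)


def snr(params: SBMParams) -> SNRValue:
    """SNR = lambda_2^2 / lambda_1 of the community profile matrix PQ.

    Eigenvalues are computed on the symmetric similar matrix
    ``S = n P^{1/2} W P^{1/2}`` and ordered by descending absolute value;
    lambda_1 is nonnegative (Perron-Frobenius on a nonnegative matrix).
    Degenerate cases — a single community, or lambda_1 at numerical zero
    (empty graph) — return SNR = 0 with a logged warning rather than erroring,
    so threshold sweeps over a full grid never abort.
    """
    if params.k < 2:
        logger.warning("single-community partition: SNR defined as 0")
        return SNRValue(0.0, float(params.pq[0, 0]) if params.pq.size else 0.0, 0.0)
    sqrtp = np.sqrt(params.p)
    sym = params.n * (sqrtp[:, None] * params.w * sqrtp[None, :])
    eigs = np.linalg.eigvalsh(sym)
    eigs = eigs[np.argsort(-np.abs(eigs), kind="stable")]
    lam1, lam2 = float(eigs[0]), float(eigs[1])
    if lam1 <= LAMBDA_TOL:
        logger.warning("degenerate spectrum (lambda1 <= %g): SNR defined as 0", LAMBDA_TOL)
        return SNRValue(0.0, lam1, lam2)
    return SNRValue(lam2 * lam2 / lam1, lam1, lam2)


def is_weak_recoverable(v: SNRValue) -> bool:
    """True iff SNR strictly exceeds the Kesten-Stigum hard threshold of 1."""
    return v.snr > 1.0


def graph_snr(g: Graph, part: Partition, cmax: str = "pairs") -> SNRValue:
    """Convenience composition: block_counts -> infer_sbm -> snr."""
    return snr(infer_sbm(block_counts(g, part, cmax=cmax), g.n))
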
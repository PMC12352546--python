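"""Core data types and text I/O for connectomes, partitions, and cohorts.

Conventions
-----------
* Node indices are 1-based in files and 0-based internally.
* Community labels are stored as contiguous integers ``1..k`` in order of
  first appearance in the input.
* Functional connectomes (FCs) are dense symmetric matrices of Pearson
  correlations; the diagonal is always coerced to zero on load, because every
  downstream edge sum runs over distinct node pairs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: maximum tolerated |A - A.T| entry in an input matrix (text round-off).
SYMMETRY_TOL = 1e-6
#: tolerated overshoot beyond |r| = 1 in an input correlation.
RANGE_TOL = 1e-6


class ConnectomeError(ValueError):
    """Raised when an input matrix or partition violates its contract."""


@dataclass
class ConnectomeMatrix:
    """A symmetric weighted connectivity matrix with zero diagonal.

    Attributes
    ----------
    values : (n, n) ndarray
        Pearson-correlation-valued entries in [-1, 1]; symmetric, zero diag.
    label : str
        Free-text identifier (subject, condition, "GA", ...).
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _validate_connectome(self.values)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _validate_connectome(a: np.ndarray) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ConnectomeError(f"shape error: expected square matrix, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ConnectomeError("range error: non-finite entries")
    asym = np.abs(a - a.T).max() if a.size else 0.0
    if asym > 1e-8:
        raise ConnectomeError(f"symmetry error: max |A - A.T| = {asym:g}")
    if np.abs(np.diagonal(a)).max(initial=0.0) > 0:
        raise ConnectomeError("diagonal must be zero")
    off = a[~np.eye(a.shape[0], dtype=bool)]
    if off.size and np.abs(off).max() > 1.0 + RANGE_TOL:
        raise ConnectomeError(f"range error: |entry| up to {np.abs(off).max():g} > 1")


@dataclass
class Partition:
    """A node-to-community assignment sigma with k labels and sizes omega.

    ``sigma[u]`` is the community label (1..k) of node ``u`` (0-based).
    """

    sigma: np.ndarray
    k: int = field(init=False)
    omega: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=int)
        if self.sigma.ndim != 1 or self.sigma.size == 0:
            raise ConnectomeError("partition must be a non-empty 1-d label vector")
        labels = np.unique(self.sigma)
        self.k = int(labels.size)
        if labels[0] != 1 or labels[-1] != self.k:
            raise ConnectomeError(
                "labels must be contiguous 1..k; use Partition.from_labels to relabel"
            )
        self.omega = np.bincount(self.sigma, minlength=self.k + 1)[1:]

    @property
    def n(self) -> int:
        return int(self.sigma.size)

    @classmethod
    def from_labels(cls, labels: Sequence) -> "Partition":
        """Build a Partition from arbitrary hashable labels.

        Labels are relabeled to contiguous ``1..k`` in order of first
        appearance, so the result is invariant under injective renamings.
        """
        seen: dict = {}
        sigma = np.empty(len(labels), dtype=int)
        for i, lab in enumerate(labels):
            if lab not in seen:
                seen[lab] = len(seen) + 1
            sigma[i] = seen[lab]
        return cls(sigma)


@dataclass
class CohortStack:
    """An ordered collection of subject connectomes sharing one parcellation."""

    matrices: list[ConnectomeMatrix]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ConnectomeError("cohort must contain at least one matrix")
        ns = {m.n for m in self.matrices}
        if len(ns) > 1:
            raise ConnectomeError(f"cohort shape error: mixed node counts {sorted(ns)}")

    @property
    def gamma(self) -> int:
        """Number of subjects Γ."""
        return len(self.matrices)

    @property
    def n(self) -> int:
        return self.matrices[0].n


@dataclass
class Graph:
    """A thresholded graph: binary adjacency or retained absolute weights.

    ``mode`` is ``"binary"`` (entries in {0, 1}) or ``"weighted"`` (retained
    absolute correlation magnitudes). Symmetric, zero diagonal.
    """

    mode: str
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "weighted"):
            raise ValueError(f"unknown graph mode {self.mode!r}")
        self.values = np.asarray(self.values, dtype=float)
        a = self.values
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ConnectomeError(f"shape error: expected square matrix, got {a.shape}")
        if np.abs(a - a.T).max(initial=0.0) > 1e-12:
            raise ConnectomeError("graph adjacency must be symmetric")
        if a.size and np.abs(np.diagonal(a)).max(initial=0.0) > 0:
            raise ConnectomeError("graph must have zero diagonal")
        if a.size and a.min() < 0:
            raise ConnectomeError("graph weights must be nonnegative")
        if self.mode == "binary" and a.size and not np.isin(a, (0.0, 1.0)).all():
            raise ConnectomeError("binary graph entries must be 0 or 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        """Number of edges (unordered node pairs with a nonzero entry)."""
        return int(np.count_nonzero(np.triu(self.values, k=1)))


def read_connectome(path, delimiter: str | None = None, label: str | None = None) -> ConnectomeMatrix:
    """Read a dense square correlation matrix from delimited text.

    The matrix is symmetrized as ``(A + A.T) / 2`` when the asymmetry is
    within tolerance, and a nonzero diagonal (raw Pearson FCs carry 1.0) is
    coerced to zero with a logged warning.

    Parameters
    ----------
    path : path-like
        Whitespace- or ``delimiter``-separated numeric text.
    delimiter : str, optional
        Column separator; ``None`` means any whitespace. Comma-separated
        files are auto-detected when ``delimiter`` is None.
    label : str, optional
        Identifier; defaults to the file stem.
    """
    path = Path(path)
    text = path.read_text()
    if delimiter is None and text.strip() and "," in text.splitlines()[0]:
        delimiter = ","
    try:
        a = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ConnectomeError(f"shape error: ragged or non-numeric matrix in {path}: {exc}") from None
    if a.shape[0] != a.shape[1]:
        raise ConnectomeError(f"shape error: {a.shape[0]}x{a.shape[1]} matrix in {path}")
    asym = np.abs(a - a.T).max(initial=0.0)
    if asym > SYMMETRY_TOL:
        raise ConnectomeError(f"symmetry error: max |A - A.T| = {asym:g} in {path}")
    a = (a + a.T) / 2.0
    if np.abs(np.diagonal(a)).max(initial=0.0) > 0:
        logger.warning("nonzero diagonal in %s coerced to 0 (self-loops excluded)", path)
        np.fill_diagonal(a, 0.0)
    off_max = np.abs(a).max(initial=0.0)
    if off_max > 1.0 + RANGE_TOL:
        raise ConnectomeError(f"range error: |entry| up to {off_max:g} > 1 in {path}")
    np.clip(a, -1.0, 1.0, out=a)
    return ConnectomeMatrix(a, label=label if label is not None else path.stem)


def read_partition(path, delimiter: str | None = None) -> Partition:
    """Read a two-column (node_index, community_label) partition file.

    Node indices must be contiguous ``1..n``; community labels may be any
    strings or integers and are relabeled to ``1..k`` by first appearance.
    """
    path = Path(path)
    rows: list[tuple[int, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(delimiter) if delimiter else line.replace(",", " ").split()
        if len(parts) != 2:
            raise ConnectomeError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        rows.append((int(parts[0]), parts[1]))
    if not rows:
        raise ConnectomeError(f"empty partition file {path}")
    n = len(rows)
    idx = [r[0] for r in rows]
    if len(set(idx)) != n:
        dup = sorted({i for i in idx if idx.count(i) > 1})
        raise ConnectomeError(f"duplicate error: node index repeated {dup} in {path}")
    missing = sorted(set(range(1, n + 1)) - set(idx))
    if missing:
        raise ConnectomeError(f"coverage error: node indices missing {missing} in {path}")
    labels_by_node = [lab for _, lab in sorted(rows)]
    return Partition.from_labels(labels_by_node)


def read_cohort(manifest, delimiter: str | None = None) -> CohortStack:
    """Load a cohort from a manifest listing one matrix path per line.

    Relative paths are resolved against the manifest's directory.
    """
    manifest = Path(manifest)
    paths = [
        line.strip()
        for line in manifest.read_text().splitlines()
        if line.strip() and not line.strip().startswith("#")
    ]
    if not paths:
        raise ConnectomeError(f"empty manifest {manifest}")
    mats = []
    for p in paths:
        p = Path(p)
        if not p.is_absolute():
            p = manifest.parent / p
        mats.append(read_connectome(p, delimiter=delimiter))
    return CohortStack(mats)


def write_connectome(fc: ConnectomeMatrix, path) -> None:
    """Write a connectome as whitespace-delimited text at 10 significant digits."""
    np.savetxt(path, fc.values, fmt="%.10g")


def write_partition(part: Partition, path) -> None:
    """Write a partition as two-column TSV (1-based node index, label)."""
    with open(path, "w") as fh:
        for u, lab in enumerate(part.sigma, 1):
            fh.write(f"{u}\t{lab}\n")


def write_table(rows: Iterable[Mapping], path, columns: Sequence[str] | None = None) -> None:
    """Write result records as TSV with a header.

    Rows are written in iteration order; floats at 10 significant digits so
    a read-back round-trips within 1e-9. An empty record list yields a
    header-only file (``columns`` must then be given).
    """
    rows = list(rows)
    if rows:
        df = pd.DataFrame(rows, columns=columns)
    else:
        if columns is None:
            raise ValueError("columns required to write an empty table")
        df = pd.DataFrame(columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
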
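"""Connectome containers, delimited-matrix I/O, and the two connectome constructors.

A connectome here is a square, symmetric, zero-diagonal weight matrix over a
fixed cortical parcellation (360 regions by default). Structural connectomes
(SC) carry non-negative streamline-derived weights; functional connectomes
(FC) carry Pearson correlations between regional time courses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Connectome",
    "read_connectome",
    "write_connectome",
    "fc_from_timeseries",
    "sc_from_streamline_counts",
]

#: tolerance beyond which asymmetry in an input matrix is a hard error
ASYMMETRY_TOL = 1e-8


@dataclass
class Connectome:
    """Square symmetric zero-diagonal weight matrix with a modality tag.

    Parameters
    ----------
    weights : (n, n) ndarray
        Edge weights. Structural: non-negative; functional: in [-1, 1].
    modality : {"structural", "functional"}
    node_ids : list of str, optional
        Region identifiers; defaults to "1".."n".
    """

    weights: np.ndarray
    modality: str
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError(f"weights must be square, got shape {self.weights.shape}")
        if self.modality not in ("structural", "functional"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not self.node_ids:
            self.node_ids = [str(i + 1) for i in range(self.n)]
        if len(self.node_ids) != self.n:
            raise ValueError(
                f"{len(self.node_ids)} node_ids for {self.n}x{self.n} matrix"
            )
        self.validate()

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def validate(self) -> None:
        w = self.weights
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite weights")
        if not np.array_equal(w, w.T):
            raise ValueError("weights not exactly symmetric")
        if np.any(np.diagonal(w) != 0):
            raise ValueError("diagonal not zero")
        if self.modality == "structural":
            if np.any(w < 0):
                raise ValueError("structural weights must be non-negative")
        else:
            if np.any(np.abs(w) > 1):
                raise ValueError("functional weights must lie in [-1, 1]")


def _symmetrize(w: np.ndarray, source: str) -> np.ndarray:
    """Check symmetry within ASYMMETRY_TOL, then symmetrize exactly by averaging."""
    delta = np.abs(w - w.T)
    if delta.size and delta.max() > ASYMMETRY_TOL:
        i, j = np.unravel_index(int(np.argmax(delta)), delta.shape)
        raise ValueError(
            f"{source}: asymmetry {delta[i, j]:.3g} at indices ({i}, {j}) "
            f"exceeds tolerance {ASYMMETRY_TOL:g}"
        )
    return (w + w.T) / 2.0


def read_connectome(
    path: str | Path, expected_n: int | None, modality: str = "structural"
) -> Connectome:
    """Read a delimited square weight matrix (comma or whitespace separated).

    The matrix must be ``expected_n`` x ``expected_n`` (any square size when
    ``expected_n`` is None) and symmetric within 1e-8 (then exactly
    symmetrized by averaging). A nonzero diagonal is forced to zero with a
    warning.
    """
    path = Path(path)
    text = path.read_text()
    rows: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split(",") if "," in line else line.split()
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell on line {lineno}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    ncols = {len(r) for r in rows}
    if len(ncols) != 1 or ncols.pop() != len(rows):
        raise ValueError(
            f"{path}: non-square matrix ({len(rows)} rows, "
            f"columns {sorted({len(r) for r in rows})})"
        )
    w = np.array(rows, dtype=float)
    if expected_n is not None and w.shape[0] != expected_n:
        raise ValueError(f"{path}: matrix is {w.shape[0]}x{w.shape[0]}, expected {expected_n}")
    w = _symmetrize(w, str(path))
    if np.any(np.diagonal(w) != 0):
        warnings.warn(f"{path}: nonzero diagonal entries forced to zero", stacklevel=2)
        np.fill_diagonal(w, 0.0)
    return Connectome(weights=w, modality=modality)


def write_connectome(conn: Connectome, path: str | Path) -> None:
    """Write comma-delimited with 17 significant digits (lossless round-trip)."""
    np.savetxt(path, conn.weights, delimiter=",", fmt="%.17g")


def fc_from_timeseries(ts: np.ndarray) -> Connectome:
    """Functional connectome from a T x n regional time-series matrix.

    Entry (i, j) is the Pearson correlation of columns i and j; the diagonal
    is set to zero. Zero-variance columns get an all-zero row/column with a
    warning (their correlations are undefined).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D (timepoints x regions) array")
    if ts.shape[0] < 3:
        raise ValueError(f"need >= 3 timepoints, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    bad = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts, rowvar=False)
    r = np.asarray(r, dtype=float)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance column(s); their correlations set to 0",
            stacklevel=2,
        )
        r[bad, :] = 0.0
        r[:, bad] = 0.0
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 0.0)
    return Connectome(weights=r, modality="functional")


def sc_from_streamline_counts(
    counts: np.ndarray, node_volumes: np.ndarray
) -> Connectome:
    """Structural connectome from streamline counts and node volumes (mm^3).

    Each edge weight is the streamline count scaled by the inverse volumes of
    its two endpoint regions::

        weight(i, j) = counts(i, j) * (1/vol_i + 1/vol_j) / 2
    """
    counts = np.asarray(counts, dtype=float)
    vol = np.asarray(node_volumes, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be square")
    if vol.shape != (counts.shape[0],):
        raise ValueError("node_volumes length must match matrix dimension")
    if np.any(vol <= 0):
        raise ValueError("node volumes must be strictly positive")
    if np.any(counts < 0):
        raise ValueError("streamline counts must be non-negative")
    counts = _symmetrize(counts, "streamline counts")
    inv = 1.0 / vol
    scale = (inv[:, None] + inv[None, :]) / 2.0
    w = counts * scale
    np.fill_diagonal(w, 0.0)
    return Connectome(weights=w, modality="structural")
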
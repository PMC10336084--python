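"""Group-level consistency-based thresholding of structural connectomes.

Tractography produces many spurious edges; edges whose weight varies wildly
across scans are the least trustworthy. We compute, for every edge, the
coefficient of variation (CV = sample SD / mean) of its weight across all
included scans — zeros counted as weights, since an absent edge is itself
evidence of inconsistency — and keep the edges whose CV falls at or below the
75th percentile of candidate-edge CVs. Edges with mean weight 0 are never
candidates. Nodes left with no surviving edges are excluded downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectomes import Connectome

__all__ = ["EdgeMask", "edge_cv", "consistency_mask", "apply_mask", "excluded_nodes"]

log = logging.getLogger(__name__)


@dataclass
class EdgeMask:
    """Binary symmetric edge-retention mask shared across scans."""

    mask: np.ndarray  # (n, n) 0/1, symmetric, zero diagonal
    cv_threshold: float  # the CV cutoff actually applied
    n_candidate_edges: int
    n_kept_edges: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("mask must be symmetric")
        if np.any(np.diagonal(self.mask) != 0):
            raise ValueError("mask diagonal must be zero")
        if not set(np.unique(self.mask)) <= {0, 1}:
            raise ValueError("mask must be binary")
        if self.n_kept_edges > self.n_candidate_edges:
            raise ValueError("kept edges exceed candidates")

    @property
    def n(self) -> int:
        return self.mask.shape[0]


def edge_cv(scans: list[Connectome] | np.ndarray) -> np.ndarray:
    """Per-edge coefficient of variation of weight across scans.

    Accepts a list of structural Connectomes or a pre-stacked (n_scans, n, n)
    array. CV uses the sample SD (n-1 denominator); edges whose mean weight is
    zero get CV = +inf (never kept). Result is symmetric with zero diagonal.
    """
    if isinstance(scans, np.ndarray):
        stack = np.asarray(scans, dtype=float)
        if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
            raise ValueError("stacked scans must have shape (n_scans, n, n)")
    else:
        if len(scans) < 2:
            raise ValueError(f"need >= 2 scans to compute CV, got {len(scans)}")
        n = scans[0].n
        for s in scans:
            if s.n != n:
                raise ValueError(f"mismatched dimensions: {s.n} vs {n}")
        stack = np.stack([s.weights for s in scans])
    if stack.shape[0] < 2:
        raise ValueError(f"need >= 2 scans to compute CV, got {stack.shape[0]}")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    cv = np.full_like(mean, np.inf)
    np.divide(sd, mean, out=cv, where=mean != 0)
    cv = (cv + cv.T) / 2.0  # exact: inputs are symmetric
    np.fill_diagonal(cv, np.inf)
    return cv


def consistency_mask(cv: np.ndarray, percentile: float = 75.0) -> EdgeMask:
    """Keep the most consistent edges: CV at or below the given percentile.

    The threshold is the linear-interpolation (type-7) quantile of the finite
    upper-triangle CVs; ties at the threshold are kept.
    """
    cv = np.asarray(cv, dtype=float)
    if cv.ndim != 2 or cv.shape[0] != cv.shape[1]:
        raise ValueError("cv must be square")
    if not np.array_equal(np.nan_to_num(cv, posinf=0.0), np.nan_to_num(cv.T, posinf=0.0)):
        raise ValueError("cv must be symmetric")
    iu = np.triu_indices(cv.shape[0], k=1)
    vals = cv[iu]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no finite CVs: nothing to threshold")
    thr = float(np.quantile(vals[finite], percentile / 100.0, method="linear"))
    keep = finite & (vals <= thr)
    mask = np.zeros_like(cv, dtype=np.int8)
    mask[iu] = keep.astype(np.int8)
    mask = mask + mask.T
    n_cand = int(finite.sum())
    n_kept = int(keep.sum())
    log.info(
        "consistency threshold: CV <= %.6g keeps %d of %d candidate edges (%.1f%%)",
        thr, n_kept, n_cand, 100.0 * n_kept / n_cand,
    )
    return EdgeMask(mask=mask, cv_threshold=thr,
                    n_candidate_edges=n_cand, n_kept_edges=n_kept)


def apply_mask(scan: Connectome, mask: EdgeMask) -> Connectome:
    """Zero out edges the mask rejects; modality and invariants preserved."""
    if scan.n != mask.n:
        raise ValueError(f"dimension mismatch: scan {scan.n}, mask {mask.n}")
    return Connectome(
        weights=scan.weights * mask.mask,
        modality=scan.modality,
        node_ids=list(scan.node_ids),
    )


def excluded_nodes(mask: EdgeMask) -> list[int]:
    """Zero-based indices of nodes with no surviving edges in the group mask.

    Such nodes have all-zero rows in every masked scan and are dropped from
    the coupling analysis for all scans.
    """
    degree = mask.mask.sum(axis=1)
    excl = [int(i) for i in np.flatnonzero(degree == 0)]
    if excl:
        log.info("excluding %d all-zero node(s): %s", len(excl), excl)
    return excl
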
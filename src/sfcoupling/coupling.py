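"""Regional structure-function coupling.

A region's coupling is the Spearman rank correlation between its structural
connectivity profile and its functional connectivity profile, restricted to
the entries where the (masked) structural weight is non-zero. FC zeros are
legitimate correlation values and are not excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import ScanRecord
from .connectomes import Connectome
from .threshold import EdgeMask, apply_mask, excluded_nodes

__all__ = ["CouplingProfile", "spearman_rho", "regional_coupling", "coupling_dataset"]

log = logging.getLogger(__name__)


@dataclass
class CouplingProfile:
    """Per-scan regional coupling: length-n vector of Spearman rho (NaN where
    undefined) plus the per-region count of profile edges used."""

    scan_key: tuple[str, int] | None
    rho: np.ndarray  # (n,) float, NaN = missing
    n_edges_used: np.ndarray  # (n,) int
    excluded: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        ok = np.isfinite(self.rho)
        if np.any(np.abs(self.rho[ok]) > 1 + 1e-12):
            raise ValueError("coupling values must lie in [-1, 1]")


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN when either vector is constant (correlation undefined).
    Raises on length mismatch or fewer than 3 pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need >= 3 pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx = rankdata(x)
    ry = rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return float("nan")
    return float(np.clip((rx @ ry) / denom, -1.0, 1.0))


def regional_coupling(
    sc: Connectome,
    fc: Connectome,
    min_edges: int = 3,
    excluded: list[int] | None = None,
    scan_key: tuple[str, int] | None = None,
) -> CouplingProfile:
    """Coupling profile of one scan.

    For region i the coupling is ``spearman_rho(sc[i, S], fc[i, S])`` with
    S = {j != i : sc[i, j] > 0}. Regions with |S| < min_edges, and regions in
    ``excluded``, get NaN. ``sc`` is expected to be consistency-masked already.
    """
    if sc.n != fc.n:
        raise ValueError(f"dimension mismatch: sc {sc.n}, fc {fc.n}")
    n = sc.n
    excluded = list(excluded) if excluded else []
    rho = np.full(n, np.nan)
    used = np.zeros(n, dtype=int)
    excl_set = set(excluded)
    for i in range(n):
        if i in excl_set:
            continue
        row = sc.weights[i]
        sel = np.flatnonzero(row > 0)
        sel = sel[sel != i]
        used[i] = sel.size
        if sel.size < min_edges:
            continue
        rho[i] = spearman_rho(row[sel], fc.weights[i, sel])
    return CouplingProfile(scan_key=scan_key, rho=rho, n_edges_used=used,
                           excluded=excluded)


def coupling_dataset(
    scans: list[tuple[ScanRecord, Connectome, Connectome]],
    mask: EdgeMask,
    min_edges: int = 3,
) -> pd.DataFrame:
    """Long coupling table: one row per (scan, non-excluded region).

    Each scan's SC is masked with the common consistency mask, its coupling
    profile computed, and the result stacked with the scan's covariates. Rows
    where rho is undefined are retained with ``missing = True`` — the
    trajectory models drop them per region. This table is the single input to
    the trajectory stage.
    """
    for rec, sc, fc in scans:
        if sc is None or fc is None:
            raise ValueError(f"scan {rec.subject_id} wave {rec.wave} lacks an SC/FC pair")
        if sc.n != mask.n or fc.n != mask.n:
            raise ValueError(f"scan {rec.subject_id} wave {rec.wave}: dimension mismatch")
    excl = excluded_nodes(mask)
    region_ids = [i for i in range(mask.n) if i not in set(excl)]
    frames = []
    for rec, sc, fc in scans:
        prof = regional_coupling(apply_mask(sc, mask), fc, min_edges=min_edges,
                                 excluded=excl, scan_key=rec.scan_key)
        frames.append(pd.DataFrame({
            "subject_id": rec.subject_id,
            "group": rec.group,
            "wave": rec.wave,
            "age": rec.age,
            "sex": rec.sex,
            "medicated": rec.medicated,
            "fd_dwi": rec.fd_dwi,
            "fd_fmri": rec.fd_fmri,
            "scanner": rec.scanner,
            "region": region_ids,
            "rho": prof.rho[region_ids],
            "n_edges_used": prof.n_edges_used[region_ids],
        }))
    table = pd.concat(frames, ignore_index=True)
    table["missing"] = ~np.isfinite(table["rho"].to_numpy())
    n_missing = int(table["missing"].sum())
    if n_missing:
        log.info("coupling table: %d of %d rows missing rho", n_missing, len(table))
    return table
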
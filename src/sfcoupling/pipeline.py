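"""End-to-end orchestration: QC -> thresholding -> coupling -> trajectories.

`analyze_scans` drives the in-memory pipeline on (record, SC, FC) triples;
`run_pipeline` wraps it with file I/O for shell use, writing every stage's
outputs plus a JSON manifest (configuration, stage counts, content hashes).
Rerunning with an identical configuration and inputs reproduces all result
CSVs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import RegionAtlas, qc_filter, read_cohort
from .connectomes import Connectome, read_connectome
from .coupling import coupling_dataset
from .gamm import SmoothSpec
from .threshold import EdgeMask, consistency_mask, edge_cv, excluded_nodes
from .trajectories import run_group_ladder, run_typical_development

__all__ = ["RunConfig", "analyze_scans", "run_pipeline", "summarize_by_network"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline settings; defaults are the study's stated choices
    (FD > 0.5 mm exclusion, 75th-percentile CV threshold, k = 4, alpha 0.05)."""

    cohort: str = "cohort.csv"
    sc_dir: str = "sc"
    fc_dir: str = "fc"
    out_dir: str = "results"
    n_nodes: int = 360
    percentile: float = 75.0
    min_edges: int = 3
    fd_limit: float = 0.5
    alpha: float = 0.05
    aic_margin: float = 2.0
    k: int = 4
    seed: int = 0
    analysis: str = "both"  # typical | group | both

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.analysis not in ("typical", "group", "both"):
            raise ValueError(f"unknown analysis {self.analysis!r}")
        if self.fd_limit <= 0 or self.alpha <= 0 or self.min_edges < 3:
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def analyze_scans(
    scans: list,
    config: RunConfig | None = None,
) -> dict:
    """Run thresholding, coupling and the trajectory analyses in memory.

    ``scans`` are (ScanRecord, sc Connectome, fc Connectome) triples that
    already passed QC. Returns a dict with the edge mask, excluded nodes, the
    long coupling table and the requested per-region result frames.
    """
    config = config or RunConfig()
    sc_list = [sc for _, sc, _ in scans]
    cv = edge_cv(sc_list)
    mask = consistency_mask(cv, percentile=config.percentile)
    table = coupling_dataset(scans, mask, min_edges=config.min_edges)
    spec = SmoothSpec(k=config.k)
    out = {
        "mask": mask,
        "excluded_nodes": excluded_nodes(mask),
        "coupling_table": table,
    }
    if config.analysis in ("typical", "both"):
        out["typical"] = run_typical_development(
            table, alpha=config.alpha, aic_margin=config.aic_margin, spec=spec)
    if config.analysis in ("group", "both"):
        out["group"] = run_group_ladder(
            table, alpha=config.alpha, aic_margin=config.aic_margin, spec=spec)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline: read cohort and per-scan matrices, run every
    stage, write stage outputs and a manifest under ``config.out_dir``.

    Expects matrices named {subject}_{wave}_sc.csv / {subject}_{wave}_fc.csv
    under sc_dir / fc_dir. Any stage failure aborts with the stage name and
    the offending item.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = read_cohort(config.cohort)
    kept, excluded = qc_filter(records, fd_limit=config.fd_limit)
    log.info("QC: kept %d scans, excluded %d (fd_fmri > %.2f mm)",
             len(kept), len(excluded), config.fd_limit)

    scans = []
    for rec in kept:
        sc_path = Path(config.sc_dir) / f"{rec.subject_id}_{rec.wave}_sc.csv"
        fc_path = Path(config.fc_dir) / f"{rec.subject_id}_{rec.wave}_fc.csv"
        try:
            sc = read_connectome(sc_path, config.n_nodes, modality="structural")
            fc = read_connectome(fc_path, config.n_nodes, modality="functional")
        except (OSError, ValueError) as exc:
            raise RuntimeError(
                f"stage load_connectomes failed for subject {rec.subject_id} "
                f"wave {rec.wave}: {exc}") from exc
        scans.append((rec, sc, fc))

    result = analyze_scans(scans, config)
    mask: EdgeMask = result["mask"]

    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)

    mask_path = out_dir / "edge_mask.csv"
    np.savetxt(mask_path, result["mask"].mask, delimiter=",", fmt="%d")
    written.append(mask_path)
    mask_json = out_dir / "edge_mask.json"
    mask_json.write_text(json.dumps({
        "cv_threshold": mask.cv_threshold,
        "n_candidate_edges": mask.n_candidate_edges,
        "n_kept_edges": mask.n_kept_edges,
        "excluded_nodes": result["excluded_nodes"],
    }, indent=2))
    written.append(mask_json)
    emit(result["coupling_table"], "coupling_table.csv")
    if "typical" in result:
        emit(result["typical"], "typical_results.csv")
    if "group" in result:
        emit(result["group"], "group_results.csv")

    manifest = {
        "config": asdict(config),
        "counts": {
            "scans_in": len(records),
            "scans_kept": len(kept),
            "scans_excluded_qc": len(excluded),
            "candidate_edges": mask.n_candidate_edges,
            "kept_edges": mask.n_kept_edges,
            "excluded_nodes": len(result["excluded_nodes"]),
            "coupling_rows": int(len(result["coupling_table"])),
        },
        "outputs": {p.name: _sha256(p) for p in written},
        "wall_time_s": round(time.time() - t0, 2),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    result["manifest"] = manifest
    return result


def summarize_by_network(
    results: pd.DataFrame, atlas: RegionAtlas
) -> tuple[pd.DataFrame, list[int]]:
    """Descriptive roll-up of per-region results by atlas network label.

    Counts significant regions per contrast and averages the fitted coupling
    change from age 9 to 14 within each network. Regions absent from the atlas
    are returned separately as ``unmapped`` and excluded from the roll-up.
    No inference is performed at the network level.
    """
    net_of = {nid - min(atlas.node_ids): net
              for nid, net in zip(atlas.node_ids, atlas.networks)}
    sig_cols = [c for c in results.columns if c.startswith("sig_")]
    change_cols = [c for c in results.columns if c.startswith("change_9_14")]
    unmapped = [int(r) for r in results["region"] if int(r) not in net_of]
    if unmapped:
        log.info("summarize_by_network: %d region(s) unmapped: %s",
                 len(unmapped), unmapped)
    mapped = results[[int(r) in net_of for r in results["region"]]].copy()
    mapped["network"] = [net_of[int(r)] for r in mapped["region"]]
    rows = []
    for net, ndf in mapped.groupby("network", sort=True):
        row = {"network": net, "n_regions": len(ndf)}
        for c in sig_cols:
            row[f"n_{c}"] = int(ndf[c].sum())
        for c in change_cols:
            row[f"mean_{c}"] = float(ndf[c].mean())
        rows.append(row)
    return pd.DataFrame(rows), unmapped
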
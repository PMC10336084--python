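"""Cohort table: per-scan records, the region atlas, and motion QC.

One ScanRecord describes one longitudinal observation (subject x wave) with
the demographic and nuisance variables the trajectory models adjust for.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "ScanRecord",
    "RegionAtlas",
    "read_cohort",
    "write_cohort",
    "read_atlas",
    "qc_filter",
    "COHORT_COLUMNS",
]

log = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "subject_id",
    "group",
    "wave",
    "age",
    "sex",
    "medicated",
    "fd_dwi",
    "fd_fmri",
    "scanner",
]

_GROUPS = {"control", "adhd"}
_SEXES = {"male", "female"}
_SCANNERS = {"pre_upgrade", "post_upgrade"}
_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


@dataclass(frozen=True)
class ScanRecord:
    """One scan: subject identity, diagnosis group, wave, age and covariates.

    fd_dwi / fd_fmri are mean frame-wise displacement (mm) of the diffusion
    and resting-state scans; scanner flags the hardware upgrade.
    """

    subject_id: str
    group: str  # control | adhd
    wave: int  # 1..3
    age: float  # years
    sex: str  # male | female
    medicated: bool
    fd_dwi: float  # mm
    fd_fmri: float  # mm
    scanner: str  # pre_upgrade | post_upgrade

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}, got {self.group!r}")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.scanner not in _SCANNERS:
            raise ValueError(f"scanner must be one of {_SCANNERS}, got {self.scanner!r}")
        if not 1 <= int(self.wave) <= 3:
            raise ValueError(f"wave must be 1-3, got {self.wave}")
        if self.fd_dwi < 0 or self.fd_fmri < 0:
            raise ValueError("frame-wise displacement must be >= 0")
        if not 8.0 <= self.age <= 16.0:
            warnings.warn(
                f"age {self.age:.2f} y outside plausible range [8, 16] "
                f"for subject {self.subject_id} wave {self.wave}",
                stacklevel=2,
            )

    @property
    def scan_key(self) -> tuple[str, int]:
        return (self.subject_id, int(self.wave))


@dataclass(frozen=True)
class RegionAtlas:
    """Parcellation lookup: region id -> label, hemisphere, functional network."""

    node_ids: tuple[int, ...]
    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]
    networks: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if not (len(self.labels) == len(self.hemispheres) == len(self.networks) == n):
            raise ValueError("atlas columns must have equal length")
        if sorted(self.node_ids) != list(range(min(self.node_ids), min(self.node_ids) + n)):
            raise ValueError("node ids must be contiguous and unique")
        if not set(self.hemispheres) <= {"L", "R"}:
            raise ValueError("hemisphere must be L or R")

    def __len__(self) -> int:
        return len(self.node_ids)

    def network_of(self, node_id: int) -> str | None:
        try:
            return self.networks[self.node_ids.index(node_id)]
        except ValueError:
            return None


def _parse_bool(value: str, row: int, col: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"row {row}: unparseable boolean {value!r} in column {col}")


def read_cohort(path: str | Path) -> list[ScanRecord]:
    """Read a cohort CSV (columns: subject_id, group, wave, age, sex,
    medicated, fd_dwi, fd_fmri, scanner). Categorical fields are parsed
    case-insensitively; duplicate (subject, wave) pairs are an error."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column{'s' if len(missing) > 1 else ''} "
                         + ", ".join(missing))
    records: list[ScanRecord] = []
    seen: set[tuple[str, int]] = set()
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # header is line 1
        try:
            rec = ScanRecord(
                subject_id=str(row["subject_id"]).strip(),
                group=str(row["group"]).strip().lower(),
                wave=int(row["wave"]),
                age=float(row["age"]),
                sex=str(row["sex"]).strip().lower(),
                medicated=_parse_bool(row["medicated"], rowno, "medicated"),
                fd_dwi=float(row["fd_dwi"]),
                fd_fmri=float(row["fd_fmri"]),
                scanner=str(row["scanner"]).strip().lower(),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {rowno}: {exc}") from None
        if rec.scan_key in seen:
            raise ValueError(
                f"{path}: duplicate scan for subject {rec.subject_id} wave {rec.wave}"
            )
        seen.add(rec.scan_key)
        records.append(rec)
    return records


def write_cohort(records: list[ScanRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "wave": r.wave,
                "age": f"{r.age:.4f}",
                "sex": r.sex,
                "medicated": r.medicated,
                "fd_dwi": f"{r.fd_dwi:.4f}",
                "fd_fmri": f"{r.fd_fmri:.4f}",
                "scanner": r.scanner,
            }
            for r in records
        ],
        columns=COHORT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_atlas(path: str | Path) -> RegionAtlas:
    """Read an atlas CSV with columns node_id, label, hemisphere, network."""
    df = pd.read_csv(path, dtype=str)
    for col in ("node_id", "label", "hemisphere", "network"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return RegionAtlas(
        node_ids=tuple(int(v) for v in df["node_id"]),
        labels=tuple(df["label"].astype(str)),
        hemispheres=tuple(df["hemisphere"].astype(str)),
        networks=tuple(df["network"].fillna("").astype(str)),
    )


def qc_filter(
    records: list[ScanRecord], fd_limit: float = 0.5
) -> tuple[list[ScanRecord], list[ScanRecord]]:
    """Exclude scans whose functional mean frame-wise displacement exceeds
    ``fd_limit`` (mm). The rule is strict: fd_fmri == fd_limit is kept.

    Returns (kept, excluded); the two lists partition the input.
    """
    kept, excluded = [], []
    for rec in records:
        if rec.fd_fmri > fd_limit:
            excluded.append(rec)
            log.info(
                "QC exclude subject %s wave %d: fd_fmri %.3f mm > %.3f mm",
                rec.subject_id, rec.wave, rec.fd_fmri, fd_limit,
            )
        else:
            kept.append(rec)
    return kept, excluded
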
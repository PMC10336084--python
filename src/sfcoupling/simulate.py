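"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a two-group developmental imaging
study — 91 ADHD and 84 control children, up to three scan waves ~18 months
apart between ages 9 and 14, with missing waves — and produces paired
structural/functional connectomes whose regional structure-function coupling
follows planted developmental trajectories.

Coupling is planted at the profile level through a Gaussian copula: for each
region, the functional profile is generated so that its Spearman correlation
with the structural profile hits a target value, using the exact bivariate
Gaussian relation r = 2 sin(pi * rho_s / 6). This gives the downstream
analysis exactly the structure it assumes, with known ground truth, without
any biophysical forward model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.special import ndtri
from scipy.stats import rankdata

from .cohort import ScanRecord
from .connectomes import Connectome

__all__ = [
    "Scenario",
    "SimConfig",
    "SimulatedStudy",
    "default_scenario_map",
    "simulate_cohort",
    "make_base_topology",
    "simulate_sc",
    "target_coupling",
    "calibrate_copula",
    "simulate_fc_given_sc",
    "simulate_dataset",
    "simulate_coupling_table",
]

log = logging.getLogger(__name__)

_KINDS = {"increasing", "increase_then_plateau", "group_offset", "group_by_age", "null"}

# fixed monotone squashing of the latent Gaussian profile into (-1, 1):
# fc = tanh(FC_LOC + FC_SCALE * u). Gives connected-pair FC centred near 0.25
# with spread ~0.35, typical of resting-state correlations.
FC_LOC = 0.25
FC_SCALE = 0.4
# unconnected pairs get weak noise correlations, sd ~ 0.12
FC_NULL_SCALE = 0.12


@dataclass(frozen=True)
class Scenario:
    """Planted developmental trajectory for one region's coupling.

    base_rho is the Spearman target at age 9; slopes are per-year changes.
    ``group_offset`` subtracts/adds a constant for the ADHD group (negative =
    weaker coupling in ADHD); ``group_by_age`` keeps controls flat while the
    ADHD group changes with age.
    """

    kind: str = "null"
    base_rho: float = 0.25
    slope_control: float = 0.04
    slope_adhd: float = 0.05
    plateau_age: float = 12.0
    offset_adhd: float = -0.10

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        for age in (9.0, 14.0):
            for group in ("control", "adhd"):
                t = target_coupling(self, group, age)
                if abs(t) > 0.95:
                    raise ValueError(
                        f"scenario implies coupling {t:.3f} outside [-0.95, 0.95]"
                    )


def target_coupling(scenario: Scenario, group: str, age: float) -> float:
    """Planted Spearman coupling target for one (region, group, age)."""
    s, da = scenario, age - 9.0
    if s.kind == "null":
        t = s.base_rho
    elif s.kind == "increasing":
        t = s.base_rho + s.slope_control * da
    elif s.kind == "increase_then_plateau":
        t = s.base_rho + s.slope_control * (min(age, s.plateau_age) - 9.0)
    elif s.kind == "group_offset":
        t = s.base_rho + (s.offset_adhd if group == "adhd" else 0.0)
    elif s.kind == "group_by_age":
        t = s.base_rho + (s.slope_adhd * da if group == "adhd" else 0.0)
    else:  # pragma: no cover - guarded by Scenario
        raise ValueError(f"unknown scenario kind {s.kind!r}")
    return float(np.clip(t, -0.95, 0.95))


def default_scenario_map(n_nodes: int = 360, seed: int = 2025) -> dict[int, Scenario]:
    """Default planted map: 20 increasing, 10 increase-then-plateau,
    10 group-offset, 10 group-by-age regions, the remainder null.

    Effect regions are spread over the parcellation by a seeded permutation so
    they do not align with the topology's community blocks.
    """
    counts = {"increasing": 20, "increase_then_plateau": 10,
              "group_offset": 10, "group_by_age": 10}
    total = sum(counts.values())
    if n_nodes < total:
        # small parcellations: scale the effect counts down proportionally
        counts = {k: max(1, int(round(v * n_nodes / (2 * total)))) for k, v in counts.items()}
        total = sum(counts.values())
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_nodes)
    smap: dict[int, Scenario] = {int(i): Scenario(kind="null") for i in range(n_nodes)}
    pos = 0
    for kind, c in counts.items():
        for i in order[pos:pos + c]:
            smap[int(i)] = Scenario(kind=kind)
        pos += c
    return smap


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate the reference sample: 91 ADHD / 84 control subjects, up
    to three waves ~1.4 years apart, first-wave age 10.4 (SD 0.5) years, and a
    per-wave retention giving ~278 scans after motion QC.
    """

    n_adhd: int = 91
    n_control: int = 84
    n_nodes: int = 360
    waves: int = 3
    wave_interval_mean: float = 1.4  # years
    wave_interval_jitter: float = 0.15  # years, uniform +/-
    age_w1_mean: float = 10.4  # years
    age_w1_sd: float = 0.5
    # per-wave attendance probability; every subject attends >= 1 wave, so the
    # expected cohort size is n_subjects * waves * retention / (1 - (1-r)^waves).
    # 0.44 puts the expectation at ~280 scans, ~278 after FD-based QC.
    retention: float = 0.44
    scenario_map: dict[int, Scenario] | None = None
    noise_sd: float = 0.05  # residual SD on planted coupling targets
    subject_sd: float = 0.02  # per-subject coupling offset SD
    # head-motion (mean FD, mm): lognormal with these means/SDs per group
    fd_dwi_mean: tuple[float, float] = (0.40, 0.35)  # (adhd, control)
    fd_dwi_sd: float = 0.15
    fd_fmri_mean: tuple[float, float] = (0.16, 0.13)
    fd_fmri_sd: float = 0.10
    prop_male: tuple[float, float] = (0.69, 0.56)  # (adhd, control)
    medicated_by_wave: tuple[float, ...] = (0.21, 0.19, 0.07)  # ADHD only
    # base-topology and scan-level SC parameters
    density: float = 0.55
    n_communities: int = 8
    subject_sigma: float = 0.4  # log-scale SD of per-scan edge factors
    dropout: float = 0.05  # fraction of base edges zeroed per scan
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adhd <= 0 or self.n_control <= 0 or self.n_nodes <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.retention <= 1:
            raise ValueError("retention must be in (0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.scenario_map is None:
            self.scenario_map = default_scenario_map(self.n_nodes)


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draws parameterized by their arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def simulate_cohort(config: SimConfig) -> list[ScanRecord]:
    """Draw the cohort table: subjects, attendance, ages, sex, motion.

    Attendance is one Bernoulli(retention) draw per wave, redrawn until at
    least one wave is attended; scanner is post-upgrade at wave 3 only.
    Deterministic given (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    records: list[ScanRecord] = []
    groups = ["adhd"] * config.n_adhd + ["control"] * config.n_control
    for idx, group in enumerate(groups):
        gi = 0 if group == "adhd" else 1
        sid = f"sub{idx + 1:03d}"
        sex = "male" if rng.random() < config.prop_male[gi] else "female"
        while True:
            attend = rng.random(config.waves) < config.retention
            if attend.any():
                break
        age = rng.normal(config.age_w1_mean, config.age_w1_sd)
        ages = [age]
        for _ in range(config.waves - 1):
            age += config.wave_interval_mean + rng.uniform(
                -config.wave_interval_jitter, config.wave_interval_jitter
            )
            ages.append(age)
        for w in range(config.waves):
            # draw per-wave covariates unconditionally so the record stream
            # stays aligned across configs; emit only attended waves
            fd_dwi = float(_lognormal(rng, config.fd_dwi_mean[gi], config.fd_dwi_sd))
            fd_fmri = float(_lognormal(rng, config.fd_fmri_mean[gi], config.fd_fmri_sd))
            med_p = config.medicated_by_wave[min(w, len(config.medicated_by_wave) - 1)]
            medicated = bool(group == "adhd" and rng.random() < med_p)
            if not attend[w]:
                continue
            records.append(ScanRecord(
                subject_id=sid,
                group=group,
                wave=w + 1,
                age=float(ages[w]),
                sex=sex,
                medicated=medicated,
                fd_dwi=fd_dwi,
                fd_fmri=fd_fmri,
                scanner="post_upgrade" if w == config.waves - 1 and config.waves >= 3
                        else "pre_upgrade",
            ))
    return records


def make_base_topology(
    n_nodes: int = 360,
    density: float = 0.55,
    n_communities: int = 8,
    seed: int = 0,
    max_retries: int = 100,
) -> Connectome:
    """Group-average structural topology: a stochastic block pattern with
    log-normal edge weights, within-community edges denser and heavier.

    Redraws until the graph is connected (error after ``max_retries``).
    """
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    comm = np.arange(n_nodes) % n_communities
    same = comm[:, None] == comm[None, :]
    iu = np.triu_indices(n_nodes, k=1)
    f_within = same[iu].mean()
    ratio = 3.0  # within-community edges ~3x more probable
    p_between = density / ((1 - f_within) + ratio * f_within)
    p_within = min(1.0, ratio * p_between)
    if p_within == 1.0:  # re-solve so the overall density is still met
        p_between = (density - f_within) / (1 - f_within)
    probs = np.where(same[iu], p_within, p_between)
    for _ in range(max_retries):
        present = rng.random(probs.shape) < probs
        w = rng.lognormal(0.0, 0.8, size=probs.shape)
        w *= np.where(same[iu], 2.0, 1.0)  # heavier within communities
        vals = np.where(present, w, 0.0)
        mat = np.zeros((n_nodes, n_nodes))
        mat[iu] = vals
        mat = mat + mat.T
        n_comp, _ = connected_components((mat > 0).astype(np.int8), directed=False)
        if n_comp == 1:
            return Connectome(weights=mat, modality="structural")
    raise RuntimeError(f"could not draw a connected topology in {max_retries} tries")


def simulate_sc(
    base: Connectome,
    subject_sigma: float = 0.4,
    dropout: float = 0.05,
    rng: np.random.Generator | int | None = 0,
) -> Connectome:
    """One scan's SC: base edges times iid log-normal factors (SD
    ``subject_sigma`` on the log scale), with a random ``dropout`` fraction of
    edges zeroed, symmetrically."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = base.n
    iu = np.triu_indices(n, k=1)
    vals = base.weights[iu].copy()
    if subject_sigma > 0:
        vals *= rng.lognormal(0.0, subject_sigma, size=vals.shape)
    if dropout > 0:
        vals[rng.random(vals.shape) < dropout] = 0.0
    w = np.zeros((n, n))
    w[iu] = vals
    w = w + w.T
    return Connectome(weights=w, modality="structural", node_ids=list(base.node_ids))


def calibrate_copula(target_spearman: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose Spearman correlation
    equals the target: r = 2 sin(pi * rho_s / 6)."""
    if abs(target_spearman) >= 1:
        raise ValueError("target Spearman must satisfy |rho| < 1")
    return float(2.0 * np.sin(np.pi * target_spearman / 6.0))


def _rank_scores(sc_weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row normal scores of edge-weight ranks over each row's support.

    Returns (Z, support) where Z[i, j] is the normal score of SC[i, j]'s rank
    within row i (0 off support) and support is the boolean edge mask.
    """
    n = sc_weights.shape[0]
    support = sc_weights > 0
    np.fill_diagonal(support, False)
    z = np.zeros((n, n))
    for i in range(n):
        sel = np.flatnonzero(support[i])
        m = sel.size
        if m:
            z[i, sel] = ndtri(rankdata(sc_weights[i, sel]) / (m + 1))
    return z, support


def _solve_row_correlations(rho_lat: np.ndarray, support: np.ndarray,
                            coherence: float, n_iter: int = 20) -> np.ndarray:
    """Per-row copula correlations that realize latent targets after the
    (i, j) / (j, i) constructions are averaged.

    The averaged latent w_ij = (u_i + u_j)/2 has
    corr(w_i., z_i.) = (r_i + c rbar_i) / sqrt(2 (1 + c r_i rbar_i)), where c
    is the coherence between the two rows' rank scores of a shared edge and
    rbar_i the mean r over row i's neighbours; solve for r by fixed point.
    """
    r = rho_lat.copy()
    deg = np.maximum(support.sum(axis=1), 1)
    for _ in range(n_iter):
        rbar = (support @ r) / deg
        r_new = rho_lat * np.sqrt(2.0 * (1.0 + coherence * r * rbar)) \
            - coherence * rbar
        r = np.clip(r_new, -0.99, 0.99)
    return r


def simulate_fc_given_sc(
    sc: Connectome,
    targets: np.ndarray,
    rng: np.random.Generator | int | None = 0,
    min_support: int = 3,
) -> Connectome:
    """FC matrix whose regional coupling with ``sc`` tracks per-node targets.

    For node i, a latent Gaussian profile over its non-zero SC neighbours is
    built as r_i * z(rank(SC_i.)) + sqrt(1 - r_i^2) * eps; the full matrix
    averages the (i, j) and (j, i) constructions and squashes the result
    monotonically into (-1, 1). Averaging would attenuate realized coupling
    below the targets, so the per-row correlations r are solved from the
    symmetrization-aware calibration (see _solve_row_correlations) with the
    rank coherence between rows estimated from the SC itself; the Spearman ->
    Pearson step uses calibrate_copula. SC-zero pairs get weak noise
    correlations. Nodes with fewer than ``min_support`` neighbours get
    pure-noise profiles.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (sc.n,):
        raise ValueError("targets must be a length-n vector")
    if np.any(np.abs(targets) >= 1):
        raise ValueError("targets must lie in (-1, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = sc.n
    z, support = _rank_scores(sc.weights)
    # rank coherence: how similar an edge's rank is in its two endpoint rows
    iu = np.triu_indices(n, k=1)
    both = support[iu]
    za, zb = z[iu][both], z.T[iu][both]
    if za.size >= 10 and za.std() > 0:
        coherence = float(np.clip(np.corrcoef(za, zb)[0, 1], 0.0, 0.99))
    else:
        coherence = 0.0
    rho_lat = np.array([calibrate_copula(t) for t in targets])
    m_row = support.sum(axis=1)
    low = m_row < min_support
    rho_lat[low] = 0.0
    if int(low.sum()):
        log.info("FC generator: %d node(s) with < %d neighbours got noise profiles",
                 int(low.sum()), min_support)
    r = _solve_row_correlations(rho_lat, support, coherence)
    eps = rng.standard_normal((n, n))
    u = (r[:, None] * z + np.sqrt(1.0 - r[:, None] ** 2) * eps) * support
    w = (u + u.T) / 2.0
    fc = np.where(support, np.tanh(FC_LOC + FC_SCALE * np.sqrt(2.0) * w),
                  np.tanh(FC_NULL_SCALE * (eps + eps.T) / np.sqrt(2.0)))
    fc = (fc + fc.T) / 2.0  # exact symmetry (support and w already symmetric)
    np.fill_diagonal(fc, 0.0)
    return Connectome(weights=fc, modality="functional", node_ids=list(sc.node_ids))


@dataclass
class SimulatedStudy:
    """Everything one synthetic study run produced, ground truth included."""

    config: SimConfig
    records: list[ScanRecord]
    base: Connectome
    scans: list[tuple[ScanRecord, Connectome, Connectome]]
    planted: "np.ndarray"  # (n_scans, n_nodes) per-scan planted targets

    def ground_truth(self) -> dict:
        """JSON-serializable ground truth for recovery checks."""
        return {
            "scenario_map": {
                str(i): asdict(s) for i, s in sorted(self.config.scenario_map.items())
            },
            "planted_targets": {
                f"{rec.subject_id}_{rec.wave}": self.planted[k].round(6).tolist()
                for k, (rec, _, _) in enumerate(self.scans)
            },
        }

    def scenario_kinds(self) -> dict[int, str]:
        return {i: s.kind for i, s in self.config.scenario_map.items()}


def _planted_targets(config: SimConfig, rec: ScanRecord, subj_offset: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    t = np.array([
        target_coupling(config.scenario_map[i], rec.group, rec.age)
        for i in range(config.n_nodes)
    ])
    t = t + subj_offset + rng.normal(0.0, config.noise_sd, size=config.n_nodes)
    return np.clip(t, -0.95, 0.95)


def simulate_dataset(config: SimConfig) -> SimulatedStudy:
    """Full synthetic study: cohort + per-scan SC/FC pairs + ground truth.

    Per-scan coupling targets are the scenario trajectory evaluated at the
    scan's (group, age), plus a per-subject offset (SD ``subject_sd``) and
    per-scan residual noise (SD ``noise_sd``).
    """
    records = simulate_cohort(config)
    rng = np.random.default_rng(config.seed + 1)
    base = make_base_topology(config.n_nodes, config.density, config.n_communities,
                              seed=config.seed + 2)
    subj_ids = sorted({r.subject_id for r in records})
    offsets = {
        s: rng.normal(0.0, config.subject_sd, size=config.n_nodes) for s in subj_ids
    }
    scans = []
    planted = np.zeros((len(records), config.n_nodes))
    for k, rec in enumerate(records):
        sc = simulate_sc(base, config.subject_sigma, config.dropout, rng)
        planted[k] = _planted_targets(config, rec, offsets[rec.subject_id], rng)
        fc = simulate_fc_given_sc(sc, planted[k], rng)
        scans.append((rec, sc, fc))
    return SimulatedStudy(config=config, records=records, base=base,
                          scans=scans, planted=planted)


def simulate_coupling_table(
    records: list[ScanRecord],
    scenario_map: dict[int, Scenario],
    noise_sd: float = 0.05,
    subject_sd: float = 0.02,
    fd_effect: float = 0.0,
    seed: int = 0,
):
    """Directly simulate the long coupling table (no connectomes).

    Useful for calibration studies of the trajectory models: rho is the
    scenario target plus a subject offset, optional linear fd_fmri effect
    (``fd_effect`` per mm), and iid residual noise.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    regions = sorted(scenario_map)
    subj_ids = sorted({r.subject_id for r in records})
    offsets = {s: rng.normal(0.0, subject_sd, size=len(regions)) for s in subj_ids}
    frames = []
    for rec in records:
        t = np.array([target_coupling(scenario_map[i], rec.group, rec.age)
                      for i in regions])
        rho = (t + offsets[rec.subject_id] + fd_effect * rec.fd_fmri
               + rng.normal(0.0, noise_sd, size=len(regions)))
        frames.append(pd.DataFrame({
            "subject_id": rec.subject_id, "group": rec.group, "wave": rec.wave,
            "age": rec.age, "sex": rec.sex, "medicated": rec.medicated,
            "fd_dwi": rec.fd_dwi, "fd_fmri": rec.fd_fmri, "scanner": rec.scanner,
            "region": regions, "rho": np.clip(rho, -1, 1),
            "n_edges_used": len(regions), "missing": False,
        }))
    return pd.concat(frames, ignore_index=True)
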
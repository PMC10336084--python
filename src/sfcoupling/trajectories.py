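"""Regional developmental-trajectory inference on the coupling table.

Two analyses mirror the study design:

* ``run_typical_development`` — controls only; per region, a null covariate
  model (M0) against a model adding a penalized smooth of age (M1), compared
  by likelihood-ratio test, with BH-FDR across regions.
* ``run_group_ladder`` — both groups; the nested ladder M0 (covariates) ->
  M1 (+ smooth age) -> M2 (+ group) -> M3 (+ group-specific smooth deviation),
  each stage tested by LRT and an AIC-improvement rule, FDR applied separately
  to the group and interaction p-value families.

All models carry mean frame-wise displacement of the diffusion and functional
scans, scanner upgrade, sex and medication as covariates, plus a subject
random intercept. Stage LRTs are computed unconditionally along the ladder;
`selected` follows the strict sequential rule while `label` names the deepest
stage that passes its own LRT + AIC criterion, which is the region's
winning-contrast classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gamm import (
    ModelFit,
    SmoothSpec,
    SmoothTerm,
    SplineBasis,
    bh_fdr,
    fit_gamm,
    lrt,
    select_model,
    spline_basis,
)

__all__ = [
    "LadderResult",
    "build_region_models",
    "run_typical_development",
    "run_group_ladder",
]

log = logging.getLogger(__name__)

_COVARIATES = ("fd_dwi", "fd_fmri", "scanner", "sex", "medicated")


def _encode_covariates(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric covariate matrix; zero-variance columns are dropped (logged)."""
    cols, names = [], []
    raw = {
        "fd_dwi": df["fd_dwi"].to_numpy(dtype=float),
        "fd_fmri": df["fd_fmri"].to_numpy(dtype=float),
        "scanner": (df["scanner"] == "post_upgrade").to_numpy(dtype=float),
        "sex": (df["sex"] == "male").to_numpy(dtype=float),
        "medicated": df["medicated"].astype(bool).to_numpy(dtype=float),
    }
    for name in _COVARIATES:
        v = raw[name]
        if np.ptp(v) == 0:
            log.debug("covariate %s constant in this subset; dropped", name)
            continue
        cols.append(v)
        names.append(name)
    x = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return x, names


@dataclass
class RegionModels:
    """Design machinery for one region's ladder: shared basis + fit method."""

    df: pd.DataFrame
    basis: SplineBasis
    x0: np.ndarray  # intercept + covariates
    names0: list[str]
    group: np.ndarray  # 1 = adhd
    subjects: np.ndarray
    ages: np.ndarray

    def fit(self, model_id: str) -> ModelFit:
        x_null, z_pen = self.basis.terms(self.ages)
        g = self.group[:, None]
        if model_id == "M0":
            return fit_gamm(self.df["rho"].to_numpy(), self.x0, [],
                            self.subjects, model_id="M0", coef_names=self.names0)
        if model_id == "M1":
            sm = [SmoothTerm("s_age", x_null, z_pen)]
            return fit_gamm(self.df["rho"].to_numpy(), self.x0, sm,
                            self.subjects, model_id="M1", coef_names=self.names0)
        if model_id == "M2":
            x = np.hstack([self.x0, g])
            sm = [SmoothTerm("s_age", x_null, z_pen)]
            return fit_gamm(self.df["rho"].to_numpy(), x, sm, self.subjects,
                            model_id="M2", coef_names=self.names0 + ["group_adhd"])
        if model_id == "M3":
            x = np.hstack([self.x0, g])
            sm = [SmoothTerm("s_age", x_null, z_pen),
                  SmoothTerm("s_age_by_group", x_null * g, z_pen * g)]
            return fit_gamm(self.df["rho"].to_numpy(), x, sm, self.subjects,
                            model_id="M3", coef_names=self.names0 + ["group_adhd"])
        raise ValueError(f"unknown model id {model_id!r}")

    def age_curve(
        self, fit: ModelFit, ages: np.ndarray, group: int = 0
    ) -> np.ndarray:
        """Fitted coupling over an age grid, covariates at their means."""
        x_null, z_pen = self.basis.terms(ages)
        p0 = self.x0.shape[1]
        covmeans = self.x0.mean(axis=0)
        yhat = np.full(len(ages), float(covmeans @ fit.beta[:p0]))
        pos = p0
        if fit.model_id in ("M2", "M3"):
            yhat += fit.beta[pos] * group
            pos += 1
        if fit.model_id != "M0":
            n0 = x_null.shape[1]
            yhat += x_null @ fit.beta[pos:pos + n0]
            yhat += z_pen @ fit.smooth_coefs("s_age")
            pos += n0
        if fit.model_id == "M3":
            n0 = x_null.shape[1]
            yhat += group * (x_null @ fit.beta[pos:pos + n0])
            yhat += group * (z_pen @ fit.smooth_coefs("s_age_by_group"))
        return yhat


def build_region_models(
    region_df: pd.DataFrame, spec: SmoothSpec = SmoothSpec()
) -> RegionModels:
    """Complete-case design machinery for one region's rows."""
    df = region_df[np.isfinite(region_df["rho"].to_numpy(dtype=float))]
    ages = df["age"].to_numpy(dtype=float)
    basis = spline_basis(ages, spec)
    covs, cnames = _encode_covariates(df)
    x0 = np.hstack([np.ones((len(df), 1)), covs])
    return RegionModels(
        df=df, basis=basis, x0=x0, names0=["intercept"] + cnames,
        group=(df["group"] == "adhd").to_numpy(dtype=float),
        subjects=df["subject_id"].to_numpy(),
        ages=ages,
    )


@dataclass
class LadderResult:
    """Per-region ladder outcome: fits, stage LRTs, selection and label."""

    region: int
    fits: dict[str, ModelFit]
    p_age: float
    p_group: float
    p_interaction: float
    delta_aic: dict[str, float]
    selected: str
    label: str


def _stage(simple: ModelFit, complex_: ModelFit) -> tuple[float, float, float]:
    dev, _, p = lrt(simple, complex_)
    return dev, p, complex_.aic - simple.aic


def run_typical_development(
    table: pd.DataFrame,
    alpha: float = 0.05,
    aic_margin: float = 2.0,
    spec: SmoothSpec = SmoothSpec(),
    min_rows: int = 10,
    age_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Age-effect analysis in controls: M0 (covariates) vs M1 (+ smooth age).

    Returns one row per region with the LRT p-value, BH-FDR q-value across
    regions, the selected model, and the fitted coupling change from age 9 to
    14 under M1 (for plotting / network roll-ups). Regions with fewer than
    ``min_rows`` usable rows are skipped with a log entry.
    """
    controls = table[table["group"] == "control"]
    rows = []
    grid = age_grid if age_grid is not None else np.array([9.0, 14.0])
    for region, rdf in controls.groupby("region", sort=True):
        usable = rdf[np.isfinite(rdf["rho"].to_numpy(dtype=float))]
        if len(usable) < min_rows:
            log.info("region %s skipped: %d usable rows < %d", region, len(usable), min_rows)
            continue
        rm = build_region_models(rdf, spec)
        m0, m1 = rm.fit("M0"), rm.fit("M1")
        dev, p, daic = _stage(m0, m1)
        curve = rm.age_curve(m1, grid)
        selected = select_model([m0, m1], alpha=alpha, aic_margin=aic_margin)
        rows.append({
            "region": region, "n_obs": m0.n_obs,
            "loglik_m0": m0.loglik, "loglik_m1": m1.loglik,
            "aic_m0": m0.aic, "aic_m1": m1.aic,
            "dev_age": dev, "p_age": p, "delta_aic_age": daic,
            "selected": selected, "edf_m1": m1.edf,
            "change_9_14": float(curve[-1] - curve[0]),
        })
    res = pd.DataFrame(rows)
    if len(res):
        q, rej = bh_fdr(res["p_age"].to_numpy(), alpha=alpha)
        res["q_age"] = q
        res["sig_age"] = rej
    return res


def run_group_ladder(
    table: pd.DataFrame,
    alpha: float = 0.05,
    aic_margin: float = 2.0,
    spec: SmoothSpec = SmoothSpec(),
    min_rows: int = 10,
    keep_fits: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[int, LadderResult]]:
    """Full-sample four-model ladder per region.

    Stage LRTs (age: M0 vs M1, group: M1 vs M2, interaction: M2 vs M3) are
    computed unconditionally; `selected` applies the sequential forward rule;
    `label` is the deepest stage passing its own LRT + AIC criterion. BH-FDR
    is applied separately to the age, group and interaction p-value families
    across regions. Regions missing a group entirely are skipped.
    """
    rows, ladders = [], {}
    for region, rdf in table.groupby("region", sort=True):
        usable = rdf[np.isfinite(rdf["rho"].to_numpy(dtype=float))]
        if len(usable) < min_rows:
            log.info("region %s skipped: %d usable rows < %d", region, len(usable), min_rows)
            continue
        if usable["group"].nunique() < 2:
            log.info("region %s skipped: only one group present", region)
            continue
        rm = build_region_models(rdf, spec)
        fits = {mid: rm.fit(mid) for mid in ("M0", "M1", "M2", "M3")}
        dev_a, p_a, daic_a = _stage(fits["M0"], fits["M1"])
        dev_g, p_g, daic_g = _stage(fits["M1"], fits["M2"])
        dev_i, p_i, daic_i = _stage(fits["M2"], fits["M3"])
        selected = select_model([fits[m] for m in ("M0", "M1", "M2", "M3")],
                                alpha=alpha, aic_margin=aic_margin)
        passes = {
            "age": p_a < alpha and daic_a <= -aic_margin,
            "group": p_g < alpha and daic_g <= -aic_margin,
            "interaction": p_i < alpha and daic_i <= -aic_margin,
        }
        label = ("interaction" if passes["interaction"]
                 else "group" if passes["group"]
                 else "age" if passes["age"] else "null")
        beta_group = float(fits["M2"].beta[fits["M2"].coef_names.index("group_adhd")])
        grid = np.array([9.0, 14.0])
        curve_ctl = rm.age_curve(fits["M3"], grid, group=0)
        curve_adhd = rm.age_curve(fits["M3"], grid, group=1)
        rows.append({
            "region": region, "n_obs": fits["M0"].n_obs,
            **{f"loglik_{m.lower()}": fits[m].loglik for m in fits},
            **{f"aic_{m.lower()}": fits[m].aic for m in fits},
            **{f"edf_{m.lower()}": fits[m].edf for m in fits},
            "dev_age": dev_a, "p_age": p_a, "delta_aic_age": daic_a,
            "dev_group": dev_g, "p_group": p_g, "delta_aic_group": daic_g,
            "dev_interaction": dev_i, "p_interaction": p_i,
            "delta_aic_interaction": daic_i,
            "selected": selected, "label": label, "beta_group": beta_group,
            "change_9_14_control": float(curve_ctl[1] - curve_ctl[0]),
            "change_9_14_adhd": float(curve_adhd[1] - curve_adhd[0]),
        })
        if keep_fits:
            ladders[int(region)] = LadderResult(
                region=int(region), fits=fits, p_age=p_a, p_group=p_g,
                p_interaction=p_i,
                delta_aic={"age": daic_a, "group": daic_g, "interaction": daic_i},
                selected=selected, label=label,
            )
    res = pd.DataFrame(rows)
    if len(res):
        for fam in ("age", "group", "interaction"):
            q, rej = bh_fdr(res[f"p_{fam}"].to_numpy(), alpha=alpha)
            res[f"q_{fam}"] = q
            res[f"sig_{fam}"] = rej
    return (res, ladders) if keep_fits else res
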
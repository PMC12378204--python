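"""Calibrated control condition and the perturbation re-simulation protocol.

Condition-to-condition changes extracted from imaging enter the simulation
as a proportionate change in the means of the methylation rate and the
chromatin-lamina affinity, holding the heterogeneity (CVs, correlation
lengths), geometry and seeds fixed.  The panel below carries the extracted
parameter changes for the five perturbations studied:

====================  ==========  ==========  =======================
condition             Gamma_me x  V_LAD x     biology
====================  ==========  ==========  =======================
hmt_inhibition        0.64        1.0         EZH2/HMT inhibitor (GSK)
hdac_inhibition       0.78        0.89        HDAC inhibitor (TSA)
contractility_loss    1.12        1.26        ROCK inhibitor (Y27)
glass_substrate       0.801       0.855       soft -> glass stiffness
tendinosis            1.30        1.116       diseased tenocytes
====================  ==========  ==========  =======================

The control simulation is calibrated once (parameters below) so that its
steady state shows discrete interior heterochromatin domains together with
peripheral LADs on a desk-scale square nucleus; every condition is reported
as the percent change of the mean interior domain radius and of the mean
LAD thickness relative to the control, averaged over matched seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domains import binarize_heterochromatin, label_domains, \
    lad_thickness_from_mask
from .geometry import make_geometry
from .model import ModelParams
from .simulate import Integrator, run_to_steady_state, sample_parameter_fields

__all__ = ["CONDITIONS", "ControlConfig", "run_condition", "run_panel",
           "percent_changes"]

#: (Gamma_me scale, V_LAD scale) per condition
CONDITIONS: dict[str, tuple[float, float]] = {
    "hmt_inhibition": (0.64, 1.0),
    "hdac_inhibition": (0.78, 0.89),
    "contractility_loss": (1.12, 1.26),
    "glass_substrate": (0.801, 0.855),
    "tendinosis": (1.30, 1.116),
}


@dataclass(frozen=True)
class ControlConfig:
    """Calibrated desk-scale control simulation.

    The geometry is a square nucleus (fast spectral stepping); physical
    parameters follow the model defaults (c, kappa in the printed range,
    interface width 12.5 nm); kinetics and affinity are calibrated so the
    control steady state shows discrete interior domains coexisting with
    peripheral LADs.  All perturbations reuse this geometry and the same
    seeds (common random numbers).
    """

    half_side: float = 600.0          # nm
    h: float = 6.25                   # nm
    c: float = 8e-3                   # pN/nm^2
    kappa: float = 1.25               # pN
    phi_h0: float = 0.8
    d0: float = 2.5                   # nm
    gamma_ac: float = 1.0e-7          # 1/s
    gamma_me_mean: float = 1.857e-7   # 1/s  (control methylation rate)
    vlad_mean: float = 0.02           # pN nm / nm^2 (control affinity)
    cv_gamma_me: float = 0.5
    cv_vlad: float = 0.5
    xi: float = 80.0                  # nm, interior correlation length
    xi_boundary: float = 600.0        # nm, affinity correlation along arc
    chromatin_fraction: float = 0.5
    dt_factor: float = 0.5            # dt in units of kappa/(M c^2)
    max_steps: int = 10000
    check_every: int = 500
    tol: float = 0.02

    def params(self) -> ModelParams:
        return ModelParams(c=self.c, kappa=self.kappa, phi_h0=self.phi_h0,
                           d0=self.d0, Gamma_ac=self.gamma_ac)

    def geometry(self):
        return make_geometry("square", self.half_side, self.h)


def _measure(field, geom, params):
    hc = binarize_heterochromatin(field, params=params)
    table = label_domains(hc, geom)
    interior = table[table["type"] == "interior"]
    prof = lad_thickness_from_mask(hc, geom, table=table)
    r_mean = float(interior["R_d_nm"].mean()) if len(interior) else np.nan
    return dict(n_interior=int(len(interior)), mean_R_d=r_mean,
                mean_T_LAD=float(prof.mean_thickness),
                peripheral_fraction=float(prof.peripheral_fraction),
                table=table, profile=prof)


def run_condition(cfg: ControlConfig, gamma_scale: float, vlad_scale: float,
                  seeds, integrator: Integrator | None = None,
                  geom=None, params=None) -> list[dict]:
    """Steady-state runs at scaled parameter means, one per seed.

    The seed controls both the heterogeneity fields and the initial noise,
    so a perturbed run is paired with the control run of the same seed
    (common random numbers).
    """
    params = params or cfg.params()
    geom = geom if geom is not None else cfg.geometry()
    integ = integrator or Integrator(geom, params)
    tc = params.kappa / (params.M_d * params.c ** 2)
    out = []
    for seed in seeds:
        pf = sample_parameter_fields(
            geom, mean_gamma_me=cfg.gamma_me_mean * gamma_scale,
            cv_gamma_me=cfg.cv_gamma_me, gamma_ac=cfg.gamma_ac,
            mean_vlad=cfg.vlad_mean * vlad_scale, cv_vlad=cfg.cv_vlad,
            xi=cfg.xi, xi_boundary=cfg.xi_boundary, seed=seed)
        ss = run_to_steady_state(
            geom, pf, params, seed=seed + 1, tol=cfg.tol,
            max_steps=cfg.max_steps, check_every=cfg.check_every,
            chromatin_fraction=cfg.chromatin_fraction,
            dt=cfg.dt_factor * tc, integrator=integ)
        m = _measure(ss.field, geom, params)
        m["seed"] = seed
        m["converged"] = ss.converged
        out.append(m)
    return out


def percent_changes(control: list[dict], perturbed: list[dict]) -> dict:
    """Percent change of mean R_d and mean T_LAD, seed-paired."""
    def seed_mean(runs, key):
        vals = [r[key] for r in runs if np.isfinite(r[key])]
        return float(np.mean(vals)) if vals else np.nan

    r0 = seed_mean(control, "mean_R_d")
    t0 = seed_mean(control, "mean_T_LAD")
    r1 = seed_mean(perturbed, "mean_R_d")
    t1 = seed_mean(perturbed, "mean_T_LAD")
    return dict(
        control_R_d=r0, control_T_LAD=t0,
        perturbed_R_d=r1, perturbed_T_LAD=t1,
        dR_d_pct=100.0 * (r1 - r0) / r0 if r0 else np.nan,
        dT_LAD_pct=100.0 * (t1 - t0) / t0 if t0 else np.nan,
    )


def run_panel(cfg: ControlConfig | None = None, conditions=None,
              seeds=(11, 12, 13), progress=False) -> dict:
    """Run the control plus the requested perturbation conditions.

    Returns {condition: percent-change report}; the control measurements
    ride along under the key "control".
    """
    cfg = cfg or ControlConfig()
    conditions = conditions or CONDITIONS
    params = cfg.params()
    geom = cfg.geometry()
    integ = Integrator(geom, params)
    control = run_condition(cfg, 1.0, 1.0, seeds, integrator=integ,
                            geom=geom, params=params)
    out = {"control": dict(
        mean_R_d=float(np.nanmean([r["mean_R_d"] for r in control])),
        mean_T_LAD=float(np.mean([r["mean_T_LAD"] for r in control])),
        n_interior=float(np.mean([r["n_interior"] for r in control])))}
    for name, (gs, vs) in conditions.items():
        if progress:
            print(f"[panel] {name}: Gamma_me x{gs}, V_LAD x{vs}")
        runs = run_condition(cfg, gs, vs, seeds, integrator=integ,
                             geom=geom, params=params)
        out[name] = percent_changes(control, runs)
    return out
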
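"""End-to-end pressure-ulcer scenarios.

A scenario runs the four-step chain: (1) resting contact area of the
body patch on the bed plane, (2) elastic deformation under the segment
weight (new area and Gaussian curvature), (3) capillary density and
curved-tube flow change, hence the delivered oxygen pressure, and
(4) the cell-death/neutrophil/DAMP cascade predicting onset and
destruction times, optionally under a repositioning schedule.

Every gap-filling convention (equation mode, sign convention, delta
definition, thresholds, calibrated catenoid scale) is emitted in the
summary so a run is auditable; the pipeline is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import damage, elasticity, geometry, hemodynamics, presets
from .errors import ConfigError

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "preset_config",
    "run_scenario",
    "compare_scenarios",
    "read_config",
    "write_config",
    "write_report",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of one scenario run."""

    name: str = "healthy"
    patch: str = "back"  # patch preset family
    body_mass: float = presets.BODY_MASS  # kg
    segment_fraction: float = presets.PELVIS_FRACTION
    g: float = elasticity.STANDARD_GRAVITY
    young_modulus: float = 0.5e6  # Pa
    poisson_ratio: float = 0.495
    skin_depth: float = 2.75e-3  # m
    resting_area: float = presets.RESTING_AREA  # m^2
    deformed_offset: float = presets.DEFORMED_OFFSET  # m
    baseline_pO2: float = 40.0  # mmHg
    impairment_factor: float = 1.0  # multiplies the baseline (0.85 = -15%)
    vessel_diameter: float = 19.5e-6  # m
    reynolds_n: float = 7e-3
    ode_params: str = "baseline-adult"
    reposition_hours: Optional[float] = None  # None = constant load
    horizon_days: float = 40.0
    onset_fraction: float = 0.9
    destruction_level: float = 0.05
    ode_mode: str = "cc"
    sign_convention: str = "printed"
    delta_definition: str = "vessel-radius-times-sqrt-sup-k"
    rtol: float = 1e-8
    atol: float = 1e-11

    def __post_init__(self) -> None:
        bad = []
        if self.horizon_days <= 0:
            bad.append("horizon_days")
        if self.baseline_pO2 <= 0:
            bad.append("baseline_pO2")
        if self.impairment_factor <= 0:
            bad.append("impairment_factor")
        if not 0 < self.onset_fraction < 1:
            bad.append("onset_fraction")
        if self.reposition_hours is not None and self.reposition_hours <= 0:
            bad.append("reposition_hours")
        if self.patch != "back":
            bad.append("patch")
        if bad:
            raise ConfigError(f"invalid configuration values for keys: {', '.join(bad)}")


@dataclass
class ScenarioResult:
    """Everything a scenario computed, each number traceable to the
    module that produced it."""

    config: ScenarioConfig
    deformation: elasticity.DeformationResult
    flow: hemodynamics.FlowState
    trajectory: damage.Trajectory
    events: damage.EventTimes
    sup_k1: geometry.CurvatureSupremum
    sup_k2: geometry.CurvatureSupremum
    metadata: dict = field(default_factory=dict)

    @property
    def t_onset_days(self) -> Optional[float]:
        return self.events.t_onset_days

    @property
    def t_destruction_days(self) -> Optional[float]:
        return self.events.t_destruction_days

    def summary(self) -> dict:
        """JSON-serializable run summary with every mode switch used."""
        cfg = asdict(self.config)
        dfm = self.deformation
        return {
            "config": cfg,
            "deformation": dfm.report(),
            "curvature": {
                "sup_abs_k_initial": self.sup_k1.value,
                "sup_abs_k_initial_at": [self.sup_k1.u, self.sup_k1.v],
                "sup_abs_k_deformed": self.sup_k2.value,
                "sup_abs_k_deformed_at": [self.sup_k2.u, self.sup_k2.v],
            },
            "flow": {
                "density_ratio": self.flow.density_ratio,
                "flow_ratio": self.flow.flow_ratio,
                "pO2_loaded_mmHg": self.flow.pO2,
                "pO2_baseline_mmHg": self.config.baseline_pO2 * self.config.impairment_factor,
            },
            "events": {
                "t_onset_days": self.events.t_onset_days,
                "t_destruction_days": self.events.t_destruction_days,
            },
            "metadata": self.metadata,
        }


def preset_config(
    name: str,
    reposition_hours: Optional[float] = None,
    horizon_days: Optional[float] = None,
) -> ScenarioConfig:
    """Built-in scenario presets: ``"healthy"`` (40 mmHg baseline) and
    ``"impaired"`` (baseline reduced by 15%)."""

    if name == "healthy":
        cfg = ScenarioConfig(name="healthy")
    elif name == "impaired":
        cfg = ScenarioConfig(name="impaired", impairment_factor=0.85)
    else:
        raise ConfigError(f"unknown scenario preset {name!r}; available: healthy, impaired")
    if reposition_hours is not None:
        cfg = replace(cfg, reposition_hours=reposition_hours)
    if horizon_days is not None:
        cfg = replace(cfg, horizon_days=horizon_days)
    return cfg


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Execute the four-step pipeline for one configuration.

    Deterministic: the same configuration always produces the same
    result, byte for byte in the JSON summary.
    """

    # step 1-2: load, strain, deformation
    mat = elasticity.MaterialProperties(
        Y=config.young_modulus, nu=config.poisson_ratio, skin_depth=config.skin_depth,
        bending_bounds=(0.0, config.skin_depth),
    )
    load = elasticity.LoadSpec.body_segment(
        body_mass=config.body_mass, segment_fraction=config.segment_fraction,
        contact_area=config.resting_area, g=config.g,
    )
    sigma = elasticity.contact_stress(load)
    strain = elasticity.hooke_strain(mat, sigma)
    initial = presets.back_initial()
    deformation = elasticity.deform_patch(
        initial, strain, sign_convention=config.sign_convention,
        offset=config.deformed_offset, mat=mat,
    )

    # step 2b: curvature before/after
    surf_i = geometry.make_elliptic_catenoid(deformation.initial)
    surf_d = geometry.make_elliptic_catenoid(deformation.deformed)
    sup_k1 = geometry.curvature_supremum(surf_i)
    sup_k2 = geometry.curvature_supremum(surf_d)

    # step 3: microcirculation
    bed = hemodynamics.CapillaryBed(
        vessel_diameter=config.vessel_diameter,
        reynolds_n=config.reynolds_n,
        baseline_pO2=config.baseline_pO2 * config.impairment_factor,
    )
    density_ratio = hemodynamics.capillary_density_ratio(
        deformation.area_initial, deformation.area_deformed
    )
    delta1 = hemodynamics.tube_deflection(sup_k1.value, bed.vessel_radius)
    delta2 = hemodynamics.tube_deflection(sup_k2.value, bed.vessel_radius)
    flow_ratio = hemodynamics.flow_change_ratio(delta1, delta2, bed.reynolds_n)
    flow = hemodynamics.perfusion_oxygen(bed, density_ratio, flow_ratio)

    # step 4: damage cascade
    params = presets.damage_params(config.ode_params)
    if config.reposition_hours is None:
        schedule = damage.PressureSchedule(loaded_p=flow.pO2, kind="constant")
    else:
        schedule = damage.PressureSchedule(
            loaded_p=flow.pO2, kind="periodic", period_hours=config.reposition_hours
        )
    traj = damage.simulate(
        params, schedule, t_end_hours=config.horizon_days * 24.0,
        rtol=config.rtol, atol=config.atol, mode=config.ode_mode,
    )
    events = damage.event_times(
        traj, onset_fraction=config.onset_fraction, destruction_level=config.destruction_level
    )

    cal = presets.calibration_info()
    metadata = {
        "pipeline": "area -> deformation -> microcirculation -> cascade",
        "ode_mode": config.ode_mode,
        "sign_convention": config.sign_convention,
        "delta_definition": config.delta_definition,
        "onset_fraction": config.onset_fraction,
        "destruction_level": config.destruction_level,
        "calibrated_c_m": cal.c,
        "calibration_residual_m2": cal.residual,
        "calibration_at_bound": cal.at_bound,
        "sigma_zz_pa": sigma,
        "biharmonic_residual_deformed": elasticity.biharmonic_residual(surf_d),
        "reference_field_sup_k2": geometry.curvature_supremum(
            presets.k2_reference, presets.REFERENCE_FIELD_REGION
        ).value,
        "trajectory_meta": traj.metadata,
    }
    return ScenarioResult(
        config=config, deformation=deformation, flow=flow, trajectory=traj,
        events=events, sup_k1=sup_k1, sup_k2=sup_k2, metadata=metadata,
    )


def compare_scenarios(results_or_configs) -> pd.DataFrame:
    """Run (if needed) and tabulate scenarios sorted by onset time.

    The ``onset_ratio_vs_first`` column is relative to the first
    argument, before sorting.
    """

    items = list(results_or_configs)
    if len(items) < 2:
        raise ConfigError("compare_scenarios needs at least two scenarios")
    results = [r if isinstance(r, ScenarioResult) else run_scenario(r) for r in items]
    ref = results[0].t_onset_days
    rows = []
    for r in results:
        onset = r.t_onset_days
        rows.append(
            {
                "name": r.config.name
                + ("" if r.config.reposition_hours is None else f"+repos{r.config.reposition_hours:g}h"),
                "t_onset_days": onset,
                "t_destruction_days": r.t_destruction_days,
                "onset_ratio_vs_first": (
                    onset / ref if (onset is not None and ref not in (None, 0)) else None
                ),
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        "t_onset_days", na_position="last", kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Config and report I/O
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {f.name for f in ScenarioConfig.__dataclass_fields__.values()}
_REQUIRED_KEYS = {"name"}


def read_config(path) -> ScenarioConfig:
    """Read a YAML scenario configuration; unknown or missing keys are
    named in the error."""

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration {path} is not a key-value document")
    unknown = sorted(set(raw) - _CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    missing = sorted(_REQUIRED_KEYS - set(raw))
    if missing:
        raise ConfigError(f"missing required configuration keys: {', '.join(missing)}")
    return ScenarioConfig(**raw)


def write_config(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def write_report(result: ScenarioResult, outdir, plot: bool = False) -> dict[str, str]:
    """Write summary.json + trajectory.csv (+ optional trajectory.png).

    Returns the written paths.  The JSON is byte-stable across repeated
    runs of the same configuration.
    """

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = str(summary_path)

    traj_path = outdir / "trajectory.csv"
    result.trajectory.to_csv(traj_path)
    paths["trajectory"] = str(traj_path)

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = result.trajectory.frame
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(frame.t_days, frame.N, label="live cells N")
        ax.plot(frame.t_days, frame.I, label="neutrophils I")
        ax.plot(frame.t_days, frame.D, label="DAMPs D")
        for t_ev, lbl in (
            (result.t_onset_days, "onset"),
            (result.t_destruction_days, "destruction"),
        ):
            if t_ev is not None:
                ax.axvline(t_ev, ls="--", lw=0.8, color="grey")
                ax.text(t_ev, 1.02, lbl, rotation=90, va="bottom", fontsize=8)
        ax.set_xlabel("time (days)")
        ax.set_ylabel("normalized density")
        ax.set_title(result.config.name)
        ax.legend()
        fig.tight_layout()
        png_path = outdir / "trajectory.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        paths["plot"] = str(png_path)
    return paths
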
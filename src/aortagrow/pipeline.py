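"""End-to-end synthetic-cohort pipeline.

Per patient: generate a dissected-aorta scene, calibrate and solve the
lumen pressure network, compute forward-penalty wall stress, generate a
follow-up geometry whose growth obeys the random-slope generative model
driven by the patient's own stress field, recover the growth map by
rigid + nonrigid registration, and average everything over the 38
descending regions.  At cohort level: mixed-effects fits of growth on
stress / WSS / pressure and of stress and growth on thrombus presence,
per-patient Pearson correlations, the lumen-pressure paired test, the
hemodynamic calibration report, and follow-up duration statistics.

Every stage is a pure function of (config, seed); rerunning a config
reproduces all numeric outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import hemodynamics as hd
from . import io as agio
from . import registration as rg
from . import stress as st
from .meshmodel import (StructuredSurface, ThicknessSpec, build_solid_mesh,
                        avg_descending_growth, parameterize_surface,
                        partition_regions)
from .mixedlm import GrowthLME
from .presets import reference_patients
from .regions import (build_region_table, pearson_by_patient, region_average,
                      thrombus_presence)
from .stress import MaterialSpec
from .synthetic import (AortaSpec, GrowthField, PatientRecord, ThrombusSpec,
                        grow_aorta, make_dissected_aorta)

log = logging.getLogger(__name__)

_STAGES = ("generate", "hemo", "stress", "growth", "stats")

__all__ = ["PipelineConfig", "run_pipeline", "compute_followup_stats"]


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    n_patients: int = 9
    seed: int = 0
    output_dir: str = "aortagrow_output"
    use_reference_records: bool = True   # nine-patient cohort scalars

    # growth generative model: GR = b0 + b1*stress + patient effects + eps
    beta0: float = 0.0                   # %/year
    beta1: float = 0.095                 # %/(year*kPa)
    sd_b0: float = 27.8                  # %/year
    sd_b1: float = 0.13                  # %/(year*kPa)
    sd_eps: float = 10.0                 # %/year

    # geometry (generator grid resolution of the scene)
    grid_axial: int = 64
    grid_circ: int = 32
    radius: float = 15.0                 # mm
    bump_amplitude: float = 0.6          # mm, smooth radius perturbations

    # wall / materials
    thickness: ThicknessSpec = field(default_factory=ThicknessSpec)
    materials: MaterialSpec = field(default_factory=MaterialSpec)

    # hemodynamics
    default_flow: float = 25.0           # L/min when no velocity is given
    blood_viscosity: float = 0.004       # Pa*s
    blood_density: float = 1060.0        # kg/m^3
    sbp_tune_tol: float = 0.02           # 2% MAPE target

    # registration
    sigma: float = 1.0
    w_W: float = 20.0                    # mm
    w_R: float = 20.0                    # mm
    registration_max_iter: int = 150
    registration_subsample: tuple = (4, 2)
    rigid_perturbation_deg: float = 3.0

    write_fields: bool = True            # VTK surface/solid outputs

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        if self.grid_axial < 16 or self.grid_circ < 12:
            raise ValueError("scene grid too coarse for a meaningful wall mesh")
        if not (0 < self.sbp_tune_tol < 1):
            raise ValueError("sbp_tune_tol is a fraction in (0, 1)")
        if min(self.sd_b0, self.sd_b1, self.sd_eps) < 0:
            raise ValueError("random-effect SDs must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "thickness" in raw:
            raw["thickness"] = ThicknessSpec(**raw["thickness"])
        if "materials" in raw:
            raw["materials"] = MaterialSpec(**raw["materials"])
        if "registration_subsample" in raw:
            raw["registration_subsample"] = tuple(raw["registration_subsample"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["registration_subsample"] = list(self.registration_subsample)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _synthetic_record(m: int, rng: np.random.Generator) -> PatientRecord:
    sbp = float(np.round(rng.uniform(120.0, 190.0)))
    years = float(rng.uniform(1.0, 5.0))
    base = date(2015, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
    return PatientRecord(
        patient_id=f"S{m + 1}", sbp=sbp, dbp=sbp - 60.0,
        baseline_date=base,
        followup_date=base + timedelta(days=max(int(years * 365.25), 30)),
        inlet_flow=25.0, thrombus_present=bool(m % 3 != 2),
    )


def _patient_scene(config: PipelineConfig, m: int, record: PatientRecord,
                   rng: np.random.Generator):
    radius = config.radius * float(1.0 + 0.06 * rng.uniform(-1, 1))
    thrombus = None
    spec0 = AortaSpec()   # probe for default landmark position
    if record.thrombus_present:
        # mural thrombus in the mid false lumen
        landmark = spec0.ascending_length + np.pi * spec0.arch_radius
        thrombus = ThrombusSpec(start=landmark + 60.0, end=landmark + 140.0,
                                depth=5.0, angle_frac=0.6)
    spec = AortaSpec(radius=radius, distal_radius=radius * 0.85,
                     n_axial=config.grid_axial, n_circ=config.grid_circ,
                     bump_amplitude=config.bump_amplitude,
                     thrombus=thrombus, seed=int(rng.integers(2 ** 31)))
    return make_dissected_aorta(spec)


def _thrombus_points(solid) -> np.ndarray | None:
    sel = solid.material == "thrombus"
    if not sel.any():
        return None
    return solid.nodes[np.unique(solid.hexes[sel])]


def run_pipeline(config: PipelineConfig, until: str = "stats") -> dict:
    """Execute the pipeline up to (and including) ``until``.

    Stage order: generate < hemo < stress < growth < stats.  Partial
    outputs are retained on failure; each stage failure raises with a
    stage-tagged message.
    """
    if until not in _STAGES:
        raise ValueError(f"unknown stage {until!r}")
    depth = _STAGES.index(until)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.use_reference_records:
        records = reference_patients()
        if config.n_patients > len(records):
            rng = np.random.default_rng((config.seed, 999))
            records += [_synthetic_record(m, rng)
                        for m in range(len(records), config.n_patients)]
        records = records[:config.n_patients]
    else:
        rng = np.random.default_rng((config.seed, 999))
        records = [_synthetic_record(m, rng) for m in range(config.n_patients)]

    report: dict = {
        "config_hash": config.config_hash(), "seed": config.seed,
        "n_patients": config.n_patients, "stages_run": _STAGES[:depth + 1],
    }
    calib_rows, region_tables, pfields = [], [], []
    growth_mm_per_year = []
    stage_t0 = time.time()

    # patient-level random effects of the growth generative model
    eff_rng = np.random.default_rng((config.seed, 7))
    b0s = eff_rng.normal(0.0, config.sd_b0, config.n_patients) if config.sd_b0 else np.zeros(config.n_patients)
    b1s = eff_rng.normal(0.0, config.sd_b1, config.n_patients) if config.sd_b1 else np.zeros(config.n_patients)

    for m, record in enumerate(records):
        pid = record.patient_id
        prng = np.random.default_rng((config.seed, m))
        stage = "generate"
        try:
            scene = _patient_scene(config, m, record, prng)
            structured = parameterize_surface(scene)
            partition = partition_regions(structured)
            if config.write_fields:
                agio.write_scene_stl(out / f"{pid}_baseline.stl", scene)
            if depth < 1:
                continue

            stage = "hemo"
            inlet = hd.inlet_from_flow(record.inlet_flow or config.default_flow,
                                       scene.inlet_radius)
            tune = hd.tune_total_resistance(
                scene, inlet, record.sbp, tol=config.sbp_tune_tol,
                mu=config.blood_viscosity, rho=config.blood_density)
            outlets = hd.allocate_outlets(tune["tuned_resistance"],
                                          [o.area for o in scene.outlets])
            pfield = hd.solve_network(scene, inlet, outlets,
                                      mu=config.blood_viscosity,
                                      rho=config.blood_density)
            pfields.append(pfield)
            calib_rows.append({"patient_id": pid, "sbp_mmhg": record.sbp,
                               "flow_l_min": inlet.flow, **tune})
            if depth < 2:
                continue

            stage = "stress"
            solid = build_solid_mesh(scene, config.thickness)
            tractions = st.map_pressure_to_solid(pfield, solid)
            sfield = st.forward_penalty_stress(solid, tractions, config.materials)
            stress_map = st.register_stress_to_structured(
                sfield.max_principal, solid.nodes, structured)
            wss_map = st.register_stress_to_structured(
                pfield.wss_pa, pfield.points, structured)
            bp_map = st.register_stress_to_structured(
                pfield.pressure_mmhg, pfield.points, structured)
            tb_map = thrombus_presence(structured, _thrombus_points(solid))
            if config.write_fields:
                agio.write_vtk_solid(out / f"{pid}_stress.vtk", solid,
                                     {"max_principal_kpa": sfield.max_principal,
                                      "von_mises_kpa": sfield.von_mises,
                                      "displacement_mm": sfield.displacement})
            if depth < 3:
                continue

            stage = "growth"
            years = record.followup_years
            sigma_regions = region_average(stress_map, partition)
            eps = prng.normal(0.0, config.sd_eps, partition.n_descending) \
                if config.sd_eps else np.zeros(partition.n_descending)
            rates = (config.beta0 + config.beta1 * sigma_regions
                     + b0s[m] + b1s[m] * sigma_regions + eps)
            gfield = GrowthField.from_region_rates(
                rates, partition, structured.layer_arclengths, duration=years)
            ang = np.deg2rad(config.rigid_perturbation_deg)
            axis = prng.normal(size=3)
            rig = rg.RigidTransform.about_axis(axis, np.rad2deg(ang),
                                               t=prng.uniform(-3, 3, 3))
            follow = grow_aorta(scene, gfield, rotation=rig.R, translation=rig.t)
            follow_structured = parameterize_surface(follow)
            growth_mm_per_year.append(
                avg_descending_growth(structured, follow_structured, years))

            icp = rg.icp_align(follow_structured.points(), structured.points())
            aligned = StructuredSurface(
                icp.apply(follow_structured.points()).reshape(
                    follow_structured.nodes.shape),
                landmark_layer=follow_structured.landmark_layer)
            _, deformed, info = rg.nonrigid_register(
                structured, aligned, sigma=config.sigma, w_W=config.w_W,
                w_R=config.w_R, max_iter=config.registration_max_iter,
                template_subsample=config.registration_subsample,
                target_subsample=config.registration_subsample)
            gmap = rg.growth_strain(structured, deformed, years)
            if config.write_fields:
                agio.write_vtk_surface(
                    out / f"{pid}_growth_baseline.vtk", structured,
                    {"growth_pct_per_year": gmap.masked(),
                     "stress_kpa": stress_map})
                agio.write_vtk_surface(
                    out / f"{pid}_growth_followup.vtk", aligned,
                    {"growth_pct_per_year": gmap.masked()})

            # structural end effects: the clamped rims perturb stress
            # within a couple of layers of each end; exclude them from
            # the stress region averages
            edge_ok = np.ones((structured.n_layers, structured.n_circ),
                              dtype=bool)
            edge_ok[:2] = edge_ok[-2:] = False
            table = build_region_table(
                pid, partition,
                {"stress_kpa": stress_map, "wss_pa": wss_map,
                 "bp_mmhg": bp_map,
                 "growth_pct_per_year": gmap.rates, "thrombus": tb_map},
                valid={"growth_pct_per_year": gmap.valid,
                       "stress_kpa": edge_ok})
            table["followup_years"] = years
            table["true_growth_pct_per_year"] = rates
            region_tables.append(table)
        except Exception as exc:
            raise RuntimeError(f"[stage {stage}] patient {pid}: {exc}") from exc
        log.info("patient %s done (%.1f s)", pid, time.time() - stage_t0)

    if calib_rows:
        calib = pd.DataFrame(calib_rows)
        agio.write_csv_with_units(
            calib, out / "calibration.csv",
            {"sbp_mmhg": "mmHg", "flow_l_min": "L/min",
             "calculated_resistance": "mmHg*min/L",
             "tuned_resistance": "mmHg*min/L", "adjustment_pct": "%"})
        report["calibration"] = calib.to_dict(orient="list")
        report["lumen_pressures"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in hd.lumen_pressure_summary(pfields).items()
        } if len(pfields) >= 2 else None

    if depth >= 4 and region_tables:
        stage = "stats"
        pooled = pd.concat(region_tables, ignore_index=True)
        agio.write_csv_with_units(
            pooled, out / "region_table.csv",
            {"stress_kpa": "kPa", "wss_pa": "Pa", "bp_mmhg": "mmHg",
             "growth_pct_per_year": "%/year", "thrombus": "0/1",
             "followup_years": "years"})
        fits = {}
        fits["growth_on_stress"] = GrowthLME.from_dataframe(pooled).fit().to_dict()
        fits["growth_on_wss"] = GrowthLME.from_dataframe(
            pooled, predictor="wss_pa").fit().to_dict()
        fits["growth_on_pressure"] = GrowthLME.from_dataframe(
            pooled, predictor="bp_mmhg").fit().to_dict()
        fits["growth_on_stress_quadratic"] = GrowthLME.from_dataframe(
            pooled, quadratic=True).fit().to_dict()
        fits["growth_on_stress_followup"] = GrowthLME.from_dataframe(
            pooled, extra_covariates=("followup_years",)).fit().to_dict()
        if pooled["thrombus"].nunique() > 1:
            fits["stress_on_thrombus"] = GrowthLME.from_dataframe(
                pooled, predictor="thrombus", response="stress_kpa").fit().to_dict()
            fits["growth_on_thrombus"] = GrowthLME.from_dataframe(
                pooled, predictor="thrombus").fit().to_dict()
        report["fits"] = fits
        report["pearson"] = pearson_by_patient(
            pooled, "stress_kpa", "growth_pct_per_year").to_dict(orient="list")
        report["followup_stats"] = compute_followup_stats(
            records, growth_mm_per_year or None)
        report["n_region_rows"] = int(len(pooled))
        agio.write_json(fits, out / "fits.json")

    agio.write_json(report, out / "report.json")
    return report


def compute_followup_stats(records: list[PatientRecord],
                           growth_rates_mm_per_year=None) -> dict:
    """Median and IQR of follow-up duration (and of growth rates).

    Durations use the 365.25 days/year convention; percentiles use
    linear interpolation (numpy default), which the quartile values
    depend on.
    """
    years = np.array([r.followup_years for r in records])
    if np.any(years <= 0):
        raise ValueError("follow-up before baseline")
    q25, q50, q75 = np.percentile(years, [25, 50, 75])
    out = {"followup_years_median": float(q50),
           "followup_years_iqr": [float(q25), float(q75)],
           "n": len(records)}
    if growth_rates_mm_per_year is not None:
        g = np.asarray(growth_rates_mm_per_year, dtype=float)
        g25, g50, g75 = np.percentile(g, [25, 50, 75])
        out["growth_mm_per_year_median"] = float(g50)
        out["growth_mm_per_year_iqr"] = [float(g25), float(g75)]
    return out
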
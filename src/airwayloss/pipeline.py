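"""End-to-end orchestration: config, pipeline run, and table/figure reports.

A run goes geometry -> plane sampling -> energy/resistance accounting ->
power-law fit, either on a synthetic airway (the default; all ground truth
known) or on user-supplied files (STL mesh, centerline CSV, plane-sample
CSV, loss-pair CSV).  CSV tables are the authoritative output surface;
figures are advisory companions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _version
from . import energy, geometry, lossmodel, sampling, synthetic
from .errors import InvalidInputError

log = logging.getLogger("airwayloss")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, explicit and hashable.

    Either ``synthetic_shape``/``synthetic_flow`` (generator parameters) or
    ``inputs`` (paths to mesh/centerline/plane-sample/loss-pair files) must
    be provided.  All physical constants live here, never in code.
    """

    seed: int = 0
    rho: float = 1.2  # kg/m**3
    mu: float = 1.8e-5  # Pa.s
    threshold: float = 0.35  # constriction-ratio threshold
    discard_before: float = 0.05  # s of start-up transient dropped
    flowrates_lmin: list[float] = field(default_factory=lambda: [23.5, 30.0, 40.0, 50.0])
    fixed_exponent: float = 2.0
    reference_landmark: str = "first_ring_station"
    outdir: str = "airwayloss_out"
    synthetic_shape: dict = field(default_factory=dict)
    synthetic_flow: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # mesh, centerline, plane_samples, loss_pairs
    geometry_spacing: float = 1.0  # mm between area-profile stations
    geometry_margin: float = 1.0  # mm kept clear of the end caps
    flow_spacing: float = 10.0  # mm between flow-sampling planes
    n_rings: int = 16  # radial sampling rings per plane
    make_figures: bool = True
    write_samples: bool = False  # full plane-sample CSV is large; opt in

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise InvalidInputError("threshold must lie in (0, 1)")
        if self.rho <= 0 or self.mu <= 0:
            raise InvalidInputError("rho and mu must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise InvalidInputError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**data)


@dataclass
class RunReport:
    """Numbers and file paths produced by one pipeline run."""

    constriction: dict
    dp_table: list[dict]  # per-flowrate measured losses
    fits: dict  # fixed-n and free-n power-law fits
    resistance_total: float  # Pa.mL**-1.s at the primary flowrate
    outputs: dict[str, str]
    provenance: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _flow_stations(shape: synthetic.AirwayShapeSpec, spacing: float) -> np.ndarray:
    """Sampling stations covering the duct, always including the throat."""
    throat = shape.extrusion_length + shape.constriction_center
    grid = np.arange(spacing, shape.total_length - spacing / 2, spacing)
    return np.unique(np.concatenate([grid, [throat]]))


def _measure_dp(cfg: PipelineConfig, profile, q_mls: float, seed: int) -> float:
    """Total-pressure loss inlet->outlet of a synthetic orifice dataset (Pa)."""
    flow = synthetic.AnalyticFlowSpec(
        **{**cfg.synthetic_flow, "Q": q_mls, "rho": cfg.rho, "mu": cfg.mu, "seed": seed}
    )
    _, series = synthetic.make_orifice_pressure_field(
        flow, profile, n_rings=cfg.n_rings
    )
    fields = [sampling.time_average(s, cfg.discard_before) for s in series]
    p = [energy.mean_total_pressure(f, cfg.rho) for f in fields]
    return float(p[0] - p[-1])


def _figures(outdir: Path, profile, cm, eprof, rprof, dp_table, fit_fixed) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(profile.x, profile.A, lw=1.5)
    ax.axhline((1 - cm.threshold) * cm.A_ref, ls="--", c="grey", lw=0.8,
               label=f"{cm.threshold:.0%} reduction level")
    ax.plot([cm.x_min], [cm.A_min], "s", c="k", ms=6)
    ax.set_xlabel("station x (mm, carina at 0)")
    ax.set_ylabel("lumen area (mm$^2$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    p = outdir / "csa_profile.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["csa_profile"] = str(p)

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(rprof.x, rprof.R, c="tab:blue", lw=1.5, label="resistance")
    ax.set_xlabel("station x (mm)")
    ax.set_ylabel(r"R (Pa mL$^{-1}$ s)", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(eprof.x, eprof.cumulative_loss, c="tab:red", lw=1.5,
             label="cumulative energy loss")
    ax2.set_ylabel("cumulative loss (W)", color="tab:red")
    fig.tight_layout()
    p = outdir / "loss_profiles.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["loss_profiles"] = str(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    q = np.array([row["Q_mLs"] for row in dp_table])
    dp = np.array([row["dp_Pa"] for row in dp_table])
    ax.plot(q, dp, "o", c="k", label="measured")
    qq = np.linspace(q.min(), q.max(), 100)
    ax.plot(qq, dp[0] * (qq / q[0]) ** 2, "--", c="tab:blue",
            label="quadratic scaling from lowest Q")
    ax.plot(qq, lossmodel.predict_dp(fit_fixed.model, qq), "-", c="tab:red",
            lw=1.0, label=f"orifice law, K={fit_fixed.model.K:.3f}")
    ax.set_xlabel("Q (mL/s)")
    ax.set_ylabel(r"$\Delta P$ (Pa)")
    ax.legend(frameon=False)
    fig.tight_layout()
    p = outdir / "scaling_overlay.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["scaling_overlay"] = str(p)
    return paths


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run geometry -> sampling -> energy -> fits and write all reports.

    Deterministic for a fixed config (the seed feeds every random draw).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run config sha256=%s seed=%d rho=%g threshold=%g "
             "TI=vector-magnitude-RMS pressure=area-averaged-mean-total",
             config.sha256()[:12], config.seed, config.rho, config.threshold)

    if config.inputs:
        return _run_from_files(config, outdir)

    # --- geometry ---------------------------------------------------------
    shape = synthetic.AirwayShapeSpec(
        **{**config.synthetic_shape, "seed": config.seed}
    )
    mesh, centerline, analytic_prof = synthetic.make_airway_surface(shape)
    mesh_path = outdir / "airway.stl"
    mesh.export(mesh_path)
    geometry.write_centerline_csv(outdir / "centerline.csv", centerline)

    m = config.geometry_margin
    cl = geometry.resample_centerline(centerline.points, config.geometry_spacing)
    keep = (cl.arclength >= m) & (cl.arclength <= shape.total_length - m)
    cl_in = geometry.Centerline(cl.points[keep], cl.arclength[keep])
    carina = centerline.landmarks["carina_offset"]
    measured = geometry.area_profile(mesh, cl_in, carina_offset=carina)
    geometry.write_profile_csv(outdir / "area_profile.csv", measured)

    ref_station = centerline.landmarks[config.reference_landmark] - carina
    cm = geometry.constriction_metrics(measured, ref_station, config.threshold)
    constriction = {
        "A_ref_mm2": cm.A_ref,
        "A_min_mm2": cm.A_min,
        "x_min_mm": cm.x_min,
        "ratio_pct": 100.0 * cm.ratio,
        "length_mm": cm.length,
        "threshold": cm.threshold,
        "analytic_ratio_pct": 100.0 * shape.constriction_depth,
    }

    # --- flow + energy accounting at the primary flowrate -----------------
    stations = _flow_stations(shape, config.flow_spacing)
    flow_prof = geometry.AreaProfile(
        x=stations, A=np.asarray(shape.analytic_area(stations))
    )
    q_primary = config.flowrates_lmin[0] * 1000.0 / 60.0
    flow0 = synthetic.AnalyticFlowSpec(
        **{**config.synthetic_flow, "Q": q_primary, "rho": config.rho,
           "mu": config.mu, "seed": config.seed}
    )
    law, series = synthetic.make_orifice_pressure_field(
        flow0, flow_prof, n_rings=config.n_rings
    )
    if config.write_samples:
        sampling.write_plane_series_csv(outdir / "plane_samples.csv", series)
    fields = [sampling.time_average(s, config.discard_before) for s in series]
    eprof = energy.cumulative_loss(fields, rho=config.rho)
    rprof = energy.resistance_profile(fields, rho=config.rho, Q=q_primary)
    energy.write_energy_csv(outdir / "energy_flux.csv", eprof)
    energy.write_resistance_csv(outdir / "resistance.csv", rprof)

    # --- per-flowrate losses and power-law fits ---------------------------
    dp_table = []
    for i, q_lmin in enumerate(config.flowrates_lmin):
        q_mls = q_lmin * 1000.0 / 60.0
        dp = _measure_dp(config, flow_prof, q_mls, seed=config.seed + 1 + i)
        dp_table.append({"Q_Lmin": q_lmin, "Q_mLs": q_mls, "dp_Pa": dp})

    a_c = float(np.min(measured.A))
    pairs = [(row["Q_mLs"], row["dp_Pa"]) for row in dp_table]
    fit_fixed = lossmodel.fit_powerlaw(pairs, A_C=a_c, rho=config.rho,
                                       fixed_n=config.fixed_exponent)
    fits = {
        "fixed_n": {
            "K": fit_fixed.model.K, "n": fit_fixed.model.n,
            "K_rho": fit_fixed.K_rho, "A_C_mm2": a_c,
            "max_rel_error": fit_fixed.max_relative_error,
        },
    }
    if len(pairs) >= 3:  # the free-exponent fit needs an extra degree of freedom
        fit_free = lossmodel.fit_powerlaw(pairs, A_C=a_c, rho=config.rho)
        fits["free_n"] = {
            "K": fit_free.model.K, "n": fit_free.model.n,
            "K_rho": fit_free.K_rho, "A_C_mm2": a_c,
            "max_rel_error": fit_free.max_relative_error,
        }

    import pandas as pd

    pd.DataFrame(dp_table).to_csv(outdir / "pressure_loss_table.csv", index=False)
    pd.DataFrame([constriction]).to_csv(outdir / "constriction_metrics.csv", index=False)
    with open(outdir / "powerlaw_fit.json", "w") as fh:
        json.dump(fits, fh, indent=2, sort_keys=True)
        fh.write("\n")

    outputs = {
        "mesh": str(mesh_path),
        "centerline": str(outdir / "centerline.csv"),
        "area_profile": str(outdir / "area_profile.csv"),
        "constriction_metrics": str(outdir / "constriction_metrics.csv"),
        "energy_flux": str(outdir / "energy_flux.csv"),
        "resistance": str(outdir / "resistance.csv"),
        "pressure_loss_table": str(outdir / "pressure_loss_table.csv"),
        "powerlaw_fit": str(outdir / "powerlaw_fit.json"),
    }
    if config.make_figures:
        outputs.update(_figures(outdir, measured, cm, eprof, rprof, dp_table, fit_fixed))

    report = RunReport(
        constriction=constriction,
        dp_table=dp_table,
        fits=fits,
        resistance_total=float(rprof.R[-1]),
        outputs=outputs,
        provenance={"config_sha256": config.sha256(), "seed": config.seed,
                    "version": _version},
    )
    report.to_json(outdir / "report.json")
    return report


def _run_from_files(config: PipelineConfig, outdir: Path) -> RunReport:
    """File-driven variant: mesh+centerline morphometrics, optional flow data."""
    import trimesh

    inputs = config.inputs
    for key in ("mesh", "centerline"):
        if key not in inputs:
            raise InvalidInputError(f"inputs requires {key!r} (file path)")
        if not Path(inputs[key]).exists():
            raise InvalidInputError(f"input file not found: {inputs[key]}")
    mesh = trimesh.load(inputs["mesh"], force="mesh")
    pts = geometry.read_centerline_csv(inputs["centerline"])
    cl = geometry.resample_centerline(pts, config.geometry_spacing)
    carina = float(inputs.get("carina_offset", cl.total_length))
    measured = geometry.area_profile(mesh, cl, carina_offset=carina)
    geometry.write_profile_csv(outdir / "area_profile.csv", measured)
    ref_station = float(inputs.get("ref_station", measured.x[0]))
    cm = geometry.constriction_metrics(measured, ref_station, config.threshold)
    constriction = {
        "A_ref_mm2": cm.A_ref, "A_min_mm2": cm.A_min, "x_min_mm": cm.x_min,
        "ratio_pct": 100.0 * cm.ratio, "length_mm": cm.length,
        "threshold": cm.threshold,
    }

    fits: dict = {}
    dp_table: list[dict] = []
    if "loss_pairs" in inputs:
        pairs = lossmodel.read_fit_pairs_csv(inputs["loss_pairs"])
        a_c = float(inputs.get("A_C_mm2", np.min(measured.A)))
        fit_fixed = lossmodel.fit_powerlaw(pairs, A_C=a_c, rho=config.rho,
                                           fixed_n=config.fixed_exponent)
        fits["fixed_n"] = {"K": fit_fixed.model.K, "n": fit_fixed.model.n,
                           "K_rho": fit_fixed.K_rho, "A_C_mm2": a_c,
                           "max_rel_error": fit_fixed.max_relative_error}
        dp_table = [{"Q_mLs": q, "dp_Pa": dp} for q, dp in pairs]

    import pandas as pd

    pd.DataFrame([constriction]).to_csv(outdir / "constriction_metrics.csv", index=False)
    report = RunReport(
        constriction=constriction,
        dp_table=dp_table,
        fits=fits,
        resistance_total=float("nan"),
        outputs={"area_profile": str(outdir / "area_profile.csv"),
                 "constriction_metrics": str(outdir / "constriction_metrics.csv")},
        provenance={"config_sha256": config.sha256(), "seed": config.seed,
                    "version": _version},
    )
    report.to_json(outdir / "report.json")
    return report
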
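"""Stage orchestration: flow -> transport, synth -> analyze -> stats.

Each stage reads what the previous stage wrote into the output directory,
so stages can run in one invocation or across several. A JSON manifest
records every stage's parameters and the SHA-256 of every artifact;
rerunning with the same config and seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import flow as flow_mod
from . import imaging, synth, transport
from .geometry import build_geometry
from .io import RunConfig, config_hash, load_fields, read_stack, save_fields, write_table
from .stats import summarize_conditions

__all__ = ["PipelineError", "run_pipeline"]

log = logging.getLogger("spheroflow")

STAGE_ORDER = ["synth", "flow", "transport", "analyze", "stats"]


class PipelineError(RuntimeError):
    """Raised when a stage dependency or input is missing."""


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _geometry(cfg: RunConfig):
    g = cfg.geometry
    return build_geometry(
        width=g.get("width_um", 1000.0),
        span=g.get("span_um", 1000.0),
        spheroid_radius=g.get("spheroid_radius_um", 100.0),
        spheroid_center=tuple(g["spheroid_center_um"]) if "spheroid_center_um" in g else None,
        grid_spacing=g.get("grid_spacing_um", 5.0),
        pillar_side=g.get("pillar_side_um", 150.0),
        channel_height=g.get("channel_height_um", 280.0),
    )


def _medium(cfg: RunConfig) -> flow_mod.PorousMedium:
    m = cfg.medium
    k = m.get("permeability_m2", 1.5e-16)
    return flow_mod.PorousMedium(
        permeability=k,
        permeability_spheroid=k * m.get("permeability_ratio", 0.01),
        viscosity=m.get("viscosity_pa_s", 1e-3),
        effective_viscosity=m.get("effective_viscosity_pa_s"),
    )


def _run_flow(cfg: RunConfig, out: Path) -> list[Path]:
    geom = _geometry(cfg)
    medium = _medium(cfg)
    bc = flow_mod.FlowBC.from_mbar(cfg.bc.get("p1_mbar", 30.0), cfg.bc.get("p2_mbar", 0.0))
    field = flow_mod.solve_flow(geom, medium, bc)
    u_m = flow_mod.mean_interstitial_velocity(field, geom)
    stress = flow_mod.interfacial_stress(field, geom, medium, bc)
    log.info("flow: residual=%.2e u_m=%.4f um/s", field.residual, u_m)
    flow_path = out / "flow.npz"
    save_fields(
        flow_path,
        pressure=field.pressure,
        velocity_x=field.velocity_x,
        velocity_y=field.velocity_y,
        flux_x=field.flux_x,
        flux_y=field.flux_y,
        residual=np.array(field.residual),
        u_m=np.array(u_m),
    )
    stress_path = out / "stress.csv"
    write_table(
        pd.DataFrame(
            {
                "theta_deg": stress.theta,
                "normal_stress_pa": stress.normal_stress,
                "shear_stress_pa": stress.shear_stress,
            }
        ),
        stress_path,
    )
    return [flow_path, stress_path]


def _run_transport(cfg: RunConfig, out: Path) -> list[Path]:
    flow_path = out / "flow.npz"
    if not flow_path.exists():
        raise PipelineError("transport requires the flow stage output (flow.npz)")
    geom = _geometry(cfg)
    data = load_fields(flow_path)
    field = flow_mod.FlowField(
        pressure=data["pressure"],
        velocity_x=data["velocity_x"],
        velocity_y=data["velocity_y"],
        flux_x=data["flux_x"],
        flux_y=data["flux_y"],
        converged=True,
        residual=float(data["residual"]),
    )
    t = cfg.transport
    d = t.get("diffusivity_m2_s", 5e-11)
    params = transport.TransportParams(
        diffusivity=d,
        diffusivity_spheroid=d * t.get("diffusivity_ratio", 0.5),
        inlet_concentration=t.get("inlet_concentration_ng_ml", 10.0),
        duration_min=t.get("duration_min", 400.0),
        output_interval_min=t.get("output_interval_min", 10.0),
        dt_s=t.get("dt_s"),
    )
    series = transport.simulate_transport(field, geom, params)
    probe = transport.interface_probe(geom)
    sat = transport.time_to_saturation(series, probe, t.get("saturation_fraction", 0.95))
    log.info("transport: saturation %.1f min (reached=%s)", sat.time_min, sat.reached)
    conc_path = out / "conc.npz"
    save_fields(conc_path, times_min=series.times_min, frames=series.frames)
    probe_path = out / "probe.csv"
    write_table(
        pd.DataFrame(
            {
                "time_min": series.times_min,
                "min_frac": series.probe_minimum(probe),
                "mean_frac": series.probe_mean(probe),
            }
        ),
        probe_path,
    )
    return [conc_path, probe_path]


def _run_synth(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    s = dict(cfg.synth)
    conditions = s.pop("conditions", None) or [
        {"label": "IF+TGFb+", "amplitude": 13.0, "asymmetry": 1.25, "motile": True, "n_spheroids": 3},
        {"label": "IF-TGFb+", "amplitude": 3.5, "asymmetry": 1.0, "motile": False, "n_spheroids": 3},
        {"label": "IF+TGFb-", "amplitude": 1.0, "asymmetry": 1.0, "motile": False, "n_spheroids": 3},
    ]
    base = synth.SyntheticConfig(
        image_size=tuple(s.get("image_size_px", (256, 256))),
        pixel_size=s.get("pixel_size_um", 2.0),
        spheroid_radius=s.get("spheroid_radius_um", 100.0),
        n_frames=s.get("n_frames", 71),
        frame_interval=s.get("frame_interval_h", 1.0),
        tau=s.get("tau_h", 25.0),
        kinetics=s.get("kinetics", "saturating"),
        noise_gaussian=s.get("noise_gaussian", 2.0),
        poisson_scale=s.get("poisson_scale", 0.5),
        background=s.get("background", 20.0),
        jitter=s.get("jitter_px", 1.5),
        amplitude_cv=s.get("amplitude_cv", 0.2),
        seed=seed,
    )
    fixtures = out / "fixtures"
    records = synth.render_condition_set(conditions, fixtures, base)
    return [fixtures / "manifest.csv"] + [Path(r["stack_path"]) for r in records]


def _run_analyze(cfg: RunConfig, out: Path) -> list[Path]:
    manifest_path = out / "fixtures" / "manifest.csv"
    if not manifest_path.exists():
        raise PipelineError("analyze requires the synth stage output (fixtures/manifest.csv)")
    manifest = pd.read_csv(manifest_path)
    a = cfg.analysis
    background = a.get("background", "annulus")
    if background in (False, "none"):
        background = None
    intensity_rows, profile_rows, motility_rows = [], [], []
    for _, row in manifest.iterrows():
        stack = read_stack(row["stack_path"])
        sid = f"{row['label']}_{row['spheroid']}"
        fluo = [c for c in stack.channels if c != "bf"]
        roi = imaging.segment_spheroid(stack.channel(fluo[0])[0], polarity="bright")
        for ch in fluo:
            series = imaging.intensity_timeseries(
                stack, roi, ch, background=background, mode=a.get("intensity_mode", "sum")
            )
            for t, raw, norm in zip(series.times, series.raw_density, series.normalized):
                intensity_rows.append(
                    {"spheroid_id": sid, "label": row["label"], "channel": ch,
                     "time_h": t, "raw_density": raw, "norm_intensity": norm}
                )
            prof = imaging.azimuthal_profile(
                stack, roi, ch,
                times=[stack.times[0], stack.times[-1]],
                n_theta=a.get("n_theta", 360), background=background,
            )
            for ti, t in enumerate(prof.times):
                for th, v in zip(prof.theta, prof.values[ti]):
                    profile_rows.append(
                        {"spheroid_id": sid, "label": row["label"], "channel": ch,
                         "time_h": t, "theta_deg": th, "norm_intensity": v}
                    )
        if "bf" in stack.channels:
            mot = imaging.temporal_sd_map(stack, "bf")
            score = imaging.peripheral_motility_score(
                mot, roi, a.get("motility_band_um", 30.0), stack.pixel_size
            )
            motility_rows.append({"spheroid_id": sid, "label": row["label"], "score": score})
            import tifffile

            tifffile.imwrite(out / f"{sid}_sdmap.tif", mot.sd.astype(np.float32),
                             photometric="minisblack")
    paths = []
    for name, rows in (
        ("intensity.csv", intensity_rows),
        ("profile.csv", profile_rows),
        ("motility.csv", motility_rows),
    ):
        paths.append(out / name)
        write_table(rows, out / name)
    return paths


def _run_stats(cfg: RunConfig, out: Path) -> list[Path]:
    intensity_path = out / "intensity.csv"
    if not intensity_path.exists():
        raise PipelineError("stats requires the analyze stage output (intensity.csv)")
    df = pd.read_csv(intensity_path)
    endpoint = cfg.analysis.get("endpoint_h", df["time_h"].max())
    end = df[np.isclose(df["time_h"], endpoint)]
    table = end.rename(columns={"label": "condition", "norm_intensity": "value"})
    summary, comparisons = summarize_conditions(table)
    paths = [out / "summary.csv", out / "stats.csv"]
    write_table(summary, paths[0])
    write_table(comparisons, paths[1])
    return paths


def run_pipeline(config: RunConfig, stages: list[str]) -> dict:
    """Execute the requested stages in canonical order; return the manifest."""
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": [], "seed": config.seed}
    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        params = getattr(config, stage if stage != "analyze" else "analysis", {})
        if stage == "flow":
            outputs = _run_flow(config, out)
        elif stage == "transport":
            outputs = _run_transport(config, out)
        elif stage == "synth":
            outputs = _run_synth(config, out, config.seed)
        elif stage == "analyze":
            outputs = _run_analyze(config, out)
        else:
            outputs = _run_stats(config, out)
        manifest["stages"].append(
            {
                "stage": stage,
                "params_hash": config_hash(params),
                "outputs": {str(p): _file_hash(Path(p)) for p in outputs},
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
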
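"""End-to-end preset runs: regulatory steady state -> branching kymograph
-> vane geometry -> silhouette, with a JSON manifest that fully
regenerates every artifact."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from .grid import SpatialGrid
from .mrf import solve_preset_state, SteadyState
from .pb import initial_pb_fields, run_pb, Kymograph
from .presets import Preset, load_preset


@dataclass
class RunConfig:
    preset: str
    out_dir: str | Path = "runs"
    seed: int = 0
    n_points: int | None = None           # override the preset's grid
    stages: tuple[str, ...] = ("mrf", "pb", "geometry")
    pb_n_steps: int | None = None
    render_png: bool = False


@dataclass
class PipelineResult:
    preset: Preset
    steady: SteadyState
    kymograph: Kymograph | None
    zone_map: geo.ZoneMap | None
    vane_geometry: geo.VaneGeometry | None
    manifest: dict = field(default_factory=dict)


def run_mrf_stage(preset: Preset, grid: SpatialGrid, seed: int) -> SteadyState:
    run = preset.run
    ss = solve_preset_state(
        preset.mrf, grid, seed=seed,
        noise_amplitude=float(run["mrf_noise_amplitude"]),
        dt=float(run["mrf_dt"]), tol=float(run["mrf_tol"]),
        max_steps=int(run["mrf_max_steps"]),
    )
    return ss


def run_pb_stage(
    preset: Preset, grid: SpatialGrid, steady: SteadyState, seed: int,
    n_steps: int | None = None,
) -> Kymograph:
    run = preset.run
    grem = steady.profile("GREM")
    gdf = steady.profile("GDF")
    A, B, C = initial_pb_fields(
        preset.pb, grid, grem=0.0, gdf=0.0,
        noise_amplitude=float(run["pb_noise_amplitude"]), seed=seed,
    )
    return run_pb(
        A, B, C, grem, gdf, preset.pb, grid,
        n_steps=int(n_steps or run["pb_n_steps"]),
        record_every=int(run["pb_record_every"]), seed=seed,
    )


def run_geometry_stage(
    preset: Preset, grid: SpatialGrid, steady: SteadyState,
    kymo: Kymograph,
) -> tuple[geo.ZoneMap, geo.VaneGeometry]:
    zones = geo.classify_zones(
        steady, grid,
        grem_threshold=float(preset.zones["grem_threshold"]),
        gdf_threshold=float(preset.zones["gdf_threshold"]),
    )
    elong = float(preset.geometry["elongation_V"])
    beta = float(preset.geometry["beta_expand"])
    rar = steady.profile("RAR")
    thetas = {}
    for side in ("lateral", "medial"):
        idx = np.nonzero(zones.labels == f"vane_{side}")[0]
        rho, v_mult, _ = geo.cell_shape_modifiers(rar[idx] if idx.size else 0.0)
        try:
            stats = geo.estimate_wave_speed(kymo, zone=idx, side=side)
            speed = stats.speed_W
        except (geo.DegeneratePatternError, ValueError, IndexError):
            speed = 0.0
        thetas[side] = geo.helical_angle(speed, elong * v_mult)
    vg = geo.VaneGeometry(
        theta_lateral=thetas["lateral"], theta_medial=thetas["medial"],
        beta_expand=beta, elongation_V=elong, zone_map=zones,
    )
    return zones, vg


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the configured stages in order and write the artifacts."""
    preset = load_preset(config.preset)
    n = int(config.n_points or preset.run["n_points"])
    grid = SpatialGrid(n)
    out = Path(config.out_dir) / config.preset
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    steady = run_mrf_stage(preset, grid, config.seed)
    if not steady.converged:
        raise RuntimeError(
            f"stage mrf: no steady state after {steady.n_steps} steps "
            f"(residual {steady.residual:.3g})"
        )
    tidy = pd.DataFrame(
        [
            {"x": x, "species": s, "concentration": c}
            for s in steady.state.fields
            for x, c in zip(grid.x, steady.state.fields[s])
        ]
    )
    tidy.to_csv(out / "steady_state.csv", index=False)

    kymo = zone_map = vane = None
    if "pb" in config.stages:
        kymo = run_pb_stage(preset, grid, steady, config.seed,
                            n_steps=config.pb_n_steps)
        np.savetxt(out / "kymograph.csv", kymo.A_xt, delimiter=",")
        if config.render_png:
            render_kymograph_png(kymo, out / "kymograph.png")
    if "geometry" in config.stages:
        if kymo is None:
            raise RuntimeError("stage geometry: requires the pb stage")
        zone_map, vane = run_geometry_stage(preset, grid, steady, kymo)
        report = {
            "theta_lateral_deg": vane.theta_lateral,
            "theta_medial_deg": vane.theta_medial,
            "barb_rachis_angle_lateral_deg": vane.barb_rachis_angle_lateral,
            "barb_rachis_angle_medial_deg": vane.barb_rachis_angle_medial,
            "rachis_width": zone_map.rachis_width,
            "bgz_width": zone_map.bgz_width,
            "vane_lateral_width": zone_map.vane_lateral_width,
            "vane_medial_width": zone_map.vane_medial_width,
            "asymmetry_index": zone_map.asymmetry_index,
            "barb_length_lateral": vane.barb_length("lateral"),
            "barb_length_medial": vane.barb_length("medial"),
        }
        with open(out / "geometry.json", "w") as fh:
            json.dump(report, fh, indent=2)
        sil = geo.render_silhouette(vane, length=1.0, n_slices=40)
        render_silhouette_svg(sil, out / "silhouette.svg")

    manifest = {
        "preset": config.preset,
        "description": preset.description,
        "seed": config.seed,
        "n_points": n,
        "stages": list(config.stages),
        "mrf": {"residual": steady.residual, "n_steps": steady.n_steps,
                "converged": steady.converged},
        "pb_params_digest": preset.pb.digest(),
        "run_config": preset.run,
        "zones": preset.zones,
        "geometry_config": preset.geometry,
        "elapsed_s": round(time.time() - t0, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(preset, steady, kymo, zone_map, vane, manifest)


def render_kymograph_png(kymo: Kymograph, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(
        kymo.A_xt, aspect="auto", origin="lower", cmap="magma",
        extent=[0, 1, kymo.times[0], kymo.times[-1]],
    )
    ax.set_xlabel("circumferential position x")
    ax.set_ylabel("time")
    fig.colorbar(im, label="activator A")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def render_silhouette_svg(sil: geo.FeatherSilhouette, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 6))
    ax.fill(sil.outline[:, 0], sil.outline[:, 1], color="#dcd3c0",
            ec="#555555", lw=0.8)
    for seg in sil.barbs_lateral + sil.barbs_medial:
        ax.plot(seg[:, 0], seg[:, 1], color="#777777", lw=0.5)
    if sil.rachis is not None:
        ax.plot(sil.rachis[:, 0], sil.rachis[:, 1], color="#333333", lw=2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
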
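"""Pipeline orchestration: simulate -> route -> classify -> ratios -> expose -> compare."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from . import io
from .classification import classify_subjects
from .comparison import compare_pair, summarize
from .exposure import compute_exposures
from .models import RatioTable
from .routing import complete_trips, filter_subjects, route_population
from .synthetic import ScenarioConfig, generate_scenario
from .temporal import compute_hourly_ratios

log = logging.getLogger("commute_exposure")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    outdir: Path = Path("pipeline_out")
    seed: int | None = None  # overrides scenario.seed when set
    n_perm: int = 999
    make_plots: bool = True
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "route", "classify", "ratios", "expose", "compare"]
    )

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.seed is not None and self.seed != self.scenario.seed:
            self.scenario = dataclasses.replace(self.scenario, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        scen = raw.pop("scenario", {})
        if "domain_extent" in scen:
            scen["domain_extent"] = tuple(scen["domain_extent"])
        return cls(scenario=ScenarioConfig(**scen), **raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("running stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, e) from e

        wrapped.__name__ = fn.__name__
        return wrapped

    return deco


@_stage("simulate")
def stage_simulate(config: ScenarioConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    network, grids, subjects, stations, truth = generate_scenario(config)
    io.write_json(io.network_to_geojson(network), outdir / "network.geojson")
    for g in grids:
        io.write_ascii_grid(g, outdir / f"grid_{g.cell_size:g}m.asc")
    io.write_json(io.subjects_to_geojson(subjects), outdir / "population.geojson")
    io.stations_to_csv(stations, outdir / "stations.csv")
    io.write_json(
        {
            "true_ratio_m": list(truth.true_ratios.ratio_m),
            "true_ratio_s": list(truth.true_ratios.ratio_s),
            "true_model_bias": truth.true_model_bias,
            "seed": config.seed,
        },
        outdir / "ground_truth.json",
    )
    return {"n_subjects": len(subjects), "n_grids": len(grids)}


@_stage("route")
def stage_route(network_path: Path, population_path: Path, out_path: Path, extent) -> dict:
    network = io.network_from_geojson(io.read_json(network_path))
    subjects = io.subjects_from_geojson(io.read_json(population_path))
    kept, reasons = filter_subjects(subjects, extent)
    kept = route_population(network, kept)
    kept = [complete_trips(s) for s in kept]
    io.write_json(io.subjects_to_geojson(kept), out_path)
    return {"n_kept": len(kept), "rejections": dict(reasons)}


@_stage("classify")
def stage_classify(legs_path: Path, network_path: Path) -> dict:
    network = io.network_from_geojson(io.read_json(network_path))
    subjects = io.subjects_from_geojson(io.read_json(legs_path))
    classify_subjects(subjects, network)
    io.write_json(io.subjects_to_geojson(subjects), legs_path)
    n_main = sum(1 for s in subjects for leg in s.all_legs() if leg.road_class == "main")
    n_legs = sum(len(s.all_legs()) for s in subjects)
    return {"n_legs": n_legs, "main_fraction": n_main / n_legs if n_legs else 0.0}


@_stage("ratios")
def stage_ratios(stations_path: Path, out_path: Path) -> dict:
    stations = {s.site_type: s for s in io.stations_from_csv(stations_path)}
    table = compute_hourly_ratios(stations["street"], stations["background"])
    io.ratios_to_csv(table, out_path)
    return {"ratio_m_mean": float(table.ratio_m.mean()), "ratio_s_mean": float(table.ratio_s.mean())}


@_stage("expose")
def stage_expose(legs_path: Path, ratios_path: Path, grids_dir: Path, out_path: Path) -> dict:
    grid_files = sorted(Path(grids_dir).glob("grid_*.asc"))
    if not grid_files:
        raise FileNotFoundError(f"no grid_*.asc files in {grids_dir}")
    grids = [io.read_ascii_grid(p, model_name=p.stem.replace("grid_", "model_")) for p in grid_files]
    subjects = io.subjects_from_geojson(io.read_json(legs_path))
    ratios = io.ratios_from_csv(ratios_path)
    records = compute_exposures(subjects, ratios, grids)
    legs_out = out_path.with_name(out_path.stem + "_legs.csv")
    io.exposures_to_csv(records, out_path, legs_out)
    return {"n_records": len(records), "models": [g.model_name for g in grids]}


@_stage("compare")
def stage_compare(
    exposure_path: Path, outdir: Path, n_perm: int, seed: int, make_plots: bool = True
) -> dict:
    import pandas as pd

    df = io.exposures_from_csv(exposure_path)
    wide = df.pivot(index="subject_id", columns="model_name", values="time_weighted")
    models = sorted(wide.columns)
    rows = []
    summaries = []
    for m in models:
        summaries.append({"model": m, **summarize(wide[m].to_numpy())})
    for a, b in combinations(models, 2):
        res = compare_pair(
            a, b, wide[a].to_numpy(), wide[b].to_numpy(), n_perm=n_perm, seed=seed
        )
        rows.append(
            {
                "model_a": res.model_a,
                "model_b": res.model_b,
                "n": res.n,
                "mean_diff": res.mean_diff,
                "sd_diff": res.sd_diff,
                "loa_low": res.loa_low,
                "loa_high": res.loa_high,
                "spearman_rho": res.spearman_rho,
                "fit_degree": res.fit_degree,
                **{f"fit_r2_deg{d}": r for d, r in res.fit_r2.items()},
                "wilcoxon_p": res.wilcoxon_p,
                "fisher_pitman_p": res.fisher_pitman_p,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "comparison.csv", index=False)
    pd.DataFrame(summaries).to_csv(outdir / "summary.csv", index=False)
    if make_plots:
        _plots(wide, models, outdir)
    return {"n_pairs": len(rows)}


def _plots(wide, models, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .comparison import bland_altman

    pairs = list(combinations(models, 2))
    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.5), squeeze=False)
    for ax, (a, b) in zip(axes[0], pairs):
        ba = bland_altman(wide[a].to_numpy(), wide[b].to_numpy())
        ax.scatter(ba["mean_of_pairs"], ba["diffs"], s=8, alpha=0.6)
        for y in (ba["mean_diff"], ba["loa_low"], ba["loa_high"]):
            ax.axhline(y, color="k", lw=0.8, ls="--")
        ax.set_xlabel(f"mean of {a}, {b}")
        ax.set_ylabel(f"{b} - {a}")
    fig.tight_layout()
    fig.savefig(outdir / "bland_altman.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.5), squeeze=False)
    for ax, (a, b) in zip(axes[0], pairs):
        ax.scatter(wide[a], wide[b], s=8, alpha=0.6)
        ax.set_xlabel(a)
        ax.set_ylabel(b)
    fig.tight_layout()
    fig.savefig(outdir / "scatter.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write a JSON manifest.

    Returns the manifest dict.  Any stage failure raises PipelineError
    naming the stage.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    scen = config.scenario
    info: dict = {}
    if "simulate" in config.stages:
        info["simulate"] = stage_simulate(scen, out)
    if "route" in config.stages:
        info["route"] = stage_route(
            out / "network.geojson", out / "population.geojson",
            out / "legs.geojson", scen.domain_extent,
        )
    if "classify" in config.stages:
        info["classify"] = stage_classify(out / "legs.geojson", out / "network.geojson")
    if "ratios" in config.stages:
        info["ratios"] = stage_ratios(out / "stations.csv", out / "ratios.csv")
    if "expose" in config.stages:
        info["expose"] = stage_expose(
            out / "legs.geojson", out / "ratios.csv", out, out / "exposure.csv"
        )
    if "compare" in config.stages:
        info["compare"] = stage_compare(
            out / "exposure.csv", out, config.n_perm, scen.seed, config.make_plots
        )

    outputs = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": scen.seed,
        "scenario": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(scen).items()
        },
        "stages": info,
        "outputs": {name: io.sha256_of(out / name) for name in outputs},
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
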
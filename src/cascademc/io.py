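"""File I/O, run configuration, and the end-to-end pipeline.

The pipeline binds the stages together: load a network description and its
per-edge CSV data, fit and bootstrap every edge, build the cascade, run the
Monte Carlo ensemble, scan for KS thresholds, and emit density clouds —
writing every artifact (fit reports, ensemble CSV, threshold JSON, cloud
CSV, plots, manifest) into one output directory.  A single master seed
spawns independent per-stage substreams so that, e.g., changing the number
of replicates does not perturb the bootstrap results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .density import build_cloud, cloud_to_records, overlay_observations
from .ensemble import (
    DEFAULT_SAMPLED_COEFFICIENTS,
    CascadeEdge,
    CascadeNetwork,
    Ensemble,
    ci_to_gaussian,
    simulate,
)
from .regression import (
    BootstrapCI,
    DoseResponseData,
    EdgeFit,
    SigmoidDirection,
    bootstrap_edge,
    fit_edge,
    kendall_tau,
)
from .thresholds import find_thresholds

logger = logging.getLogger("cascademc")

__all__ = ["RunConfig", "load_edge_csv", "load_network_config", "build_network", "run_pipeline"]


def load_edge_csv(path: str | Path) -> DoseResponseData:
    """Read a two-column `x,y` CSV (``#`` comments skipped) into paired data.

    Errors name the offending row so sparse hand-edited tables are easy to
    fix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge data file not found: {path}")
    xs, ys = [], []
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                cols = [c.strip().lower() for c in line.split(",")]
                if cols[:2] != ["x", "y"]:
                    raise ValueError(f"{path}: expected header 'x,y', got {line!r}")
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise ValueError(f"{path}, row {lineno}: expected two columns, got {line!r}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}, row {lineno}: non-numeric cell in {line!r}") from exc
    if len(xs) < 4:
        raise ValueError(f"{path}: need at least 4 data rows, found {len(xs)}")
    return DoseResponseData(xs, ys)


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for one pipeline run."""

    network_path: Path
    out_dir: Path
    grid_min: float = 0.0
    grid_max: float = 6.0
    grid_points: int = 25
    replicates: int = 1000
    m_bootstrap: int = 999
    alpha: float = 0.05
    seed: int = 0
    sampled_coefficients: frozenset[str] = DEFAULT_SAMPLED_COEFFICIENTS
    bootstrap_curve_mode: bool = False
    exclude_data: tuple[str, ...] = ()
    make_plots: bool = True
    n_bins: int = 100

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.m_bootstrap < 39:
            raise ValueError("m_bootstrap must be >= 39")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.grid_min >= self.grid_max:
            raise ValueError("grid_min must be < grid_max")
        if self.grid_points < 3:
            raise ValueError("grid_points must be >= 3")

    def to_dict(self) -> dict:
        return {
            "network_path": str(self.network_path),
            "out_dir": str(self.out_dir),
            "grid_min": self.grid_min,
            "grid_max": self.grid_max,
            "grid_points": self.grid_points,
            "replicates": self.replicates,
            "m_bootstrap": self.m_bootstrap,
            "alpha": self.alpha,
            "seed": self.seed,
            "sampled_coefficients": sorted(self.sampled_coefficients),
            "bootstrap_curve_mode": self.bootstrap_curve_mode,
            "exclude_data": list(self.exclude_data),
            "make_plots": self.make_plots,
            "n_bins": self.n_bins,
        }


def load_network_config(path: str | Path) -> dict:
    """Load and minimally validate a YAML/JSON network description."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("nodes", "edges"):
        if key not in cfg:
            raise ValueError(f"{path}: network config missing {key!r} section")
    return cfg


def config_from_network(
    network_path: str | Path, out_dir: str | Path, **overrides
) -> RunConfig:
    """RunConfig from the network file's `simulation` block plus overrides."""
    cfg = load_network_config(network_path)
    sim = dict(cfg.get("simulation", {}))
    sampled = sim.pop("sampled_coefficients", sorted(DEFAULT_SAMPLED_COEFFICIENTS))
    kwargs = {
        "grid_min": sim.get("grid_min", 0.0),
        "grid_max": sim.get("grid_max", 6.0),
        "grid_points": sim.get("grid_points", 25),
        "replicates": sim.get("replicates", 1000),
        "m_bootstrap": sim.get("m_bootstrap", 999),
        "alpha": sim.get("alpha", 0.05),
        "seed": sim.get("seed", 0),
        "sampled_coefficients": frozenset(sampled),
    }
    kwargs.update(overrides)
    return RunConfig(network_path=Path(network_path), out_dir=Path(out_dir), **kwargs)


def _substreams(seed: int) -> dict[str, np.random.SeedSequence]:
    root = np.random.SeedSequence(seed)
    boot, sim = root.spawn(2)
    return {"bootstrap": boot, "simulation": sim}


def build_network(
    config: RunConfig,
) -> CascadeNetwork:
    """Load data, fit and bootstrap every edge, and assemble the cascade.

    Edges whose data file is listed in ``config.exclude_data`` keep their
    place in the chain but must still have at least one usable data file;
    exclusion removes listed files from a multi-file edge or drops the rows
    of a single file entirely, in which case loading fails loudly.
    """
    cfg = load_network_config(config.network_path)
    base = Path(config.network_path).parent
    streams = _substreams(config.seed)
    boot_seeds = streams["bootstrap"].generate_state(len(cfg["edges"]))

    edges = []
    for i, e in enumerate(cfg["edges"]):
        data_files = e["data"] if isinstance(e["data"], list) else [e["data"]]
        kept = [f for f in data_files if f not in config.exclude_data]
        if not kept:
            raise ValueError(
                f"edge {e['parent']}->{e['child']}: every data file is excluded"
            )
        frames = [load_edge_csv(base / f) for f in kept]
        x = np.concatenate([d.x for d in frames])
        y = np.concatenate([d.y for d in frames])
        data = DoseResponseData(x, y)
        direction = {
            "auto": None,
            "increasing": SigmoidDirection.INCREASING,
            "decreasing": SigmoidDirection.DECREASING,
        }[e.get("direction", "auto")]
        fit = fit_edge(data, direction)
        tau = kendall_tau(data.x, data.y)
        logger.info(
            "edge %s->%s: tau=%.3f direction=%s ymax=%.4g K=%.4g h=%.4g ssr=%.4g",
            e["parent"], e["child"], tau, fit.direction.value,
            fit.coefficients.ymax, fit.coefficients.K, fit.coefficients.h, fit.ssr,
        )
        ci = bootstrap_edge(fit, m=config.m_bootstrap, rng_seed=int(boot_seeds[i] % (2**31)))
        dist = ci_to_gaussian(ci, config.sampled_coefficients)
        edges.append(
            CascadeEdge(parent=e["parent"], child=e["child"], fit=fit, ci=ci, distribution=dist)
        )
    return CascadeNetwork(nodes=tuple(cfg["nodes"]), edges=tuple(edges))


def _fit_report(edge: CascadeEdge) -> dict:
    return {
        "parent": edge.parent,
        "child": edge.child,
        "direction": edge.direction.value,
        "ymax": edge.fit.coefficients.ymax,
        "K": edge.fit.coefficients.K,
        "h": edge.fit.coefficients.h,
        "ci": {
            name: [iv.lower, iv.upper] for name, iv in edge.ci.intervals.items()
        },
        "m": edge.ci.m,
        "n_failed": edge.ci.n_failed,
        "seed": edge.ci.seed,
    }


def ensemble_to_frame(ens: Ensemble) -> pd.DataFrame:
    """Long-format (node, input, replicate, value) table of an ensemble."""
    rows = []
    for node, mat in ens.values.items():
        R, G = mat.shape
        rows.append(
            pd.DataFrame(
                {
                    "node": node,
                    "input": np.repeat(ens.input_grid, R),
                    "replicate": np.tile(np.arange(R), G),
                    "value": mat.T.ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: RunConfig) -> Path:
    """Run fit -> simulate -> thresholds -> cloud and write all artifacts.

    Returns the output directory.  Re-running with the same config
    reproduces all numeric outputs exactly (plots excluded from that
    guarantee).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = "failed"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    try:
        network = build_network(config)
    except Exception as exc:  # noqa: BLE001 - stage-labeled diagnostics
        fail("fit", exc)
    manifest["stages"]["fit"] = "ok"
    with open(out / "fits.json", "w") as fh:
        json.dump([_fit_report(e) for e in network.edges], fh, indent=2)

    try:
        grid = np.linspace(config.grid_min, config.grid_max, config.grid_points)
        sim_seed = int(_substreams(config.seed)["simulation"].generate_state(1)[0] % (2**31))
        ens = simulate(
            network,
            grid,
            config.replicates,
            seed=sim_seed,
            bootstrap_curve_mode=config.bootstrap_curve_mode,
        )
    except Exception as exc:  # noqa: BLE001
        fail("simulate", exc)
    manifest["stages"]["simulate"] = "ok"
    ensemble_to_frame(ens).to_csv(out / "ensemble.csv", index=False, float_format="%.10g")

    try:
        leaf = network.leaf
        thr = find_thresholds(ens, leaf, config.alpha)
    except Exception as exc:  # noqa: BLE001
        fail("thresholds", exc)
    manifest["stages"]["thresholds"] = "ok"
    with open(out / "thresholds.json", "w") as fh:
        json.dump(
            {
                "node": thr.node,
                "alpha": thr.alpha,
                "lower": thr.lower,
                "upper": thr.upper,
                "scan": [
                    {
                        "input": r.input,
                        "D_vs_low": r.D_vs_low,
                        "D_vs_high": r.D_vs_high,
                        "critical": r.critical,
                        "reject_low": r.reject_low,
                        "reject_high": r.reject_high,
                    }
                    for r in thr.scan
                ],
            },
            fh,
            indent=2,
        )

    try:
        cloud = build_cloud(ens, network.leaf, config.n_bins)
        pd.DataFrame(cloud_to_records(cloud)).to_csv(
            out / "cloud.csv", index=False, float_format="%.10g"
        )
        if config.make_plots:
            observed = network.edges[-1].fit.data if len(network.edges) == 1 else None
            overlay_observations(cloud, observed, out / "cloud.png")
    except Exception as exc:  # noqa: BLE001
        fail("cloud", exc)
    manifest["stages"]["cloud"] = "ok"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info(
        "pipeline complete: leaf=%s lower=%s upper=%s -> %s",
        network.leaf, thr.lower, thr.upper, out,
    )
    return out
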
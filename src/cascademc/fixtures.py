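"""Synthetic cascades with known ground truth.

Generates the kind of data the method is built for: sparse (5-15 point)
response-response tables whose mean follows a monotone Hill sigmoid with
additive homoscedastic Gaussian noise, chainable across several edges the
way chained endpoint measurements share a common exposure series.  Every
generator is seeded and emits a truth record, so parameter-recovery and
end-to-end pipeline tests run without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .regression import DoseResponseData, SigmoidCoefficients, SigmoidDirection, sigmoid_eval

__all__ = [
    "SyntheticEdgeSpec",
    "SyntheticCascadeSpec",
    "generate_edge_data",
    "generate_cascade",
    "default_cascade_spec",
]


@dataclass(frozen=True)
class SyntheticEdgeSpec:
    """Ground truth for one synthetic edge.

    ``x_design`` is the explicit parent-activity design; ``noise_sd`` is the
    sd of the additive Gaussian noise on the child response (child units).
    """

    true_coefficients: SigmoidCoefficients
    direction: SigmoidDirection
    noise_sd: float
    x_design: np.ndarray
    name: str = "edge"

    def __post_init__(self) -> None:
        design = np.asarray(self.x_design, dtype=float)
        if design.ndim != 1 or len(design) < 4:
            raise ValueError("x_design must be a 1-D sequence of >= 4 points")
        if np.any(design < 0):
            raise ValueError("design points must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "x_design", design)

    @property
    def n_points(self) -> int:
        return len(self.x_design)


@dataclass(frozen=True)
class SyntheticCascadeSpec:
    """An ordered chain of synthetic edges plus node names and a seed."""

    edges: tuple[SyntheticEdgeSpec, ...]
    node_names: tuple[str, ...]
    seed: int = 0
    noisy_x: bool = False

    def __post_init__(self) -> None:
        if len(self.edges) < 1:
            raise ValueError("cascade needs at least one edge")
        if len(self.node_names) != len(self.edges) + 1:
            raise ValueError("need one node name per edge plus the root")


def generate_edge_data(spec: SyntheticEdgeSpec, seed: int | None = None) -> DoseResponseData:
    """Noisy paired data from one edge's true sigmoid: y = f(x) + N(0, sd)."""
    rng = np.random.default_rng(seed)
    y_true = sigmoid_eval(spec.x_design, spec.true_coefficients, spec.direction)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_points) if spec.noise_sd > 0 else 0.0
    return DoseResponseData(spec.x_design, np.asarray(y_true) + noise)


def generate_cascade(spec: SyntheticCascadeSpec, out_dir: str | Path) -> dict:
    """Write a ready-to-run cascade directory: edge CSVs, network YAML, truth JSON.

    Each edge's design points are the previous edge's *noise-free* outputs at
    its design points (chained endpoints measured on a shared exposure
    series), unless ``noisy_x`` requests the noisy child values instead.
    Returns the truth record that was written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    truth: dict = {"seed": spec.seed, "nodes": list(spec.node_names), "edges": []}
    net_edges = []
    x_current = None
    for i, edge in enumerate(spec.edges):
        if x_current is None:
            design = edge.x_design
        else:
            design = np.asarray(x_current, dtype=float)
        eff = SyntheticEdgeSpec(
            true_coefficients=edge.true_coefficients,
            direction=edge.direction,
            noise_sd=edge.noise_sd,
            x_design=design,
            name=edge.name,
        )
        data = generate_edge_data(eff, seed=int(rng.integers(0, 2**31 - 1)))
        parent, child = spec.node_names[i], spec.node_names[i + 1]
        csv_path = out_dir / f"{parent}__{child}.csv"
        with open(csv_path, "w") as fh:
            fh.write("x,y\n")
            for xv, yv in zip(data.x, data.y):
                fh.write(f"{float(xv)!r},{float(yv)!r}\n")
        net_edges.append(
            {"parent": parent, "child": child, "data": csv_path.name, "direction": "auto"}
        )
        truth["edges"].append(
            {
                "parent": parent,
                "child": child,
                "ymax": edge.true_coefficients.ymax,
                "K": edge.true_coefficients.K,
                "h": edge.true_coefficients.h,
                "direction": edge.direction.value,
                "noise_sd": edge.noise_sd,
                "data": csv_path.name,
            }
        )
        y_clean = np.asarray(
            sigmoid_eval(design, edge.true_coefficients, edge.direction)
        )
        x_current = np.asarray(data.y) if spec.noisy_x else y_clean

    root_design = spec.edges[0].x_design
    network_cfg = {
        "nodes": list(spec.node_names),
        "edges": net_edges,
        "simulation": {
            "grid_min": float(np.min(root_design)),
            "grid_max": float(np.max(root_design)),
            "grid_points": 25,
            "replicates": 1000,
            "m_bootstrap": 999,
            "alpha": 0.05,
            "seed": spec.seed,
            "sampled_coefficients": ["K", "h"],
        },
    }
    with open(out_dir / "network.yaml", "w") as fh:
        yaml.safe_dump(network_cfg, fh, sort_keys=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth


def default_cascade_spec(
    seed: int = 0,
    n_points: int = 12,
    noise_fraction: float = 0.10,
) -> SyntheticCascadeSpec:
    """A 4-edge cascade mimicking an abridged reproductive AOP chain.

    Receptor activation (fold change, 0-6) suppresses an enzyme-like
    activity, which drives a hormone-like concentration, a biomarker-like
    concentration, and finally a fecundity-like output — one increasing edge
    feeding three chained responses.  Noise sd per edge is
    ``noise_fraction * ymax`` (default 10%, within the realistic 5-30% band
    for sparse in vivo endpoint tables).
    """
    x0 = np.linspace(0.25, 6.0, n_points)
    mk = SigmoidCoefficients
    # each K sits mid-range of the edge's actual (chained) input span and the
    # span reaches near-saturation on both sides, so every edge is
    # identifiable from its own data — as in a well-designed exposure series
    edges = (
        SyntheticEdgeSpec(mk(1.0, 3.0, 3.0), SigmoidDirection.DECREASING,
                          noise_fraction * 1.0, x0, name="receptor_to_enzyme"),
        SyntheticEdgeSpec(mk(25.0, 0.4, 3.0), SigmoidDirection.INCREASING,
                          noise_fraction * 25.0, x0, name="enzyme_to_hormone"),
        SyntheticEdgeSpec(mk(4.0, 6.0, 2.0), SigmoidDirection.INCREASING,
                          noise_fraction * 4.0, x0, name="hormone_to_biomarker"),
        SyntheticEdgeSpec(mk(30.0, 1.2, 2.5), SigmoidDirection.INCREASING,
                          noise_fraction * 30.0, x0, name="biomarker_to_fecundity"),
    )
    return SyntheticCascadeSpec(
        edges=edges,
        node_names=("receptor", "enzyme", "hormone", "biomarker", "fecundity"),
        seed=seed,
    )
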
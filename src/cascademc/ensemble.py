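"""Cascade networks and Monte Carlo propagation of an input activity.

A cascade is an ordered single-parent chain of nodes (root = the input,
leaf = the apical output).  Each edge carries a fitted sigmoid plus the
Gaussian parameter distributions implied by its bootstrap confidence
intervals: mean = interval midpoint, sd = width / (2 * 1.959964).  A single
simulation draws one coefficient set per edge (rejecting nonpositive draws)
and propagates the input value through the chain; repeating this over a grid
of input levels and R replicates yields an :class:`Ensemble` of per-node
response distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .regression import (
    Z_95,
    BootstrapCI,
    EdgeFit,
    SigmoidCoefficients,
    SigmoidDirection,
    sigmoid_eval,
)

logger = logging.getLogger("cascademc")

__all__ = [
    "ParameterDistribution",
    "CascadeEdge",
    "CascadeNetwork",
    "Ensemble",
    "DegenerateDistributionError",
    "MultiParentError",
    "ci_to_gaussian",
    "sample_edge_parameters",
    "propagate",
    "simulate",
]

#: default coefficient subset drawn stochastically (ymax held at its point
#: estimate; CI tables report K and h)
DEFAULT_SAMPLED_COEFFICIENTS = frozenset({"K", "h"})

_COEF_NAMES = ("ymax", "K", "h")
_REJECTION_CAP = 1000


class DegenerateDistributionError(RuntimeError):
    """Positive draws could not be obtained; the CI conflicts with positivity."""


class MultiParentError(ValueError):
    """Raised when a node would receive more than one incoming edge."""


@dataclass(frozen=True)
class ParameterDistribution:
    """Independent Gaussians for (ymax, K, h) implied by 95% CIs.

    Coefficients outside ``sampled`` have sd 0 and mean equal to the point
    estimate, making their draws deterministic.
    """

    means: dict[str, float]
    sds: dict[str, float]
    sampled: frozenset[str]

    def __post_init__(self) -> None:
        for name in _COEF_NAMES:
            if self.sds[name] < 0:
                raise ValueError(f"sd for {name} must be nonnegative")


def ci_to_gaussian(
    ci: BootstrapCI, sampled: frozenset[str] | set[str] = DEFAULT_SAMPLED_COEFFICIENTS
) -> ParameterDistribution:
    """Convert bootstrap CIs to the Gaussian underlying a 95% interval.

    mean = (upper + lower) / 2 and sd = (upper - lower) / (2 * 1.959964) for
    each sampled coefficient; unsampled coefficients are fixed at their point
    estimate with sd 0.
    """
    sampled = frozenset(sampled)
    unknown = sampled - set(_COEF_NAMES)
    if unknown:
        raise ValueError(f"unknown coefficient names in sampled set: {sorted(unknown)}")
    means, sds = {}, {}
    for name in _COEF_NAMES:
        iv = ci[name]
        if name in sampled:
            means[name] = 0.5 * (iv.upper + iv.lower)
            sds[name] = (iv.upper - iv.lower) / (2.0 * Z_95)
        else:
            means[name] = iv.point
            sds[name] = 0.0
    return ParameterDistribution(means=means, sds=sds, sampled=sampled)


def sample_edge_parameters(
    dist: ParameterDistribution, rng: np.random.Generator
) -> SigmoidCoefficients:
    """Draw one coefficient set: Normal(mean, sd) per sampled coefficient,
    redrawn until positive (rejection, capped), fixed coefficients as-is."""
    values = {}
    for name in _COEF_NAMES:
        mu, sd = dist.means[name], dist.sds[name]
        if sd == 0.0:
            values[name] = mu
            continue
        for _ in range(_REJECTION_CAP):
            draw = rng.normal(mu, sd)
            if draw > 0:
                values[name] = draw
                break
        else:
            raise DegenerateDistributionError(
                f"could not draw a positive {name} from Normal({mu}, {sd}) in "
                f"{_REJECTION_CAP} attempts; the CI is inconsistent with positivity"
            )
    return SigmoidCoefficients(**values)


@dataclass(frozen=True)
class CascadeEdge:
    """One parent->child interaction with its fit, CI, and sampling law."""

    parent: str
    child: str
    fit: EdgeFit
    ci: BootstrapCI
    distribution: ParameterDistribution

    @property
    def direction(self) -> SigmoidDirection:
        return self.fit.direction


@dataclass(frozen=True)
class CascadeNetwork:
    """Ordered single-parent cascade from the input node to the output node.

    ``nodes`` lists node names in topological order (root first).  Every
    non-root node has exactly one incoming edge whose parent precedes it.
    """

    nodes: tuple[str, ...]
    edges: tuple[CascadeEdge, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError("a cascade needs at least two nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        order = {name: i for i, name in enumerate(self.nodes)}
        seen_children: dict[str, str] = {}
        for e in self.edges:
            if e.parent not in order or e.child not in order:
                raise ValueError(f"edge {e.parent}->{e.child} references unknown node")
            if order[e.parent] >= order[e.child]:
                raise ValueError(
                    f"edge {e.parent}->{e.child} violates topological order"
                )
            if e.child in seen_children:
                raise MultiParentError(
                    f"node {e.child!r} has parents {seen_children[e.child]!r} and "
                    f"{e.parent!r}; convergent (multi-parent) edges are not supported"
                )
            seen_children[e.child] = e.parent
        root = self.nodes[0]
        if root in seen_children:
            raise ValueError(f"root node {root!r} must have no incoming edge")
        missing = [n for n in self.nodes[1:] if n not in seen_children]
        if missing:
            raise ValueError(f"nodes without an incoming edge: {missing}")

    @property
    def root(self) -> str:
        return self.nodes[0]

    @property
    def leaf(self) -> str:
        return self.nodes[-1]


def propagate(
    network: CascadeNetwork,
    input_value: float,
    drawn_params: dict[tuple[str, str], SigmoidCoefficients]
    | list[SigmoidCoefficients],
) -> dict[str, float]:
    """Push one input activity through the cascade with fixed drawn parameters.

    ``drawn_params`` supplies one coefficient set per edge, either keyed by
    (parent, child) or as a list in edge order.  Returns the activity of
    every node, root included.
    """
    if input_value < 0:
        raise ValueError("input activity must be nonnegative")
    if isinstance(drawn_params, list):
        if len(drawn_params) != len(network.edges):
            raise ValueError("need exactly one coefficient set per edge")
        drawn = {
            (e.parent, e.child): c for e, c in zip(network.edges, drawn_params)
        }
    else:
        drawn = drawn_params
    values: dict[str, float] = {network.root: float(input_value)}
    for e in network.edges:
        coefs = drawn[(e.parent, e.child)]
        values[e.child] = sigmoid_eval(values[e.parent], coefs, e.direction)
    return values


@dataclass(frozen=True)
class Ensemble:
    """Replicate-by-input-grid simulation output for every node.

    ``values[node]`` is an (R, len(input_grid)) array; the root node's array
    is the input grid broadcast across replicates.
    """

    input_grid: np.ndarray
    replicates: int
    values: dict[str, np.ndarray] = field(repr=False)
    seed: int | None = None

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.values)

    def node_column(self, node: str, grid_index: int) -> np.ndarray:
        """All replicate values of ``node`` at one input-grid point."""
        return self.values[node][:, grid_index]


def simulate(
    network: CascadeNetwork,
    input_grid,
    replicates: int,
    seed: int | None = None,
    *,
    bootstrap_curve_mode: bool = False,
) -> Ensemble:
    """Monte Carlo ensemble over an input grid.

    For every (replicate, grid value) pair a fresh coefficient set is drawn
    per edge — either from the Gaussians implied by the bootstrap CIs
    (default) or, in ``bootstrap_curve_mode``, uniformly from the stored
    pooled bootstrap coefficient vectors — and the input is propagated
    through the chain.  Columns of the result are therefore independent
    ensembles, one per input level, which is what the per-level KS threshold
    comparisons assume.
    """
    grid = np.asarray(input_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 1:
        raise ValueError("input grid must be a nonempty 1-D sequence")
    if np.any(np.diff(grid) < 0):
        raise ValueError("input grid must be sorted ascending")
    if np.any(grid < 0):
        raise ValueError("input activities must be nonnegative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    rng = np.random.default_rng(seed)
    G = len(grid)
    R = replicates
    values: dict[str, np.ndarray] = {network.root: np.broadcast_to(grid, (R, G)).copy()}

    # vectorized over the whole (R, G) block: draw an (R, G) matrix per
    # coefficient per edge, then evaluate the sigmoid elementwise
    for e in network.edges:
        parent_vals = values[e.parent]
        if bootstrap_curve_mode:
            idx = rng.integers(0, e.ci.samples.shape[0], size=(R, G))
            ymax = e.ci.samples[idx, 0]
            K = e.ci.samples[idx, 1]
            h = e.ci.samples[idx, 2]
        else:
            ymax = _draw_matrix(e.distribution, "ymax", rng, (R, G))
            K = _draw_matrix(e.distribution, "K", rng, (R, G))
            h = _draw_matrix(e.distribution, "h", rng, (R, G))
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            ratio = np.where(parent_vals > 0, np.power(parent_vals / K, h), 0.0)
            if e.direction is SigmoidDirection.INCREASING:
                child = np.where(np.isinf(ratio), ymax, ymax * ratio / (1.0 + ratio))
            else:
                child = ymax / (1.0 + ratio)
        values[e.child] = child
    return Ensemble(input_grid=grid, replicates=R, values=values, seed=seed)


def _draw_matrix(
    dist: ParameterDistribution, name: str, rng: np.random.Generator, shape: tuple[int, int]
) -> np.ndarray:
    """Matrix of truncated-at-zero Gaussian draws for one coefficient."""
    mu, sd = dist.means[name], dist.sds[name]
    if sd == 0.0:
        return np.full(shape, mu)
    out = rng.normal(mu, sd, size=shape)
    bad = out <= 0
    attempts = 0
    while np.any(bad):
        attempts += 1
        if attempts > _REJECTION_CAP:
            raise DegenerateDistributionError(
                f"could not draw positive values for {name} from Normal({mu}, {sd})"
            )
        out[bad] = rng.normal(mu, sd, size=int(bad.sum()))
        bad = out <= 0
    return out
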
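"""Conditional probability-density clouds of node responses.

For each input level of an ensemble, the replicate distribution of a node's
response is binned on a shared response axis and normalized into a
conditional probability mass function, reported as log10 probabilities.
Rendered as a heatmap with the experimental observations overlaid, the
cloud makes the model's predicted variability directly comparable with the
data it was trained on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import Ensemble
from .regression import DoseResponseData

__all__ = ["DensityCloud", "build_cloud", "overlay_observations"]

DEFAULT_N_BINS = 100


@dataclass(frozen=True)
class DensityCloud:
    """log10 conditional response probabilities on an input x response grid.

    ``log10_prob`` has shape (len(input_grid), len(response_bin_edges) - 1);
    empty bins hold NaN (undefined, rendered as background), and per input
    column the probabilities of the defined bins sum to 1.
    """

    node: str
    input_grid: np.ndarray
    response_bin_edges: np.ndarray
    log10_prob: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.response_bin_edges) - 1


def build_cloud(ensemble: Ensemble, node: str, n_bins: int = DEFAULT_N_BINS) -> DensityCloud:
    """Bin a node's replicate responses per input level into a log10 PMF cloud.

    Bins span the node's observed min-max over the whole ensemble.  When all
    responses are identical (zero range) the cloud degenerates to a single
    bin with log10 p = 0 in every column.
    """
    if node not in ensemble.values:
        raise ValueError(f"node {node!r} not present in ensemble")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mat = ensemble.values[node]
    lo, hi = float(np.min(mat)), float(np.max(mat))
    if lo == hi:
        # degenerate: one bin containing the single observed value
        edges = np.array([lo - 0.5, lo + 0.5])
        log10_prob = np.zeros((len(ensemble.input_grid), 1))
        return DensityCloud(
            node=node,
            input_grid=ensemble.input_grid,
            response_bin_edges=edges,
            log10_prob=log10_prob,
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    R = mat.shape[0]
    log10_prob = np.full((len(ensemble.input_grid), n_bins), np.nan)
    for j in range(len(ensemble.input_grid)):
        counts, _ = np.histogram(mat[:, j], bins=edges)
        nz = counts > 0
        log10_prob[j, nz] = np.log10(counts[nz] / R)
    return DensityCloud(
        node=node,
        input_grid=ensemble.input_grid,
        response_bin_edges=edges,
        log10_prob=log10_prob,
    )


def overlay_observations(
    cloud: DensityCloud,
    observed: DoseResponseData | None,
    path,
    *,
    input_label: str = "input activity",
    response_label: str | None = None,
) -> None:
    """Render the cloud as a heatmap with observed points overlaid, to a file.

    Observations falling outside the response range are drawn clipped at the
    plot margin.  Purely presentational: the only contract is that ``path``
    exists and is non-empty afterwards.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    grid = cloud.input_grid
    # pcolormesh needs cell edges on the input axis too
    if len(grid) > 1:
        mid = 0.5 * (grid[1:] + grid[:-1])
        x_edges = np.concatenate([[grid[0] - (mid[0] - grid[0])], mid,
                                  [grid[-1] + (grid[-1] - mid[-1])]])
    else:
        x_edges = np.array([grid[0] - 0.5, grid[0] + 0.5])
    mesh = ax.pcolormesh(
        x_edges,
        cloud.response_bin_edges,
        cloud.log10_prob.T,
        cmap="Blues_r",
        shading="flat",
    )
    fig.colorbar(mesh, ax=ax, label="log10 probability")
    if observed is not None and len(observed.x) > 0:
        y_lo, y_hi = cloud.response_bin_edges[0], cloud.response_bin_edges[-1]
        ax.plot(
            np.clip(observed.x, x_edges[0], x_edges[-1]),
            np.clip(observed.y, y_lo, y_hi),
            "o",
            color="red",
            markersize=5,
            label="observed",
        )
        ax.legend(loc="best")
    ax.set_xlabel(input_label)
    ax.set_ylabel(response_label or cloud.node)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cloud_to_records(cloud: DensityCloud) -> list[dict]:
    """Long-format (input, bin_lower, bin_upper, log10_prob) rows, defined bins only."""
    rows = []
    for i, x in enumerate(cloud.input_grid):
        for b in range(cloud.n_bins):
            p = cloud.log10_prob[i, b]
            if np.isnan(p):
                continue
            rows.append(
                {
                    "input": float(x),
                    "bin_lower": float(cloud.response_bin_edges[b]),
                    "bin_upper": float(cloud.response_bin_edges[b + 1]),
                    "log10_prob": float(p),
                }
            )
    return rows
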
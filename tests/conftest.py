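import numpy as np
import pytest

from cascademc import (
    BootstrapCI,
    CascadeEdge,
    CascadeNetwork,
    CoefficientInterval,
    DoseResponseData,
    EdgeFit,
    ParameterDistribution,
    SigmoidCoefficients,
    SigmoidDirection,
    sigmoid_eval,
)

INC = SigmoidDirection.INCREASING
DEC = SigmoidDirection.DECREASING


def exact_edge_data(coefs, direction, x=None):
    """Noise-free paired data lying exactly on a sigmoid."""
    if x is None:
        x = np.arange(0.5, 6.5, 0.5)
    x = np.asarray(x, dtype=float)
    return DoseResponseData(x, sigmoid_eval(x, coefs, direction))


def make_edge(parent, child, coefs, direction, sds=None):
    """A CascadeEdge with prescribed coefficients and Gaussian sds.

    The fit is synthetic (exact data, zero residuals) so that simulation
    behavior is fully controlled by ``coefs`` and ``sds``.
    """
    data = exact_edge_data(coefs, direction)
    fit = EdgeFit(
        direction=direction,
        coefficients=coefs,
        residuals=np.zeros(len(data)),
        data=data,
    )
    point = coefs.as_array()
    sds = sds or {}
    intervals = {}
    for j, name in enumerate(("ymax", "K", "h")):
        sd = sds.get(name, 0.0)
        half = 1.959964 * sd
        intervals[name] = CoefficientInterval(
            lower=point[j] - half, upper=point[j] + half, point=point[j]
        )
    ci = BootstrapCI(
        intervals=intervals, m=999, n_failed=0, samples=point[None, :].repeat(4, axis=0)
    )
    dist = ParameterDistribution(
        means={n: intervals[n].point if n not in sds else 0.5 * (intervals[n].lower + intervals[n].upper) for n in ("ymax", "K", "h")},
        sds={n: sds.get(n, 0.0) for n in ("ymax", "K", "h")},
        sampled=frozenset(sds),
    )
    return CascadeEdge(parent=parent, child=child, fit=fit, ci=ci, distribution=dist)


def make_chain(edge_specs, node_names=None):
    """CascadeNetwork from [(coefs, direction, sds-or-None), ...]."""
    n = len(edge_specs)
    if node_names is None:
        node_names = [f"n{i}" for i in range(n + 1)]
    edges = tuple(
        make_edge(node_names[i], node_names[i + 1], coefs, direction, sds)
        for i, (coefs, direction, sds) in enumerate(edge_specs)
    )
    return CascadeNetwork(nodes=tuple(node_names), edges=edges)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def steep_chain():
    """Two-edge all-increasing chain with a sharp transition near input 3."""
    return make_chain(
        [
            (SigmoidCoefficients(10.0, 3.0, 8.0), INC, {"K": 0.05, "h": 0.2}),
            (SigmoidCoefficients(20.0, 5.0, 2.0), INC, {"K": 0.1, "h": 0.1}),
        ]
    )
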
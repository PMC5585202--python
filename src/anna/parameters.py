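"""The six whole-network topological parameters.

For an anatomical network with N nodes and K links the package reports:

* ``N`` — number of anatomical structures (bones + muscles),
* ``K`` — number of physical connections,
* ``D`` — density, ``2K / (N(N-1))``, links relative to the maximum
  possible; a proxy for complexity,
* ``C`` — mean local clustering coefficient, the average fraction of a
  node's neighbour pairs that are themselves linked; a proxy for
  integration,
* ``L`` — characteristic path length, the mean shortest-path distance
  over all node pairs (each link 1 unit); a proxy for effective
  proximity of parts,
* ``H`` — heterogeneity, sd(degree)/mean(degree); a proxy for
  anisomerism (disparity among parts).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import AnatomicalNetwork, degree_sequence, is_connected

__all__ = [
    "NetworkParameters",
    "density",
    "clustering_coefficient",
    "characteristic_path_length",
    "heterogeneity",
    "compute_all",
    "round_half_away",
]


@dataclass(frozen=True)
class NetworkParameters:
    """The (N, K, D, C, L, H) tuple for one network."""

    N: int
    K: int
    D: float
    C: float
    L: float
    H: float

    def as_dict(self) -> dict[str, float]:
        return {"N": self.N, "K": self.K, "D": self.D, "C": self.C, "L": self.L, "H": self.H}


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (so 0.0505 -> 0.051 at 3 decimals).

    Report tables use this convention; plain ``round`` is banker's
    rounding and would print 0.050.
    """
    factor = 10.0 ** ndigits
    scaled = x * factor
    # nudge by an ulp-scale epsilon so values printed at the half are not
    # lost to binary representation (0.0505 stores as 0.0504999...)
    eps = np.finfo(float).eps * abs(scaled) * 4
    return np.sign(scaled) * np.floor(abs(scaled) + 0.5 + eps) / factor


def density(net: AnatomicalNetwork) -> float:
    """Fraction of possible links present: ``2K / (N(N-1))``."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return 2.0 * net.n_edges / (n * (n - 1))


def clustering_coefficient(net: AnatomicalNetwork, include_low_degree: bool = True) -> float:
    """Mean local clustering coefficient.

    Local clustering of node *i* is ``2 t_i / (k_i (k_i - 1))`` where
    ``t_i`` counts links among the neighbours of *i*.  Nodes of degree
    0 or 1 have no neighbour pair; by default they enter the average as
    0 (``include_low_degree=True``), keeping C defined on every network.
    With ``include_low_degree=False`` they are dropped from the average
    instead — both conventions appear in the network literature.
    """
    if net.n_nodes == 0:
        raise ValueError("clustering requires at least 1 node")
    g = net.to_networkx()
    local = nx.clustering(g)
    if include_low_degree:
        return float(np.mean([local[v] for v in g.nodes]))
    eligible = [local[v] for v in g.nodes if g.degree[v] >= 2]
    if not eligible:
        return 0.0
    return float(np.mean(eligible))


def characteristic_path_length(net: AnatomicalNetwork) -> float:
    """Mean shortest-path length over all unordered node pairs.

    Defined only on connected networks; a disconnected input raises
    rather than silently averaging infinities.
    """
    connected, sizes = is_connected(net)
    if not connected:
        raise ValueError(
            f"path length is undefined on a disconnected network (component sizes {sizes})"
        )
    if net.n_nodes < 2:
        raise ValueError("path length requires at least 2 nodes")
    return float(nx.average_shortest_path_length(net.to_networkx()))


def heterogeneity(
    net: AnatomicalNetwork, sd: str = "population", statistic: str = "sd"
) -> float:
    """Degree dispersion relative to the mean degree.

    The default is the coefficient of variation sd(k)/mean(k); with
    ``statistic="variance"`` the variance-to-mean ratio var(k)/mean(k)
    (the index of dispersion) is returned instead — both appear as
    definitions of network heterogeneity in the literature.  ``sd``
    selects the estimator: ``"population"`` divides by N (default),
    ``"sample"`` by N-1.  Zero exactly when every node has the same
    degree (regular graphs).
    """
    if net.n_edges < 1:
        raise ValueError("heterogeneity is undefined with no links (mean degree 0)")
    if statistic not in ("sd", "variance"):
        raise ValueError(f"unknown statistic {statistic!r}")
    degrees = np.array([d for _, d in degree_sequence(net)], dtype=float)
    if sd == "population":
        var = degrees.var(ddof=0)
    elif sd == "sample":
        var = degrees.var(ddof=1)
    else:
        raise ValueError(f"unknown sd convention {sd!r}")
    spread = np.sqrt(var) if statistic == "sd" else var
    return float(spread / degrees.mean())


def compute_all(
    net: AnatomicalNetwork,
    include_low_degree: bool = True,
    sd: str = "population",
) -> NetworkParameters:
    """All six parameters for a valid connected network."""
    return NetworkParameters(
        N=net.n_nodes,
        K=net.n_edges,
        D=density(net),
        C=clustering_coefficient(net, include_low_degree=include_low_degree),
        L=characteristic_path_length(net),
        H=heterogeneity(net, sd=sd),
    )
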
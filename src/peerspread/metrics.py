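"""Individual centralities and class-level density / Freeman centralization.

Centralities are computed on the unweighted digraph (edge presence only):
in-degree is the count of distinct nominators, betweenness is directed
shortest-path betweenness normalised by (n-1)(n-2), and closeness uses
incoming distances (how quickly a pupil is reached by classmates) with the
Wasserman-Faust correction for disconnected graphs.  Edge weights are
reserved for the diffusion simulation.

Freeman centralization summarises how star-like a class is for a given
centrality: the sum of differences from the most central pupil, divided by
the same sum in the maximally centralized (star) configuration of equal
size, giving a score in [0, 1].
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CENTRALITY_MEASURES",
    "centralities",
    "density",
    "centralization",
    "class_structure",
    "structure_table",
    "centrality_table",
    "centrality_correlations",
]

CENTRALITY_MEASURES = ("in_degree", "betweenness", "closeness")


def centralities(network: nx.DiGraph) -> pd.DataFrame:
    """Per-node in-degree, betweenness and closeness centrality.

    Returns a frame indexed by node with columns in_degree (nomination
    count), betweenness and closeness (both normalised to [0, 1]).
    """
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("centralities require at least 2 nodes")
    indeg = dict(network.in_degree())
    betw = nx.betweenness_centrality(network, normalized=True, weight=None)
    clos = nx.closeness_centrality(network, wf_improved=True)
    df = pd.DataFrame(
        {
            "in_degree": pd.Series(indeg, dtype=float),
            "betweenness": pd.Series(betw),
            "closeness": pd.Series(clos),
        }
    )
    return df.loc[list(network.nodes)]


def density(network: nx.DiGraph) -> float:
    """Directed density |E| / n(n-1)."""
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return network.number_of_edges() / (n * (n - 1))


def _star_denominator(measure: str, n: int) -> float:
    """Maximum of sum(C_max - C_i) over graphs of size n, attained by a star.

    * in_degree: the inward star (everyone nominates the hub) gives the hub
      n-1 and the leaves 0, so the sum is (n-1)^2.
    * betweenness (normalised): the reciprocal star routes every leaf pair
      through the hub, whose normalised score is 1 while leaves score 0;
      the sum is n-1.
    * closeness (incoming, normalised): in the inward star the hub is reached
      by everyone at distance 1 (score 1) and the leaves are unreachable
      (score 0); the sum is n-1.
    """
    if measure == "in_degree":
        return float((n - 1) ** 2)
    if measure in ("betweenness", "closeness"):
        return float(n - 1)
    raise ValueError(f"unknown centrality measure {measure!r}")


def centralization(table: pd.DataFrame, measure: str, n: int | None = None) -> float:
    """Freeman centralization of one centrality measure for one class."""
    if measure not in CENTRALITY_MEASURES:
        raise ValueError(f"unknown centrality measure {measure!r}")
    values = np.asarray(table[measure], dtype=float)
    if n is None:
        n = len(values)
    if n < 3:
        raise ValueError("centralization requires at least 3 nodes")
    spread = float(np.sum(values.max() - values))
    return spread / _star_denominator(measure, n)


def class_structure(network: nx.DiGraph,
                    table: pd.DataFrame | None = None) -> dict[str, float]:
    """Density plus the three centralizations of one class network."""
    if table is None:
        table = centralities(network)
    out = {"density": density(network)}
    n = network.number_of_nodes()
    for m in CENTRALITY_MEASURES:
        out[f"centralization_{m}"] = centralization(table, m, n)
    return out


def centrality_table(networks: dict[str, nx.DiGraph]) -> pd.DataFrame:
    """Pooled per-pupil centralities over all classes."""
    frames = []
    for class_id, g in networks.items():
        df = centralities(g)
        df.insert(0, "class_id", class_id)
        frames.append(df)
    out = pd.concat(frames)
    out.index.name = "participant_id"
    return out


def structure_table(networks: dict[str, nx.DiGraph]) -> pd.DataFrame:
    """Per-class density and centralizations, indexed by class_id."""
    rows = {cid: class_structure(g) for cid, g in networks.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "class_id"
    return df


def centrality_correlations(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of the pooled centralities.

    Returns (r, p) frames over the three measures.  A constant column yields
    NaN (undefined correlation) rather than an error.
    """
    cols = list(CENTRALITY_MEASURES)
    if len(table) < 3:
        raise ValueError("need at least 3 pooled individuals")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            x, y = table[a].to_numpy(float), table[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p
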
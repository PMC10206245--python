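"""Differential connectivity and rewiring between two group networks.

Connectivity K of a node is its degree standardized by the maximum degree
within that group's own network, so K is in [0, 1]. The differential
connectivity of node i is DK_i = K_SFH,i - K_FH,i (SFH, the subfertile
group, is the reference for gain/loss calls); DK is z-scored across the
union node universe and |z| >= 1.96 (two-sided p <= 0.05) is called
significant.

Rewiring follows the DyNet central-reference idea: per node, the two
groups' weighted neighbor vectors (entry = edge correlation r, 0 when the
edge is absent) are compared to their centroid; the Dn score is the mean
Euclidean distance from the centroid, optionally divided by the union
degree. With two states this reduces to half the Euclidean distance
between the two vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from mircornet.containers import CorrelationEdge

logger = logging.getLogger(__name__)


def to_graph(edges: list[CorrelationEdge]) -> nx.Graph:
    """Weighted undirected graph from an edge list (weight = r)."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.node_a, e.node_b, r=e.r, edge_class=e.edge_class)
    return g


def _as_graph(net) -> nx.Graph:
    return net if isinstance(net, nx.Graph) else to_graph(net)


@dataclass
class ConnectivityRecord:
    node_id: str
    degree_fh: int
    degree_sfh: int
    k_fh: float
    k_sfh: float
    dk: float
    z: float = float("nan")
    significant: bool = False
    direction: str = "none"


def differential_connectivity(
    net_fh, net_sfh, z_crit: float = 1.96
) -> list[ConnectivityRecord]:
    """Per-node DK = K_SFH - K_FH with a z-score significance call.

    The node universe is the union of both node sets; a node absent from
    one network has degree 0 there. z is the sample z-score of dk over the
    whole universe.
    """
    g_fh, g_sfh = _as_graph(net_fh), _as_graph(net_sfh)
    if g_fh.number_of_nodes() == 0 or g_sfh.number_of_nodes() == 0:
        raise ValueError("both networks must be non-empty")
    max_fh = max(dict(g_fh.degree).values())
    max_sfh = max(dict(g_sfh.degree).values())
    if max_fh == 0 or max_sfh == 0:
        raise ValueError("a network with max degree 0 cannot be standardized")

    universe = sorted(set(g_fh.nodes) | set(g_sfh.nodes))
    records = []
    for node in universe:
        d_fh = g_fh.degree(node) if node in g_fh else 0
        d_sfh = g_sfh.degree(node) if node in g_sfh else 0
        k_fh = d_fh / max_fh
        k_sfh = d_sfh / max_sfh
        records.append(
            ConnectivityRecord(node, d_fh, d_sfh, k_fh, k_sfh, k_sfh - k_fh)
        )

    dk = np.array([r.dk for r in records])
    sd = dk.std(ddof=1) if len(dk) > 1 else 0.0
    if sd == 0:
        logger.warning("sd(DK) = 0; all z-scores set to 0")
        z = np.zeros_like(dk)
    else:
        z = (dk - dk.mean()) / sd
    for rec, zi in zip(records, z):
        rec.z = float(zi)
        rec.significant = bool(abs(zi) >= z_crit)
        if rec.significant and rec.dk > 0:
            rec.direction = "gain"
        elif rec.significant and rec.dk < 0:
            rec.direction = "loss"
    return records


@dataclass
class RewiringRecord:
    node_id: str
    dn: float
    dn_degree_corrected: float
    union_degree: int
    isolated: bool = False


def dyn_rewiring(net_fh, net_sfh) -> list[RewiringRecord]:
    """DyNet-style per-node rewiring score between the two group networks."""
    g_fh, g_sfh = _as_graph(net_fh), _as_graph(net_sfh)
    universe = sorted(set(g_fh.nodes) | set(g_sfh.nodes))
    records = []
    for node in universe:
        nbrs_fh = set(g_fh[node]) if node in g_fh else set()
        nbrs_sfh = set(g_sfh[node]) if node in g_sfh else set()
        union = sorted(nbrs_fh | nbrs_sfh)
        if not union:
            records.append(RewiringRecord(node, 0.0, 0.0, 1, isolated=True))
            continue
        v_fh = np.array(
            [g_fh[node][n]["r"] if n in nbrs_fh else 0.0 for n in union]
        )
        v_sfh = np.array(
            [g_sfh[node][n]["r"] if n in nbrs_sfh else 0.0 for n in union]
        )
        centroid = (v_fh + v_sfh) / 2.0
        dn = float(
            (
                np.linalg.norm(v_fh - centroid) + np.linalg.norm(v_sfh - centroid)
            )
            / 2.0
        )
        records.append(RewiringRecord(node, dn, dn / len(union), len(union)))
    return records


def central_reference(net_fh, net_sfh) -> pd.DataFrame:
    """Union network with per-edge provenance in {FH-only, SFH-only, shared}.

    Returns an edge table; node provenance is available via
    :func:`node_provenance`.
    """
    g_fh, g_sfh = _as_graph(net_fh), _as_graph(net_sfh)
    e_fh = {tuple(sorted(e)) for e in g_fh.edges}
    e_sfh = {tuple(sorted(e)) for e in g_sfh.edges}
    rows = []
    for a, b in sorted(e_fh | e_sfh):
        if (a, b) in e_fh and (a, b) in e_sfh:
            prov = "shared"
        elif (a, b) in e_fh:
            prov = "FH-only"
        else:
            prov = "SFH-only"
        r_fh = g_fh[a][b]["r"] if (a, b) in e_fh else np.nan
        r_sfh = g_sfh[a][b]["r"] if (a, b) in e_sfh else np.nan
        rows.append((a, b, prov, r_fh, r_sfh))
    return pd.DataFrame(
        rows, columns=["node_a", "node_b", "provenance", "r_fh", "r_sfh"]
    )


def node_provenance(net_fh, net_sfh) -> pd.Series:
    """Per-node provenance in {FH-only, SFH-only, shared} over the union."""
    g_fh, g_sfh = _as_graph(net_fh), _as_graph(net_sfh)
    out = {}
    for node in sorted(set(g_fh.nodes) | set(g_sfh.nodes)):
        if node in g_fh and node in g_sfh:
            out[node] = "shared"
        elif node in g_fh:
            out[node] = "FH-only"
        else:
            out[node] = "SFH-only"
    return pd.Series(out, name="provenance")


def connectivity_table(records: list[ConnectivityRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def rewiring_table(records: list[RewiringRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
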
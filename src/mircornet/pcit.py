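"""PCIT (partial correlation and information theory) network inference.

For every unordered trio of features (x, y, z) the three first-order
partial correlations are computed, e.g.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

and the trio's local tolerance is the mean absolute ratio of partial to
direct correlation,

    eps = (|r_xy.z / r_xy| + |r_xz.y / r_xz| + |r_yz.x / r_yz|) / 3,

where a ratio with a zero direct correlation contributes 0 (an absent
direct association cannot justify eliminating others). The edge (x, y) is
eliminated if some third node z satisfies |r_xy| < |eps r_xz| and
|r_xy| < |eps r_yz|; edges never eliminated by any trio are the PCIT
"significant" associations. Trios containing a conditioning correlation of
magnitude 1 are skipped (the partial is undefined) and counted.

The O(n^3) trio loop is JIT-compiled with numba; ~750 nodes complete in
seconds on one CPU.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from mircornet.containers import CorrelationEdge, NormalizedMatrix

logger = logging.getLogger(__name__)


def correlation_matrix(
    norm: NormalizedMatrix, samples: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation between features over a sample subset.

    Zero-variance features get r = 0 against every other feature (with a
    warning) and 1 on the diagonal.
    """
    data = norm.cpm if samples is None else norm.cpm[list(samples)]
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "%d zero-variance feature(s); correlations set to 0", int(flat.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=data.index, columns=data.index)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z.

    Undefined (raises) when a conditioning correlation has magnitude 1.
    """
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("conditioning correlation of magnitude 1")
    return (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))


@njit(cache=True)
def _pcit_core(corr):  # pragma: no cover - exercised via pcit()
    n = corr.shape[0]
    eliminated = np.zeros((n, n), dtype=np.bool_)
    skipped = 0
    for x in range(n - 2):
        for y in range(x + 1, n - 1):
            rxy = corr[x, y]
            for z in range(y + 1, n):
                rxz = corr[x, z]
                ryz = corr[y, z]
                if abs(rxy) >= 1.0 or abs(rxz) >= 1.0 or abs(ryz) >= 1.0:
                    skipped += 1
                    continue
                pxy = (rxy - rxz * ryz) / np.sqrt(
                    (1.0 - rxz * rxz) * (1.0 - ryz * ryz)
                )
                pxz = (rxz - rxy * ryz) / np.sqrt(
                    (1.0 - rxy * rxy) * (1.0 - ryz * ryz)
                )
                pyz = (ryz - rxy * rxz) / np.sqrt(
                    (1.0 - rxy * rxy) * (1.0 - rxz * rxz)
                )
                eps = 0.0
                if rxy != 0.0:
                    eps += abs(pxy / rxy)
                if rxz != 0.0:
                    eps += abs(pxz / rxz)
                if ryz != 0.0:
                    eps += abs(pyz / ryz)
                eps /= 3.0
                if abs(rxy) < abs(eps * rxz) and abs(rxy) < abs(eps * ryz):
                    eliminated[x, y] = True
                    eliminated[y, x] = True
                if abs(rxz) < abs(eps * rxy) and abs(rxz) < abs(eps * ryz):
                    eliminated[x, z] = True
                    eliminated[z, x] = True
                if abs(ryz) < abs(eps * rxy) and abs(ryz) < abs(eps * rxz):
                    eliminated[y, z] = True
                    eliminated[z, y] = True
    return eliminated, skipped


def pcit(corr) -> np.ndarray:
    """Boolean significance matrix of the PCIT trio-elimination test.

    Parameters
    ----------
    corr
        Symmetric correlation matrix with unit diagonal (ndarray or
        DataFrame).

    Returns
    -------
    Symmetric boolean ndarray; True = the association survives every trio.
    The diagonal is True by convention.
    """
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(c), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    eliminated, skipped = _pcit_core(c)
    if skipped:
        logger.info("pcit: skipped %d trio(s) with |r| = 1", skipped)
    significant = ~eliminated
    np.fill_diagonal(significant, True)
    return significant


def edge_p_value(r: float, n_samples: int) -> float:
    """Two-sided p of the correlation t-test (reported, not used to filter)."""
    if n_samples <= 2 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 else float("nan")
    t = abs(r) * np.sqrt((n_samples - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n_samples - 2))


def _edge_class(a: str, b: str, mirnas: set) -> str:
    k = (a in mirnas) + (b in mirnas)
    return ("gene-gene", "miRNA-gene", "miRNA-miRNA")[k]


def build_group_network(
    norm: NormalizedMatrix,
    demis,
    targets,
    group: str,
    r_min: float = 0.6,
    samples: list[str] | None = None,
    full_output: bool = False,
    scale: str = "log2",
):
    """Per-group PCIT network over DEMIs + expressed target genes.

    Edges are pairs that are PCIT-significant AND |r| > r_min AND involve
    at least one miRNA. Gene-gene significant pairs are recorded in the
    full dump (``full_output=True`` returns ``(edges, all_edges)``) but are
    excluded from the returned network.

    ``scale`` chooses the expression scale the Pearson correlation is
    computed on: "log2" (log2(CPM + 1), default — variance-stabilized, the
    scale on which multiplicative miRNA repression is linear) or "raw"
    (plain CPM).
    """
    demis = [d for d in demis if d in norm.cpm.index]
    targets = [t for t in targets if t in norm.cpm.index]
    nodes = list(dict.fromkeys(list(demis) + list(targets)))
    if not nodes:
        raise ValueError("empty node set: no DEMI or target present in the matrix")
    if samples is None:
        samples = norm.samples_in(group)
    if scale not in ("log2", "raw"):
        raise ValueError(f"unknown correlation scale: {scale!r}")
    values = norm.cpm.loc[nodes, list(samples)]
    if scale == "log2":
        values = np.log2(values + 1.0)
    sub = NormalizedMatrix(values, norm.groups, norm.feature_kind)
    corr = correlation_matrix(sub)
    sig = pcit(corr)
    mirnas = set(demis)
    n_s = len(samples)

    edges: list[CorrelationEdge] = []
    all_edges: list[CorrelationEdge] = []
    cvals = corr.to_numpy()
    for i in range(len(nodes) - 1):
        for j in range(i + 1, len(nodes)):
            if not sig[i, j]:
                continue
            r = float(cvals[i, j])
            if abs(r) <= r_min:
                continue
            cls = _edge_class(nodes[i], nodes[j], mirnas)
            edge = CorrelationEdge(
                nodes[i], nodes[j], r, group, cls, True, edge_p_value(r, n_s)
            )
            all_edges.append(edge)
            if cls != "gene-gene":
                edges.append(edge)
    logger.info(
        "build_group_network(%s): %d nodes, %d miRNA-involving edges "
        "(|r| > %g), %d total significant edges",
        group,
        len(nodes),
        len(edges),
        r_min,
        len(all_edges),
    )
    if full_output:
        return edges, all_edges
    return edges
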
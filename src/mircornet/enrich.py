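"""Pathway over-representation with Holm correction and kappa clustering.

Over-representation of a query gene set in each annotated term is tested
with the upper-tail hypergeometric probability P(X >= overlap) (population
= annotation universe, successes = term members, draws = query). Family-wise
error is controlled with Holm's step-down ("Bonferroni step-down")
procedure at 0.05. Redundant terms are clustered by Cohen's kappa over
gene-membership agreement across the universe: term pairs with
kappa >= 0.4 are linked and clusters are the connected components, each
represented by its lowest adjusted-p member.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def read_gmt(path: str | Path) -> dict[str, set]:
    """Read GMT (term <tab> description <tab> genes...) into term -> gene set."""
    terms: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        terms[fields[0]] = set(fields[2:])
    return terms


def write_gmt(terms: dict[str, set], path: str | Path, descriptions=None) -> None:
    lines = []
    for term, genes in terms.items():
        desc = (descriptions or {}).get(term, "na")
        lines.append("\t".join([term, desc] + sorted(genes)))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_test(query, term, universe) -> float:
    """Upper-tail hypergeometric p-value P(X >= |query & term|)."""
    query, term, universe = set(query), set(term), set(universe)
    if not query:
        raise ValueError("empty query set")
    if not term <= universe or not query <= universe:
        raise ValueError("term and query must be subsets of the universe")
    overlap = len(query & term)
    return float(
        stats.hypergeom.sf(overlap - 1, len(universe), len(term), len(query))
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="holm")[1]


def cohen_kappa(set_a, set_b, universe) -> float:
    """Cohen's kappa of two gene sets' membership over the universe."""
    a, b, u = set(set_a), set(set_b), set(universe)
    n = len(u)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = n - n11 - n10 - n01
    po = (n11 + n00) / n
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / n**2
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


@dataclass
class EnrichmentRecord:
    term_id: str
    term_size: int
    overlap: int
    universe_size: int
    query_size: int
    p_hyper: float
    p_holm: float = float("nan")
    significant: bool = False
    cluster_id: int = -1
    cluster_representative: bool = False
    overlap_genes: tuple = ()


def kappa_cluster(
    records: list[EnrichmentRecord],
    terms: dict[str, set],
    universe,
    kappa_min: float = 0.4,
) -> list[EnrichmentRecord]:
    """Assign cluster ids by connected components of the kappa >= kappa_min graph.

    The representative of each cluster is its lowest-p_holm member
    (ties broken by term id).
    """
    ids = [r.term_id for r in records]
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(ids) - 1):
        for j in range(i + 1, len(ids)):
            if cohen_kappa(terms[ids[i]], terms[ids[j]], universe) >= kappa_min:
                g.add_edge(ids[i], ids[j])
    by_id = {r.term_id: r for r in records}
    for cid, component in enumerate(
        sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    ):
        rep = min(component, key=lambda t: (by_id[t].p_holm, t))
        for term in component:
            by_id[term].cluster_id = cid
            by_id[term].cluster_representative = term == rep
    return records


def ora(
    query,
    terms: dict[str, set],
    universe,
    alpha: float = 0.05,
    kappa_min: float = 0.4,
) -> list[EnrichmentRecord]:
    """Full over-representation analysis of one query gene set.

    Hypergeometric test per term, Holm adjustment across terms,
    significance at p_holm <= alpha, then kappa clustering.
    """
    query, universe = set(query) & set(universe), set(universe)
    records = []
    for term_id in sorted(terms):
        genes = terms[term_id] & universe
        overlap = query & genes
        records.append(
            EnrichmentRecord(
                term_id=term_id,
                term_size=len(genes),
                overlap=len(overlap),
                universe_size=len(universe),
                query_size=len(query),
                p_hyper=hypergeom_test(query, genes, universe),
                overlap_genes=tuple(sorted(overlap)),
            )
        )
    adj = holm_adjust([r.p_hyper for r in records])
    for rec, p in zip(records, adj):
        rec.p_holm = float(p)
        rec.significant = bool(p <= alpha)
    return kappa_cluster(records, terms, universe, kappa_min)


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    if not df.empty:
        df["overlap_genes"] = df["overlap_genes"].map(",".join)
    return df
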
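"""Thresholded Pearson co-expression network, hub ranking, and the
gene-vs-plasma-triglyceride correlation.

Correlations are computed over the 4 group base-mean TPM values (L0, L4, L8,
N0) by default, matching how the network is defined; a per-sample mode is
available for sensitivity analysis.  An edge joins two genes iff r > 0.9 or
r < -0.9 (strict).  With only 4 points per profile, |r| > 0.9 arises in
roughly 10-15% of independent random pairs, so edge counts on unstructured
data are far from zero — hub calls rest on relative degree, not on the
existence of edges.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd

from .types import SampleDesign, groups_of

log = logging.getLogger(__name__)


def correlation_network(group_means: pd.DataFrame,
                        gene_subset: list[str] | None = None,
                        r_threshold: float = 0.9,
                        direction_reference: str = "N0") -> nx.Graph:
    """Build the |r|-thresholded Pearson co-expression graph.

    Nodes carry ``direction`` ("up"/"down": sign of reference minus L0 mean);
    edges carry ``r`` and ``sign``.  Zero-variance genes are excluded with a
    warning.
    """
    if group_means.shape[1] < 3:
        raise ValueError("need >= 3 distinct conditions for Pearson correlation")
    gm = group_means.loc[list(gene_subset)] if gene_subset is not None else group_means
    x = gm.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        dropped = gm.index[sd == 0].tolist()
        log.warning("correlation_network: excluding %d zero-variance gene(s): %s",
                    len(dropped), dropped[:5])
        gm, x = gm.loc[sd > 0], x[sd > 0]
    genes = gm.index.tolist()
    G = nx.Graph()
    for g, row in zip(genes, x):
        ref = gm.loc[g, direction_reference] if direction_reference in gm.columns else np.nan
        l0 = gm.loc[g, "L0"] if "L0" in gm.columns else np.nan
        G.add_node(g, direction="up" if ref >= l0 else "down")
    r = np.corrcoef(x)
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            rij = r[i, j]
            if rij > r_threshold or rij < -r_threshold:
                G.add_edge(genes[i], genes[j], r=float(rij),
                           sign="+" if rij > 0 else "-")
    log.info("correlation_network: %d nodes, %d edges at |r| > %g",
             G.number_of_nodes(), G.number_of_edges(), r_threshold)
    return G


def detect_hubs(G: nx.Graph, hub_degree_min: int = 15,
                hub_top_frac: float = 0.2) -> pd.DataFrame:
    """Rank nodes by degree and flag highlighted genes and hubs.

    ``highlighted`` <=> degree > ``hub_degree_min`` ("more than 15 highly
    correlated genes"); ``hub`` <=> the node is among the top
    ceil(hub_top_frac * n_nodes) by degree, ties broken lexicographically.
    """
    nodes = sorted(G.nodes)
    if not nodes:
        return pd.DataFrame(columns=["gene_id", "degree", "highlighted", "hub"])
    degree = {n: G.degree(n) for n in nodes}
    ranked = sorted(nodes, key=lambda n: (-degree[n], n))
    n_hubs = math.ceil(hub_top_frac * len(nodes))
    hubs = set(ranked[:n_hubs])
    return pd.DataFrame({
        "gene_id": ranked,
        "degree": [degree[n] for n in ranked],
        "highlighted": [degree[n] > hub_degree_min for n in ranked],
        "hub": [n in hubs for n in ranked],
    })


def trait_correlation(group_means: pd.DataFrame, trait: pd.DataFrame,
                      design: list[SampleDesign],
                      gene_subset: list[str] | None = None) -> pd.DataFrame:
    """Pearson r of each gene's group-mean TPM vs group-mean plasma TG.

    The per-sample trait is averaged within each group to 4 points first.
    A constant trait gives an undefined r, reported as missing with a warning.
    Negative r means expression rises as TG falls.
    """
    grp = groups_of(design)
    tg = trait.set_index("sample_id")["tg_mg_dl"]
    group_tg = pd.Series({g: tg.loc[members].mean() for g, members in grp.items()})
    group_tg = group_tg.loc[[c for c in group_means.columns if c in group_tg.index]]
    gm = group_means.loc[list(gene_subset)] if gene_subset is not None else group_means
    gm = gm[group_tg.index]
    y = group_tg.to_numpy(dtype=float)
    if y.std() == 0:
        log.warning("trait_correlation: constant trait; correlations undefined")
        return pd.DataFrame({"gene_id": gm.index, "r": np.nan,
                             "n_points": len(y)})
    rs = []
    for _, row in gm.iterrows():
        x = row.to_numpy(dtype=float)
        rs.append(np.nan if x.std() == 0 else float(np.corrcoef(x, y)[0, 1]))
    return pd.DataFrame({"gene_id": gm.index, "r": rs, "n_points": len(y)})


def write_network(G: nx.Graph, hub_table: pd.DataFrame, edge_path, node_path) -> None:
    """Canonical TSV export: edge list and node table."""
    edges = sorted((min(a, b), max(a, b), d) for a, b, d in G.edges(data=True))
    pd.DataFrame(
        [(a, b, f"{d['r']:.9f}", d["sign"]) for a, b, d in edges],
        columns=["gene_a", "gene_b", "r", "sign"],
    ).to_csv(edge_path, sep="\t", index=False, lineterminator="\n")
    hub_table.to_csv(node_path, sep="\t", index=False, lineterminator="\n")
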
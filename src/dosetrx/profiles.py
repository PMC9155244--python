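"""Dose-series expression-profile clustering and profile-category calls.

Gene trajectories over the ordered conditions L0 -> L4 -> L8 -> N0 are
z-scaled per gene, anchored so the L0 value is exactly 0, clustered by
complete-linkage agglomeration under a Minkowski distance, and each cluster's
centroid is classified into one of three dose-response categories:

* ``increased_dose_effect`` — expression moves toward the reference (N0)
  level gradually as the tryptophan dose rises;
* ``sensitive_dose`` — most of the gap to N0 closes already at the 0.4% dose;
* ``counter_effect`` — expression moves away from the N0 level with dose.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .types import GROUPS, PROFILE_CATEGORIES

log = logging.getLogger(__name__)


def center_profiles(group_means: pd.DataFrame,
                    gene_subset: list[str] | None = None) -> pd.DataFrame:
    """Per-gene z-scale of the 4 group means, then shift so L0 maps to 0.

    Genes with zero variance across groups are dropped with a warning.  The
    result is invariant to affine transforms a*x + b (a > 0) of a gene's raw
    means.
    """
    if gene_subset is not None:
        if not len(gene_subset):
            raise ValueError("empty gene subset")
        missing = set(gene_subset) - set(group_means.index)
        if missing:
            raise KeyError(f"genes absent from group means: {sorted(missing)[:5]}")
        group_means = group_means.loc[list(gene_subset)]
    cols = [g for g in GROUPS if g in group_means.columns]
    x = group_means[cols].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        dropped = group_means.index[degenerate].tolist()
        log.warning("center_profiles: dropping %d zero-variance gene(s): %s",
                    len(dropped), dropped[:5])
    x, idx = x[~degenerate], group_means.index[~degenerate]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[~degenerate, None]
    z = z - z[:, [cols.index("L0")]]
    return pd.DataFrame(z, index=idx, columns=cols)


def cluster_profiles(profiles: pd.DataFrame, n_clusters: int = 6,
                     minkowski_order: float = 2.0) -> pd.Series:
    """Complete-linkage clustering of centered profiles; returns cluster ids 1..k.

    Genes are processed in lexicographic id order so ties break
    deterministically and the partition is invariant to input order.
    """
    if len(profiles) < n_clusters:
        raise ValueError(f"need >= {n_clusters} genes, got {len(profiles)}")
    prof = profiles.sort_index()
    d = pdist(prof.to_numpy(dtype=float), metric="minkowski", p=minkowski_order)
    Z = linkage(d, method="complete")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    out = pd.Series(labels, index=prof.index, name="cluster")
    n_found = out.nunique()
    if n_found < n_clusters:
        log.warning("cluster_profiles: only %d distinct clusters at k=%d "
                    "(tied merge heights)", n_found, n_clusters)
    return out.loc[profiles.index]


def classify_profiles(clustering: pd.Series, profiles: pd.DataFrame,
                      gamma: float = 0.67) -> dict[int, str]:
    """Assign one dose-response category to each cluster centroid.

    With gap g(x) = |x - c_N0| of the centroid c:

    * counter_effect        iff g(c_L8) >= g(c_L0);
    * else sensitive_dose   iff (g(c_L0) - g(c_L4)) >= gamma * (g(c_L0) - g(c_L8));
    * else increased_dose_effect.

    The rule is total and mutually exclusive; gamma is the fraction of the
    overall gap closure that must already be achieved at the 0.4% dose.
    """
    out: dict[int, str] = {}
    for cid in sorted(clustering.unique()):
        c = profiles.loc[clustering.index[clustering == cid]].mean(axis=0)
        g = {col: abs(c[col] - c["N0"]) for col in ("L0", "L4", "L8")}
        if g["L8"] >= g["L0"]:
            cat = "counter_effect"
        elif (g["L0"] - g["L4"]) >= gamma * (g["L0"] - g["L8"]):
            cat = "sensitive_dose"
        else:
            cat = "increased_dose_effect"
        out[int(cid)] = cat
    assert set(out.values()) <= set(PROFILE_CATEGORIES)
    return out


def profile_table(clustering: pd.Series, categories: dict[int, str]) -> pd.DataFrame:
    """Per-gene table (gene_id, cluster, category)."""
    return pd.DataFrame({
        "gene_id": clustering.index,
        "cluster": clustering.to_numpy(),
        "category": [categories[int(c)] for c in clustering],
    })
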
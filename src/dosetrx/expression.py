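"""TPM normalization, low-expression filtering, differential expression,
and per-group base means.

TPM (transcripts per million) divides each gene's counts by its effective
length in kb, then rescales each sample so the column sums to 1e6.  The
differential-expression contract is the FDR < 0.1 decision rule on a simple,
fully documented test: by default a Welch t-test on log2(CPM + 0.5), with
Benjamini-Hochberg correction across the tested genes.  The heavier
quasi-likelihood machinery of dedicated count-model packages is deliberately
out of scope; the method is pluggable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GROUPS, CountMatrix, SampleDesign, groups_of

log = logging.getLogger(__name__)

LOG_CPM_OFFSET = 0.5


def compute_tpm(cm: CountMatrix) -> pd.DataFrame:
    """Gene x sample TPM matrix; every non-degenerate column sums to 1e6."""
    if cm.lengths is None:
        missing = cm.genes[0] if cm.genes else "<none>"
        raise ValueError(f"effective lengths missing (first gene: {missing}); "
                         "attach gene lengths before TPM")
    rate = cm.counts / (cm.lengths[:, None] / 1e3)  # reads per kb
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        bad = [s for s, z in zip(cm.samples, zero_cols) if z]
        log.warning("compute_tpm: all-zero sample column(s) %s; output left at zero", bad)
    safe = np.where(zero_cols, 1.0, colsum)
    tpm = rate / safe * 1e6
    return pd.DataFrame(tpm, index=pd.Index(cm.genes, name="gene_id"),
                        columns=cm.samples)


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million, no length normalization."""
    lib = cm.counts.sum(axis=0).astype(float)
    lib[lib == 0] = 1.0
    return pd.DataFrame(cm.counts / lib * 1e6,
                        index=pd.Index(cm.genes, name="gene_id"), columns=cm.samples)


def filter_low_expressed(cm: CountMatrix, design: list[SampleDesign],
                         min_count: float = 10.0,
                         min_total: float = 15.0) -> list[str]:
    """Deterministic low-expression filter.

    A gene is kept iff its CPM reaches ``min_count / median_library_size * 1e6``
    in at least k samples, where k is the smallest group size, AND its total
    count across all samples is at least ``min_total``.
    """
    if not design:
        raise ValueError("empty design")
    grp = groups_of(design)
    k = min(len(v) for v in grp.values())
    lib = cm.counts.sum(axis=0).astype(float)
    cpm_cut = min_count / np.median(lib) * 1e6
    cpm_mat = cpm(cm).to_numpy()
    keep = ((cpm_mat >= cpm_cut).sum(axis=1) >= k) & \
           (cm.counts.sum(axis=1) >= min_total)
    kept = [g for g, f in zip(cm.genes, keep) if f]
    log.info("filter_low_expressed: kept %d / %d genes (CPM cut %.3f in >=%d samples, "
             "total >= %g)", len(kept), len(cm.genes), cpm_cut, k, min_total)
    return kept


def differential_expression(cm: CountMatrix, design: list[SampleDesign],
                            group_a: str, group_b: str,
                            method: str = "welch",
                            fdr_deg: float = 0.1) -> pd.DataFrame:
    """Two-group differential expression, B over A.

    Returns a table with columns gene_id, log2fc, p, fdr, is_deg, where
    is_deg <=> fdr < ``fdr_deg``.  Methods: ``welch`` (Welch t on
    log2(CPM+0.5)) or ``binomial`` (exact binomial on pooled
    library-size-normalized counts).
    """
    grp = groups_of(design)
    for g in (group_a, group_b):
        if g not in grp or len(grp[g]) < 2:
            raise ValueError(f"group {g} needs >= 2 replicates")
    idx = {s: i for i, s in enumerate(cm.samples)}
    cols_a = [idx[s] for s in grp[group_a]]
    cols_b = [idx[s] for s in grp[group_b]]

    log_cpm = np.log2(cpm(cm).to_numpy() + LOG_CPM_OFFSET)
    log2fc = log_cpm[:, cols_b].mean(axis=1) - log_cpm[:, cols_a].mean(axis=1)

    if method == "welch":
        res = stats.ttest_ind(log_cpm[:, cols_b], log_cpm[:, cols_a],
                              axis=1, equal_var=False)
        p = np.asarray(res.pvalue)
        # zero variance in both groups with equal means -> no evidence
        p = np.where(np.isnan(p), 1.0, p)
    elif method == "binomial":
        lib = cm.counts.sum(axis=0).astype(float)
        lib_a, lib_b = lib[cols_a].sum(), lib[cols_b].sum()
        p_null = lib_b / (lib_a + lib_b)
        p = np.ones(len(cm.genes))
        tot_a = cm.counts[:, cols_a].sum(axis=1)
        tot_b = cm.counts[:, cols_b].sum(axis=1)
        for i, (xa, xb) in enumerate(zip(tot_a, tot_b)):
            n = int(xa + xb)
            if n > 0:
                p[i] = stats.binomtest(int(xb), n, p_null).pvalue
    else:
        raise ValueError(f"unknown method {method!r}")

    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "gene_id": cm.genes, "log2fc": log2fc, "p": p, "fdr": fdr,
        "is_deg": fdr < fdr_deg,
    })
    log.info("differential_expression %s vs %s (%s): %d / %d genes at FDR < %g",
             group_b, group_a, method, int(out.is_deg.sum()), len(out), fdr_deg)
    return out


def group_base_means(tpm: pd.DataFrame, design: list[SampleDesign]) -> pd.DataFrame:
    """Arithmetic mean TPM per group ("base mean"), columns ordered L0,L4,L8,N0."""
    grp = groups_of(design)
    cols = {}
    for g in GROUPS:
        if g in grp:
            cols[g] = tpm[grp[g]].mean(axis=1)
    out = pd.DataFrame(cols)
    out.index.name = "gene_id"
    return out
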
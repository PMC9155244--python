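"""Percent-spliced-in computation and the differential-splicing filter.

PSI for one event in one sample is inclusion/(inclusion + exclusion) junction
reads.  An event is called differentially spliced against the L0 control iff
its Benjamini-Hochberg FDR is below ``fdr_splice`` AND |dPSI| >= ``dpsi_min``,
where dPSI is the comparison-group mean PSI minus the L0 mean PSI.  The
default test is a two-sided Fisher's exact test on the 2x2 table of pooled
within-group inclusion/exclusion counts; a per-replicate Welch t-test on PSI
is available as an option.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import SampleDesign, SpliceEvent, groups_of

log = logging.getLogger(__name__)


def compute_psi(inclusion: int, exclusion: int) -> float:
    """PSI = inc / (inc + exc); 0/0 is undefined and returned as NaN."""
    if inclusion < 0 or exclusion < 0:
        raise ValueError("negative junction counts")
    total = inclusion + exclusion
    if total == 0:
        log.warning("compute_psi: zero total coverage; PSI undefined")
        return float("nan")
    return inclusion / total


def psi_table(events: list[SpliceEvent]) -> pd.DataFrame:
    """Per-sample PSI for every event (rows: event_id, columns: samples)."""
    if not events:
        return pd.DataFrame()
    samples = list(events[0].inclusion)
    rows = {
        ev.event_id: [ev.inclusion[s] / t if (t := ev.inclusion[s] + ev.exclusion[s])
                      else np.nan for s in samples]
        for ev in events
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


def differential_events(events: list[SpliceEvent], design: list[SampleDesign],
                        comparison_group: str, control: str = "L0",
                        method: str = "fisher", fdr_splice: float = 0.1,
                        dpsi_min: float = 0.05) -> pd.DataFrame:
    """Call differential splicing for one comparison against the control group.

    Returns one row per event with mean PSI per group, dPSI (comparison minus
    control), p, BH FDR across all events of all types jointly, and
    ``is_differential`` per the FDR-and-dPSI conjunction.
    Events with all-missing PSI in either group are excluded with a warning.
    """
    grp = groups_of(design)
    for g in (control, comparison_group):
        if g not in grp or len(grp[g]) < 2:
            raise ValueError(f"group {g} needs >= 2 samples")
    rows, pvals = [], []
    for ev in events:
        inc_c = sum(ev.inclusion[s] for s in grp[control])
        exc_c = sum(ev.exclusion[s] for s in grp[control])
        inc_t = sum(ev.inclusion[s] for s in grp[comparison_group])
        exc_t = sum(ev.exclusion[s] for s in grp[comparison_group])
        psi_c = [ev.inclusion[s] / t for s in grp[control]
                 if (t := ev.inclusion[s] + ev.exclusion[s]) > 0]
        psi_t = [ev.inclusion[s] / t for s in grp[comparison_group]
                 if (t := ev.inclusion[s] + ev.exclusion[s]) > 0]
        if not psi_c or not psi_t:
            log.warning("differential_events: event %s has a group with no defined "
                        "PSI; excluded", ev.event_id)
            continue
        if method == "fisher":
            p = stats.fisher_exact([[inc_t, exc_t], [inc_c, exc_c]],
                                   alternative="two-sided")[1]
        elif method == "ttest":
            if len(psi_c) < 2 or len(psi_t) < 2:
                p = 1.0
            else:
                p = stats.ttest_ind(psi_t, psi_c, equal_var=False).pvalue
                p = 1.0 if np.isnan(p) else float(p)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({
            "event_id": ev.event_id, "event_type": ev.event_type,
            "gene_id": ev.gene_id,
            f"mean_psi_{control}": float(np.mean(psi_c)),
            f"mean_psi_{comparison_group}": float(np.mean(psi_t)),
            "delta_psi": float(np.mean(psi_t) - np.mean(psi_c)),
        })
        pvals.append(float(p))
    if not rows:
        return pd.DataFrame(columns=["event_id", "event_type", "gene_id",
                                     "delta_psi", "p", "fdr", "is_differential"])
    out = pd.DataFrame(rows)
    out["p"] = pvals
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["is_differential"] = (out["fdr"] < fdr_splice) & \
        (out["delta_psi"].abs() >= dpsi_min)
    log.info("differential_events %s vs %s (%s): %d / %d flagged "
             "(FDR < %g and |dPSI| >= %g)", comparison_group, control, method,
             int(out.is_differential.sum()), len(out), fdr_splice, dpsi_min)
    return out


def tally_event_types(results: pd.DataFrame) -> dict[str, int]:
    """Count flagged events per splicing pattern {SE, A5SS, A3SS, MXE, RI}."""
    tally = {t: 0 for t in ("SE", "A5SS", "A3SS", "MXE", "RI")}
    if len(results):
        flagged = results[results["is_differential"]]
        for t, n in flagged["event_type"].value_counts().items():
            tally[t] = int(n)
    return tally
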
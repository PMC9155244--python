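"""RNA-binding-protein motif enrichment around alternatively spliced exons.

A binding region is the alternatively spliced exon body plus up to 250 bp of
flanking sequence on each side, with the 10 intronic bases adjacent to each
splice junction excluded (they carry the core spliceosomal signal, not RBP
signal).  Regions from differential events are compared against regions
sampled from non-differential events; a one-sided Fisher's exact test on
"region contains >= 1 motif hit" counts gives the per-motif enrichment P, and
within each RBP only the smallest-P motif is kept.

Scanning is strand-aware: region sequences are sense-strand (5'->3' in
transcript orientation) and matches never span the gap between non-adjacent
genomic intervals.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import IUPAC_CODES
from .types import Motif, SpliceEvent

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class BindingRegion:
    """Strand-aware interval set scanned for RBP motifs.

    ``intervals`` are the genomic pieces (0-based half-open, sorted);
    ``pieces`` are the contiguous sense-strand sequence chunks in 5'->3'
    transcript order; ``sequence`` is their concatenation.
    """

    event_id: str
    chrom: str
    strand: str
    intervals: list[tuple[int, int]]
    pieces: list[str]

    @property
    def sequence(self) -> str:
        return "".join(self.pieces)


def build_binding_regions(event: SpliceEvent, genome: dict[str, str],
                          flank_bp: int = 250, trim_bp: int = 10) -> list[BindingRegion]:
    """Construct the binding region(s) for one event.

    The event body is the skipped exon (SE), each exclusive exon separately
    (MXE), the alternative long-minus-short segment (A5SS/A3SS), or the
    retained intron (RI).  Flanks extending past a chromosome end are clipped
    with a warning; a body outside the chromosome is an error.
    """
    if event.chrom not in genome:
        raise KeyError(f"chromosome {event.chrom} not in genome")
    chrom_seq = genome[event.chrom]
    bodies = [event.exon] if event.event_type != "MXE" else [event.exon, event.exon2]
    regions = []
    for k, (s, e) in enumerate(bodies):
        if e > len(chrom_seq) or s < 0:
            raise ValueError(f"event {event.event_id}: body [{s},{e}) outside "
                             f"chromosome {event.chrom} (length {len(chrom_seq)})")
        up = (max(0, s - flank_bp), max(0, s - trim_bp))
        down = (min(e + trim_bp, len(chrom_seq)), min(e + flank_bp, len(chrom_seq)))
        if s - flank_bp < 0 or e + flank_bp > len(chrom_seq):
            log.warning("build_binding_regions: event %s flank clipped at "
                        "chromosome end", event.event_id)
        intervals = [iv for iv in (up, (s, e), down) if iv[0] < iv[1]]
        # merge genomically adjacent intervals (trim_bp == 0 makes flanks abut
        # the body); matches may cross merged junctions but never real gaps
        merged: list[list[int]] = []
        for iv in intervals:
            if merged and merged[-1][1] == iv[0]:
                merged[-1][1] = iv[1]
            else:
                merged.append(list(iv))
        runs = [chrom_seq[a:b] for a, b in merged]
        if event.strand == "-":
            pieces = [reverse_complement(r) for r in reversed(runs)]
        else:
            pieces = runs
        suffix = f":{k + 1}" if len(bodies) > 1 else ""
        regions.append(BindingRegion(event.event_id + suffix, event.chrom,
                                     event.strand,
                                     [tuple(iv) for iv in merged], pieces))
    return regions


def _iupac_regex(consensus: str) -> re.Pattern:
    parts = []
    for ch in consensus:
        allowed = IUPAC_CODES[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return re.compile(f"(?=({''.join(parts)}))")


def _pfm_logodds(pfm: np.ndarray) -> np.ndarray:
    probs = pfm / pfm.sum(axis=0, keepdims=True)
    return np.log2(np.maximum(probs, 1e-6) / 0.25)


def scan_motif(region: BindingRegion, motif: Motif) -> list[int]:
    """All hit start offsets of a motif in the region's sense sequence.

    IUPAC mode matches the consensus exactly under IUPAC degeneracy (T and U
    equivalent); PFM mode reports positions whose log-odds score against a
    uniform background reaches ``score_threshold`` x the maximum attainable
    score.  Offsets index into ``region.sequence``; matches are confined to
    single contiguous pieces.
    """
    hits: list[int] = []
    w = motif.width
    if motif.consensus is not None:
        pat = _iupac_regex(motif.consensus)
        offset = 0
        for piece in region.pieces:
            hits.extend(offset + m.start() for m in pat.finditer(piece))
            offset += len(piece)
    else:
        lo = _pfm_logodds(motif.pfm)
        cutoff = motif.score_threshold * lo.max(axis=0).sum()
        base_idx = {b: i for i, b in enumerate("ACGT")}
        offset = 0
        for piece in region.pieces:
            for i in range(len(piece) - w + 1):
                window = piece[i:i + w]
                try:
                    score = sum(lo[base_idx[b], j] for j, b in enumerate(window))
                except KeyError:
                    continue  # ambiguous base in sequence: no score
                if score >= cutoff:
                    hits.append(offset + i)
            offset += len(piece)
    return hits


def sample_background(non_differential_events: list[SpliceEvent], n_background: int,
                      genome: dict[str, str], rng: np.random.Generator,
                      flank_bp: int = 250, trim_bp: int = 10) -> list[BindingRegion]:
    """Uniformly sample events without replacement and build their regions.

    ``n_background`` counts events; MXE events contribute two regions each.
    """
    if n_background > len(non_differential_events):
        raise ValueError(
            f"requested {n_background} background events but only "
            f"{len(non_differential_events)} non-differential events exist; "
            "lower the background multiplier")
    picks = rng.choice(len(non_differential_events), size=n_background, replace=False)
    regions = []
    for i in sorted(picks):
        regions.extend(build_binding_regions(non_differential_events[i], genome,
                                             flank_bp, trim_bp))
    return regions


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment, upper-tail on cell a) Fisher exact P.

    P(X >= a) for X hypergeometric with population a+b+c+d, a+b successes,
    a+c draws.
    """
    return float(hypergeom.sf(a - 1, a + b + c + d, a + b, a + c))


def enrich(differential_regions: list[BindingRegion],
           background_regions: list[BindingRegion],
           motifs: list[Motif], alpha_enrich: float = 0.05) -> pd.DataFrame:
    """Per-motif enrichment of differential vs background binding regions.

    A region "contains" a motif iff it has >= 1 hit.  Columns a,b,c,d are the
    2x2 counts (differential with/without; background with/without), tested
    one-sided for enrichment in differential regions.  Within each RBP only
    the minimum-P motif is flagged ``selected`` (ties broken by motif id);
    ``significant`` <=> p <= alpha_enrich.
    """
    if not differential_regions or not background_regions:
        raise ValueError("both region sets must be non-empty")
    if not motifs:
        raise ValueError("need >= 1 motif")
    keys = [(m.rbp_name, m.motif_id) for m in motifs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (rbp, motif_id) in motif list")
    rows = []
    for m in motifs:
        a = sum(1 for r in differential_regions if scan_motif(r, m))
        b = len(differential_regions) - a
        c = sum(1 for r in background_regions if scan_motif(r, m))
        d = len(background_regions) - c
        p = fisher_one_sided(a, b, c, d)
        odds = (a * d) / (b * c) if b * c else float("inf") if a * d else float("nan")
        rows.append({"rbp_name": m.rbp_name, "motif_id": m.motif_id,
                     "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p_one_sided": p})
    out = pd.DataFrame(rows).sort_values(
        ["rbp_name", "p_one_sided", "motif_id"]).reset_index(drop=True)
    out["selected"] = ~out.duplicated("rbp_name", keep="first")
    out["significant"] = out["p_one_sided"] <= alpha_enrich
    n_sig = int((out.selected & out.significant).sum())
    log.info("enrich: %d motifs, %d RBPs, %d RBPs significant at alpha <= %g",
             len(out), out.rbp_name.nunique(), n_sig, alpha_enrich)
    return out
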
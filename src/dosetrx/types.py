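"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; conversion
from 1-based inclusive (GTF) happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered treatment groups: low-birth-weight piglets on 0 / 0.4 / 0.8 %
#: dietary tryptophan, plus the normal-birth-weight reference.
GROUPS = ("L0", "L4", "L8", "N0")

#: Dietary tryptophan dose (% of diet) per group; N0 carries 0.0 and is the
#: normal-birth-weight reference rather than a dose point.
GROUP_DOSE = {"L0": 0.0, "L4": 0.4, "L8": 0.8, "N0": 0.0}

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")

PROFILE_CATEGORIES = ("increased_dose_effect", "sensitive_dose", "counter_effect")


@dataclass(frozen=True)
class SampleDesign:
    """One sequenced liver sample and its treatment assignment."""

    sample_id: str
    group: str
    dose_pct: float
    replicate_index: int
    is_reference: bool = False

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")


def design_frame(design: list[SampleDesign]) -> pd.DataFrame:
    """Tabular view of a design, one row per sample."""
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in design")
    return pd.DataFrame(
        {
            "sample_id": ids,
            "group": [d.group for d in design],
            "dose_pct": [d.dose_pct for d in design],
            "replicate_index": [d.replicate_index for d in design],
            "is_reference": [d.is_reference for d in design],
        }
    )


def groups_of(design: list[SampleDesign]) -> dict[str, list[str]]:
    """Map group label -> ordered sample ids, in fixed GROUPS order."""
    out: dict[str, list[str]] = {}
    for g in GROUPS:
        members = [d.sample_id for d in design if d.group == g]
        if members:
            out[g] = members
    return out


@dataclass
class GeneModel:
    """Gene structure from a GTF: exon intervals and union-exon length."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for s, e in self.exons:
            if not s < e:
                raise ValueError(f"gene {self.gene_id}: invalid exon [{s},{e})")
        self.exons = sorted(self.exons)

    @property
    def effective_length(self) -> int:
        """Length of the union of exon intervals, in bp."""
        total = 0
        cur_s, cur_e = self.exons[0]
        for s, e in self.exons[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        return total + (cur_e - cur_s)


@dataclass
class CountMatrix:
    """Gene x sample read counts, optionally with per-gene effective lengths."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray  # int, shape (n_genes, n_samples)
    lengths: np.ndarray | None = None  # bp per gene

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match gene/sample axes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths)
            if self.lengths.shape != (len(self.genes),):
                raise ValueError("lengths do not match gene axis")
            if np.any(self.lengths <= 0):
                raise ValueError("non-positive gene length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.genes, name="gene_id"),
                            columns=self.samples)

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.genes)}
        rows = [idx[g] for g in gene_ids]
        lengths = self.lengths[rows] if self.lengths is not None else None
        return CountMatrix(list(gene_ids), list(self.samples),
                           self.counts[rows, :], lengths)


@dataclass
class SpliceEvent:
    """One alternative-splicing event with per-sample junction counts.

    ``exon`` is the event body: the skipped exon (SE), the first exclusive
    exon (MXE, with the second in ``exon2``), the alternative long-minus-short
    segment (A5SS/A3SS) or the retained intron (RI).
    """

    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    exon: tuple[int, int]
    upstream: tuple[int, int]
    downstream: tuple[int, int]
    inclusion: dict[str, int] = field(default_factory=dict)
    exclusion: dict[str, int] = field(default_factory=dict)
    exon2: tuple[int, int] | None = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.event_type == "MXE" and self.exon2 is None:
            raise ValueError(f"event {self.event_id}: MXE requires two target exons")
        for name, iv in (("exon", self.exon), ("upstream", self.upstream),
                         ("downstream", self.downstream), ("exon2", self.exon2)):
            if iv is None:
                continue
            if not iv[0] < iv[1]:
                raise ValueError(f"event {self.event_id}: invalid {name} interval {iv}")
        for cnts in (self.inclusion, self.exclusion):
            for s, v in cnts.items():
                if v < 0:
                    raise ValueError(f"event {self.event_id}: negative count for {s}")


@dataclass
class Motif:
    """An RBP recognition motif, as IUPAC consensus or position-frequency matrix.

    Stored on the DNA (T) alphabet; U in input is mapped to T.  PFM columns are
    base frequencies in A,C,G,T order; ``score_threshold`` is the fraction of
    the maximum attainable log-odds score required for a PFM hit.
    """

    rbp_name: str
    motif_id: str
    consensus: str | None = None
    pfm: np.ndarray | None = None  # shape (4, width), rows A,C,G,T
    score_threshold: float = 0.8

    @property
    def width(self) -> int:
        if self.consensus is not None:
            return len(self.consensus)
        return self.pfm.shape[1]
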
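"""Readers and writers for every external format the pipeline touches.

Canonical table dialect: UTF-8, tab-separated, ``.`` decimal, LF line
endings, fixed column orders.  Every reader/writer pair is a lossless round
trip on this dialect.  GTF input is 1-based inclusive and converted to
0-based half-open on read; splice-event tables carry 0-based half-open
coordinates directly (rMATS ``exonStart_0base`` convention).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (EVENT_TYPES, CountMatrix, GeneModel, Motif, SampleDesign,
                    SpliceEvent, design_frame)

log = logging.getLogger(__name__)

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_EVENT_FIXED_COLS = [
    "event_id", "event_type", "gene_id", "chrom", "strand",
    "exon_start", "exon_end", "exon2_start", "exon2_end",
    "upstream_start", "upstream_end", "downstream_start", "downstream_end",
]


# ---------------------------------------------------------------------------
# count matrix

def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a gene x sample TSV of integer read counts.

    First column holds gene ids; remaining columns are sample ids.  Negative,
    missing, or non-integer cells are format errors naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a gene id column plus >=1 sample column")
    gene_col = df.columns[0]
    genes = df[gene_col].tolist()
    dup = pd.Series(genes)[pd.Series(genes).duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id(s): {', '.join(dup[:5])}")
    samples = list(df.columns[1:])
    counts = np.empty((len(genes), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        for i, raw in enumerate(df[s]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                raise ValueError(f"{path}: missing count at gene {genes[i]}, sample {s}")
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-integer count {raw!r} at gene {genes[i]}, sample {s}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"{path}: negative count {v} at gene {genes[i]}, sample {s}")
            counts[i, j] = v
    log.info("read_count_matrix: %d genes x %d samples from %s",
             len(genes), len(samples), path)
    return CountMatrix(genes, samples, counts)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# sample design

def read_design(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "dose_pct", "replicate_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design table missing columns {sorted(missing)}")
    design = [
        SampleDesign(
            sample_id=str(r.sample_id), group=str(r.group),
            dose_pct=float(r.dose_pct), replicate_index=int(r.replicate_index),
            is_reference=bool(getattr(r, "is_reference", False)),
        )
        for r in df.itertuples()
    ]
    if len({d.sample_id for d in design}) != len(design):
        raise ValueError(f"{path}: duplicate sample ids")
    return design


def write_design(design: list[SampleDesign], path: str | Path) -> None:
    design_frame(design).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GTF gene models

def read_gtf_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse exon features from a GTF into GeneModel records.

    GTF coordinates are 1-based inclusive; internal intervals are 0-based
    half-open, so an exon ``start..end`` becomes ``[start-1, end)`` and keeps
    its length.  Gene effective length is the union-exon length.
    """
    text = Path(path).read_text()
    if not text.strip():
        log.warning("read_gtf_gene_models: %s is empty; no gene models", path)
        return []
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, force=True,
        merge_strategy="create_unique", keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True)
    by_gene: dict[str, GeneModel] = {}
    order: list[str] = []
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        if "gene_id" not in feat.attributes:
            raise ValueError(f"{path}: exon at {feat.seqid}:{feat.start} lacks gene_id")
        gid = feat.attributes["gene_id"][0]
        if feat.end < feat.start:
            raise ValueError(f"{path}: exon with end < start for gene {gid}")
        iv = (feat.start - 1, feat.end)  # 1-based inclusive -> 0-based half-open
        if gid not in by_gene:
            by_gene[gid] = GeneModel(gid, feat.seqid, feat.strand or "+", [iv])
            order.append(gid)
        else:
            gm = by_gene[gid]
            if feat.seqid != gm.chrom:
                raise ValueError(f"{path}: gene {gid} spans chromosomes")
            gm.exons = sorted(gm.exons + [iv])
    log.info("read_gtf_gene_models: %d genes from %s", len(order), path)
    return [by_gene[g] for g in order]


def write_gtf_gene_models(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gm in models:
            for s, e in gm.exons:
                fh.write(
                    f"{gm.chrom}\tdosetrx\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                    f'gene_id "{gm.gene_id}";\n')


# ---------------------------------------------------------------------------
# motifs

def _validate_iupac(s: str, where: str) -> str:
    s = s.upper().replace("U", "T")
    bad = set(s) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"{where}: illegal IUPAC character(s) {sorted(bad)}")
    return s


def read_motifs(path: str | Path, score_threshold: float = 0.8) -> list[Motif]:
    """Read RBP motifs in either supported dialect.

    Dialect A: one motif per line, ``RBP_NAME<TAB>MOTIF_ID<TAB>IUPAC_STRING``.
    Dialect B: PFM blocks — a ``>RBP_NAME MOTIF_ID`` header followed by four
    rows ``A:``/``C:``/``G:``/``T:`` (or ``U:``) of per-position counts.
    All PFM columns must sum to a common total within 1%.
    """
    lines = Path(path).read_text().splitlines()
    nonempty = [ln for ln in lines if ln.strip()]
    if not nonempty:
        log.warning("read_motifs: %s is empty", path)
        return []
    if nonempty[0].startswith(">"):
        return _read_pfm_blocks(nonempty, path, score_threshold)
    motifs = []
    for ln in nonempty:
        parts = ln.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: expected RBP<TAB>MOTIF_ID<TAB>IUPAC, got {ln!r}")
        rbp, mid, iupac = parts
        motifs.append(Motif(rbp, mid, consensus=_validate_iupac(iupac, f"{path}:{mid}"),
                            score_threshold=score_threshold))
    return motifs


def _read_pfm_blocks(lines: list[str], path, score_threshold: float) -> list[Motif]:
    motifs = []
    i = 0
    row_order = "ACGT"
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ValueError(f"{path}: expected '>' header, got {header!r}")
        fields = header[1:].split()
        if len(fields) != 2:
            raise ValueError(f"{path}: PFM header must be '>RBP MOTIF_ID', got {header!r}")
        rbp, mid = fields
        rows = {}
        for k in range(4):
            ln = lines[i + 1 + k]
            m = re.match(r"^\s*([ACGTU])\s*[:|]?\s*(.+)$", ln)
            if not m:
                raise ValueError(f"{path}:{mid}: bad PFM row {ln!r}")
            base = m.group(1).replace("U", "T")
            rows[base] = [float(x) for x in m.group(2).split()]
        if set(rows) != set(row_order):
            raise ValueError(f"{path}:{mid}: PFM needs one row per base A,C,G,T/U")
        pfm = np.array([rows[b] for b in row_order], dtype=float)
        sums = pfm.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError(f"{path}:{mid}: PFM column with non-positive sum")
        ref = np.median(sums)
        if np.any(np.abs(sums - ref) > 0.01 * ref):
            raise ValueError(f"{path}:{mid}: PFM column sums deviate >1% "
                             f"(sums {sums.tolist()})")
        motifs.append(Motif(rbp, mid, pfm=pfm, score_threshold=score_threshold))
        i += 5
    return motifs


def write_motifs(motifs: list[Motif], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            if m.consensus is not None:
                fh.write(f"{m.rbp_name}\t{m.motif_id}\t{m.consensus}\n")
            else:
                fh.write(f">{m.rbp_name} {m.motif_id}\n")
                for base, row in zip("ACGT", m.pfm):
                    fh.write(f"{base}: " + " ".join(f"{v:g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# splice-event tables

def read_event_counts(path: str | Path,
                      design: list[SampleDesign] | None = None) -> list[SpliceEvent]:
    """Read a junction-count table of alternative-splicing events.

    Fixed columns (0-based half-open coordinates) are followed by one
    ``inc:<sample>`` and one ``exc:<sample>`` column per sample.  When a
    design is given, the count columns must cover exactly its sample ids.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_EVENT_FIXED_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    inc_cols = [c for c in df.columns if c.startswith("inc:")]
    exc_cols = [c for c in df.columns if c.startswith("exc:")]
    inc_samples = [c[4:] for c in inc_cols]
    exc_samples = [c[4:] for c in exc_cols]
    if inc_samples != exc_samples:
        raise ValueError(f"{path}: inclusion/exclusion sample columns disagree")
    if design is not None:
        expected = [d.sample_id for d in design]
        if sorted(inc_samples) != sorted(expected):
            raise ValueError(f"{path}: count columns do not match the sample design")
    events = []
    for _, row in df.iterrows():
        etype = row["event_type"]
        if etype not in EVENT_TYPES:
            raise ValueError(f"{path}: unknown event type {etype!r} "
                             f"for event {row['event_id']}")
        exon2 = None
        if etype == "MXE":
            if pd.isna(row["exon2_start"]) or pd.isna(row["exon2_end"]):
                raise ValueError(f"{path}: MXE event {row['event_id']} "
                                 "missing second-exon coordinates")
            exon2 = (int(row["exon2_start"]), int(row["exon2_end"]))
        events.append(SpliceEvent(
            event_id=str(row["event_id"]), event_type=etype,
            gene_id=str(row["gene_id"]), chrom=str(row["chrom"]),
            strand=str(row["strand"]),
            exon=(int(row["exon_start"]), int(row["exon_end"])),
            upstream=(int(row["upstream_start"]), int(row["upstream_end"])),
            downstream=(int(row["downstream_start"]), int(row["downstream_end"])),
            exon2=exon2,
            inclusion={s: int(row[c]) for s, c in zip(inc_samples, inc_cols)},
            exclusion={s: int(row[c]) for s, c in zip(exc_samples, exc_cols)},
        ))
    log.info("read_event_counts: %d events from %s", len(events), path)
    return events


def write_event_counts(events: list[SpliceEvent], path: str | Path) -> None:
    if not events:
        raise ValueError("no events to write")
    samples = list(events[0].inclusion)
    rows = []
    for ev in events:
        row = {
            "event_id": ev.event_id, "event_type": ev.event_type,
            "gene_id": ev.gene_id, "chrom": ev.chrom, "strand": ev.strand,
            "exon_start": ev.exon[0], "exon_end": ev.exon[1],
            "exon2_start": ev.exon2[0] if ev.exon2 else "",
            "exon2_end": ev.exon2[1] if ev.exon2 else "",
            "upstream_start": ev.upstream[0], "upstream_end": ev.upstream[1],
            "downstream_start": ev.downstream[0], "downstream_end": ev.downstream[1],
        }
        for s in samples:
            row[f"inc:{s}"] = ev.inclusion[s]
        for s in samples:
            row[f"exc:{s}"] = ev.exclusion[s]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# trait table and FASTA

def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Per-sample trait table: columns sample_id, tg_mg_dl."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "tg_mg_dl"} <= set(df.columns):
        raise ValueError(f"{path}: trait table needs columns sample_id, tg_mg_dl")
    return df


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6f")


def read_fasta(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
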
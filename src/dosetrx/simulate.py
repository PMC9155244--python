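"""Synthetic-data generators with known planted truth.

Emulates every input of the real study design — 4 treatment groups (L0, L4,
L8, N0) x 6 liver replicates — so each downstream stage can be tested
against ground truth without the original sequencing data:

* negative-binomial read counts (Var = mu + phi*mu^2) with dose-response
  archetypes planted on a background of null genes;
* binomial inclusion/exclusion junction counts for splice events with a
  subset carrying group-specific PSI;
* a uniform-random genome with an RBP motif planted at a high rate inside
  differential-event binding regions and a low rate in background regions;
* a plasma-triglyceride trait linearly coupled to the planted hub gene;
* ortholog sequences mutated to controlled percent identity.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rbp import build_binding_regions, reverse_complement
from .types import (GROUP_DOSE, GROUPS, CountMatrix, GeneModel, Motif,
                    SampleDesign, SpliceEvent)

ARCHETYPES = ("increased_dose_effect", "sensitive_dose", "counter_effect")

#: default planted per-species ortholog identities (percent / 100)
DEFAULT_SPECIES_IDENTITIES = {
    "human": 0.95, "mouse": 0.90, "blue_whale": 0.85, "dog": 0.80,
    "horse": 0.75, "sheep": 0.70, "cow": 0.65,
}

_EVENT_TYPE_WEIGHTS = {"SE": 0.60, "MXE": 0.12, "A5SS": 0.10, "A3SS": 0.10, "RI": 0.08}


@dataclass
class SimulationTruth:
    """Planted ground truth across all generators."""

    deg_genes: dict[str, float] = field(default_factory=dict)  # gene -> fold (N0/L0)
    profile_archetype: dict[str, str] = field(default_factory=dict)
    hub_gene: str | None = None
    diff_events: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_motif: dict | None = None
    species_identities: dict[str, float] = field(default_factory=dict)
    trait_slope: float | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


def make_design(n_reps: int = 6) -> list[SampleDesign]:
    """The study layout: 4 groups x n_reps samples (default 6, i.e. 24 total)."""
    design = []
    for g in GROUPS:
        for r in range(1, n_reps + 1):
            design.append(SampleDesign(f"{g}_{r}", g, GROUP_DOSE[g], r,
                                       is_reference=(g == "N0")))
    return design


# ---------------------------------------------------------------------------
# counts

def _archetype_means(mu_l0: float, mu_n0: float, archetype: str) -> dict[str, float]:
    """Group means for one gene given its L0 and N0 levels and archetype.

    increased_dose_effect moves linearly from L0 toward N0 as the dose rises
    0 -> 0.4 -> 0.8%; sensitive_dose reaches the N0 level already at 0.4%;
    counter_effect moves away from N0 with dose.
    """
    delta = mu_n0 - mu_l0
    if archetype == "increased_dose_effect":
        means = {"L0": mu_l0, "L4": mu_l0 + 0.5 * delta, "L8": mu_n0, "N0": mu_n0}
    elif archetype == "sensitive_dose":
        means = {"L0": mu_l0, "L4": mu_n0, "L8": mu_n0, "N0": mu_n0}
    elif archetype == "counter_effect":
        means = {"L0": mu_l0, "L4": mu_l0 - 0.5 * delta, "L8": mu_l0 - delta,
                 "N0": mu_n0}
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    if min(means.values()) <= 0:
        raise ValueError(f"effect size drives a group mean non-positive: {means}")
    return means


def simulate_counts(design: list[SampleDesign], n_genes: int = 2000,
                    phi: float = 0.1, seed: int = 0,
                    baseline_range: tuple[float, float] = (20.0, 2000.0),
                    n_per_archetype: int = 20,
                    fold_range: tuple[float, float] = (2.5, 4.0),
                    counter_fold_range: tuple[float, float] = (1.4, 1.9),
                    mean_library_size: float = 20e6,
                    library_sigma: float = 0.2,
                    ) -> tuple[CountMatrix, list[GeneModel], SimulationTruth]:
    """Negative-binomial count matrix with planted dose-response genes.

    Returns the counts (with effective lengths attached), synthetic gene
    models, and the planted truth.  ``n_per_archetype = 0`` gives an all-null
    matrix.  Library sizes are log-normal (sigma ``library_sigma``) around
    ``mean_library_size``; per-gene baseline means are log-uniform over
    ``baseline_range`` at the nominal library size.
    """
    if n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    if phi < 0:
        raise ValueError("dispersion phi must be >= 0")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    lengths = np.exp(rng.uniform(np.log(500), np.log(5000), n_genes)).astype(int)
    mu_l0 = np.exp(rng.uniform(np.log(baseline_range[0]), np.log(baseline_range[1]),
                               n_genes))

    truth = SimulationTruth()
    n_planted = 3 * n_per_archetype
    if n_planted > n_genes:
        raise ValueError("more planted genes than genes")
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    group_means = {g: mu_l0.copy() for g in GROUPS}
    for a_i, arch in enumerate(ARCHETYPES):
        for gi in planted_idx[a_i * n_per_archetype:(a_i + 1) * n_per_archetype]:
            lo, hi = counter_fold_range if arch == "counter_effect" else fold_range
            fold = rng.uniform(lo, hi)
            if rng.random() < 0.5:
                fold = 1.0 / fold
            mu_n0 = mu_l0[gi] * fold
            means = _archetype_means(mu_l0[gi], mu_n0, arch)
            for g in GROUPS:
                group_means[g][gi] = means[g]
            truth.deg_genes[genes[gi]] = float(fold)
            truth.profile_archetype[genes[gi]] = arch
    for gi in range(n_genes):
        truth.profile_archetype.setdefault(genes[gi], "null")
    if n_per_archetype > 0:
        # hub: an increased_dose_effect gene; its archetype mates share exactly
        # collinear mean trajectories, giving it > 15 true |r| = 1 partners
        hub_idx = planted_idx[0]
        truth.hub_gene = genes[hub_idx]

    samples = [d.sample_id for d in design]
    lib = np.exp(np.log(mean_library_size)
                 + rng.normal(0.0, library_sigma, len(samples)))
    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, d in enumerate(design):
        # library sizes vary log-normally around the nominal depth; genes see
        # their group mean scaled by the sample's relative depth
        mu = np.maximum(group_means[d.group] * (lib[j] / mean_library_size), 1e-9)
        if phi < 1e-8:
            counts[:, j] = rng.poisson(mu)
        else:
            n_param = 1.0 / phi
            p_param = n_param / (n_param + mu)
            counts[:, j] = rng.negative_binomial(n_param, p_param)

    models = _make_gene_models(genes, lengths, rng)
    cm = CountMatrix(genes, samples, counts, lengths=lengths.astype(float))
    return cm, models, truth


def _make_gene_models(genes: list[str], lengths: np.ndarray,
                      rng: np.random.Generator) -> list[GeneModel]:
    """Tile synthetic multi-exon gene models along one chromosome."""
    models = []
    pos = 1000
    for g, L in zip(genes, lengths):
        n_ex = int(rng.integers(1, 5))
        cuts = np.sort(rng.choice(np.arange(1, L), size=n_ex - 1, replace=False)) \
            if n_ex > 1 else np.array([], dtype=int)
        sizes = np.diff(np.concatenate([[0], cuts, [L]]))
        exons, p = [], pos
        for sz in sizes:
            exons.append((int(p), int(p + sz)))
            p += int(sz) + int(rng.integers(100, 1000))  # intron
        models.append(GeneModel(g, "chrE", "+" if rng.random() < 0.5 else "-", exons))
        pos = p + 2000
    return models


# ---------------------------------------------------------------------------
# splice events

def simulate_events(design: list[SampleDesign], n_events: int = 200,
                    coverage: int = 100, n_diff: int = 30,
                    dpsi: float = 0.3, seed: int = 0,
                    base_psi: float | dict[str, float] | None = None,
                    ) -> tuple[list[SpliceEvent], SimulationTruth]:
    """Binomial junction counts for splice events on a synthetic chromosome.

    Inclusion ~ Binomial(coverage, PSI_group); exclusion = coverage minus
    inclusion.  ``n_diff`` events get group-specific PSI (all non-L0 groups
    shifted by +-``dpsi`` from the L0 value); the rest share one PSI, drawn
    uniformly from [0.2, 0.8] per event unless ``base_psi`` fixes it (a
    scalar, or a per-group map applied to every event).
    """
    if coverage < 10:
        raise ValueError("coverage must be >= 10")
    if not 0 <= dpsi <= 1:
        raise ValueError("dpsi must be in [0, 1]")
    if n_diff > n_events:
        raise ValueError("n_diff exceeds n_events")
    rng = np.random.default_rng(seed)
    width = len(str(n_events))
    types = rng.choice(list(_EVENT_TYPE_WEIGHTS), size=n_events,
                       p=list(_EVENT_TYPE_WEIGHTS.values()))
    diff_idx = set(rng.choice(n_events, size=n_diff, replace=False).tolist())
    truth = SimulationTruth()
    events = []
    spacing, body = 2500, 150
    for i in range(n_events):
        eid = f"E{i + 1:0{width}d}"
        s = 1000 + i * spacing
        e = s + body
        if base_psi is None:
            psi0 = float(rng.uniform(0.2, 0.8))
            group_psi = {g: psi0 for g in GROUPS}
        elif isinstance(base_psi, dict):
            if not all(0 <= v <= 1 for v in base_psi.values()):
                raise ValueError("PSI values must be in [0, 1]")
            psi0 = float(base_psi["L0"])
            group_psi = {g: float(base_psi[g]) for g in GROUPS}
        else:
            if not 0 <= base_psi <= 1:
                raise ValueError("PSI values must be in [0, 1]")
            psi0 = float(base_psi)
            group_psi = {g: psi0 for g in GROUPS}
        if i in diff_idx:
            sign = 1.0 if psi0 + dpsi <= 0.98 else -1.0
            if psi0 - dpsi < 0.02 and sign < 0:
                sign = 1.0
            for g in GROUPS:
                if g != "L0":
                    group_psi[g] = float(np.clip(psi0 + sign * dpsi, 0.0, 1.0))
            truth.diff_events[eid] = dict(group_psi)
        ev = SpliceEvent(
            event_id=eid, event_type=str(types[i]), gene_id=f"SG{i + 1:0{width}d}",
            chrom="chr1", strand="+" if rng.random() < 0.5 else "-",
            exon=(s, e),
            exon2=(s + body + 400, s + 2 * body + 400) if types[i] == "MXE" else None,
            upstream=(s - 500, s - 350), downstream=(e + 350, e + 500),
        )
        for d in design:
            inc = int(rng.binomial(coverage, group_psi[d.group]))
            ev.inclusion[d.sample_id] = inc
            ev.exclusion[d.sample_id] = coverage - inc
        events.append(ev)
    return events, truth


# ---------------------------------------------------------------------------
# genome with planted motifs

def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    from .io import IUPAC_CODES
    return "".join(c if c in "ACGT" else rng.choice(list(IUPAC_CODES[c]))
                   for c in consensus)


def simulate_genome_with_motifs(events: list[SpliceEvent], diff_event_ids: set[str],
                                motif: Motif, p_diff: float = 0.8,
                                p_bg: float = 0.1, seed: int = 0,
                                flank_bp: int = 250, trim_bp: int = 10,
                                ) -> tuple[dict[str, str], SimulationTruth]:
    """I.i.d. uniform genome with the motif planted inside binding regions.

    The motif consensus (one concrete realization per plant) is written at a
    random position inside the binding region of each differential event with
    probability ``p_diff`` and of each other event with probability ``p_bg``.
    Plants land inside region intervals, hence never inside the trimmed
    splice-site-adjacent exclusion zones.  Minus-strand plants are written as
    the reverse complement so the sense-strand scan recovers them.
    """
    if not 0 <= p_diff <= 1 or not 0 <= p_bg <= 1:
        raise ValueError("plant rates must be in [0, 1]")
    if motif.consensus is None:
        raise ValueError("plant motif must have an IUPAC consensus")
    rng = np.random.default_rng(seed)
    chrom_len: dict[str, int] = {}
    for ev in events:
        far = max(ev.exon[1], ev.downstream[1],
                  ev.exon2[1] if ev.exon2 else 0) + flank_bp + 100
        chrom_len[ev.chrom] = max(chrom_len.get(ev.chrom, 0), far)
    genome = {c: "".join(rng.choice(list("ACGT"), size=n))
              for c, n in sorted(chrom_len.items())}
    w = motif.width
    planted: dict[str, int] = {}
    for ev in sorted(events, key=lambda e: e.event_id):
        rate = p_diff if ev.event_id in diff_event_ids else p_bg
        if rng.random() >= rate:
            continue
        region = build_binding_regions(ev, genome, flank_bp, trim_bp)[0]
        slots = [(a, b) for a, b in region.intervals if b - a >= w]
        if not slots:
            continue
        a, b = slots[int(rng.integers(len(slots)))]
        start = int(rng.integers(a, b - w + 1))
        word = _realize_consensus(motif.consensus, rng)
        if ev.strand == "-":
            word = reverse_complement(word)
        seq = genome[ev.chrom]
        genome[ev.chrom] = seq[:start] + word + seq[start + w:]
        planted[ev.event_id] = start
    truth = SimulationTruth(planted_motif={
        "rbp_name": motif.rbp_name, "motif_id": motif.motif_id,
        "p_diff": p_diff, "p_bg": p_bg, "planted_positions": planted,
    })
    return genome, truth


# ---------------------------------------------------------------------------
# trait and orthologs

def simulate_trait(design: list[SampleDesign], group_means: pd.DataFrame,
                   hub_gene: str, slope: float = -0.5, noise_sd: float = 5.0,
                   intercept: float = 150.0, seed: int = 0) -> pd.DataFrame:
    """Per-sample postprandial plasma TG (mg/dL) linearly coupled to the hub.

    TG = intercept + slope * hub-gene group-mean TPM + Gaussian noise.
    """
    if hub_gene not in group_means.index:
        raise KeyError(f"hub gene {hub_gene} absent from group means")
    rng = np.random.default_rng(seed)
    rows = []
    for d in design:
        tg = intercept + slope * float(group_means.loc[hub_gene, d.group]) \
            + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append({"sample_id": d.sample_id, "tg_mg_dl": tg})
    return pd.DataFrame(rows)


def simulate_orthologs(pig_length: int = 1000,
                       species_identities: dict[str, float] | None = None,
                       seed: int = 0, indel_rate: float = 0.0,
                       ) -> tuple[dict[str, str], SimulationTruth]:
    """Pig sequence plus per-species mutated copies at controlled identity.

    Each species copies the pig sequence and substitutes a (1 - identity)
    fraction of positions to a different base.  ``indel_rate`` > 0 adds
    short indels to exercise the alignment path of the conservation module.
    """
    if species_identities is None:
        species_identities = dict(DEFAULT_SPECIES_IDENTITIES)
    for sp, f in species_identities.items():
        if not 0 <= f <= 1:
            raise ValueError(f"identity for {sp} outside [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    pig = "".join(rng.choice(bases, size=pig_length))
    seqs = {"sus_scrofa": pig}
    for sp in sorted(species_identities):
        ident = species_identities[sp]
        n_mut = round((1.0 - ident) * pig_length)
        pos = rng.choice(pig_length, size=n_mut, replace=False)
        arr = np.array(list(pig))
        for p in pos:
            arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
        seq = "".join(arr)
        if indel_rate > 0:
            out, i = [], 0
            while i < len(seq):
                if rng.random() < indel_rate:
                    if rng.random() < 0.5:
                        i += 1  # deletion
                        continue
                    out.append("".join(rng.choice(bases, size=int(rng.integers(1, 4)))))
                out.append(seq[i])
                i += 1
            seq = "".join(out)
        seqs[sp] = seq
    truth = SimulationTruth(species_identities=dict(species_identities))
    return seqs, truth
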
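"""Cross-species conservation scoring of pig genes.

Per-species identity is the percentage of the pig (Sus scrofa) sequence
matched by the ortholog — matches divided by the ungapped pig length.  The
gene conservation score averages this percentage over the seven mammals
(human, mouse, blue whale, dog, horse, sheep, cow).  A per-gene species tree
is built by single-linkage agglomeration on the 1-D distances between
per-species identities and emitted as Newick.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

SPECIES = ("human", "mouse", "blue_whale", "dog", "horse", "sheep", "cow")
PIG_ID = "sus_scrofa"

_GAP_PENALTY = -2
_MATCH = 1
_MISMATCH = -1


def _needleman_wunsch(a: str, b: str) -> tuple[int, int]:
    """Global alignment of a (pig) vs b; returns (score, n_matching_columns).

    Linear gap penalty; traceback tie-break prefers diagonal, then up
    (consume a), then left (consume b), giving a deterministic alignment.
    """
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    H[0, :] = _GAP_PENALTY * np.arange(m + 1)
    H[:, 0] = _GAP_PENALTY * np.arange(n + 1)
    j1 = np.arange(1, m + 1)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], _MATCH, _MISMATCH)
        cand = np.maximum(H[i - 1, :m] + sub, H[i - 1, 1:] + _GAP_PENALTY)
        # left-gap closure in one scan:
        # H[i,j] = max_{k<=j}(base_k - 2*(j-k)) with base_0 = H[i,0], base_k = cand[k]
        g = np.empty(m + 1, dtype=np.int64)
        g[0] = H[i, 0]
        g[1:] = cand - _GAP_PENALTY * j1
        H[i, 1:] = np.maximum.accumulate(g)[1:] + _GAP_PENALTY * j1
    # traceback
    i, j, matches = n, m, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (
                _MATCH if a[i - 1] == b[j - 1] else _MISMATCH):
            if a[i - 1] == b[j - 1]:
                matches += 1
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + _GAP_PENALTY:
            i -= 1
        else:
            j -= 1
    return int(H[n, m]), matches


def pairwise_identity(pig_seq: str, other_seq: str,
                      mode: str = "prealigned") -> float:
    """Percent of the pig sequence matched by the other sequence.

    ``prealigned``: sequences must have equal length; identity is the
    fraction of equal positions.  ``align``: global alignment (match +1,
    mismatch -1, gap -2), then matches / ungapped pig length.  The pig-length
    denominator makes align-mode identity asymmetric by design.
    """
    if not pig_seq or not other_seq:
        raise ValueError("empty sequence")
    pig_seq, other_seq = pig_seq.upper(), other_seq.upper()
    if mode == "prealigned":
        if len(pig_seq) != len(other_seq):
            raise ValueError("prealigned mode requires equal-length sequences")
        matches = sum(x == y for x, y in zip(pig_seq, other_seq))
        denom = sum(c != "-" for c in pig_seq)
    elif mode == "align":
        _, matches = _needleman_wunsch(pig_seq, other_seq)
        denom = len(pig_seq)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return matches / denom * 100.0


def alignment_score(pig_seq: str, other_seq: str) -> int:
    """Global alignment score under the fixed scoring (match +1, mismatch -1, gap -2)."""
    return _needleman_wunsch(pig_seq.upper(), other_seq.upper())[0]


def gene_conservation_score(per_species_identity: dict[str, float]) -> float:
    """Arithmetic mean percent identity over the species present.

    Species missing from the map are excluded with a warning.
    """
    present = {s: v for s, v in per_species_identity.items() if not np.isnan(v)}
    missing = [s for s in SPECIES if s not in present]
    if missing:
        log.warning("gene_conservation_score: missing species %s; averaging over "
                    "the remaining %d", missing, len(present))
    if not present:
        raise ValueError("no species identities available")
    return float(np.mean(list(present.values())))


def conservation_from_fastas(ortholog_seqs: dict[str, str],
                             mode: str = "prealigned") -> dict[str, float]:
    """Per-species identity of every non-pig record against the pig record."""
    if PIG_ID not in ortholog_seqs:
        raise ValueError(f"pig record {PIG_ID!r} required in ortholog FASTA")
    pig = ortholog_seqs[PIG_ID]
    return {sp: pairwise_identity(pig, seq, mode=mode)
            for sp, seq in ortholog_seqs.items() if sp != PIG_ID}


def build_species_tree(per_species_identity: dict[str, float]) -> str:
    """Single-linkage tree over |identity_i - identity_j| distances, as Newick.

    The tree is ultrametric: a cluster merged at height h places its leaves
    at depth h/2, so two species at distance d appear as ``(A:d/2,B:d/2);``.
    Labels are processed in sorted order for deterministic tie-breaking.
    """
    species = sorted(per_species_identity)
    if len(species) < 2:
        raise ValueError("need >= 2 species for a tree")
    vals = np.array([[per_species_identity[s]] for s in species], dtype=float)
    Z = linkage(pdist(vals), method="single")
    root = to_tree(Z)

    def newick(node, parent_height):
        bl = (parent_height - node.dist) / 2.0
        if node.is_leaf():
            return f"{species[node.id]}:{bl:.6g}"
        inner = f"({newick(node.left, node.dist)},{newick(node.right, node.dist)})"
        return f"{inner}:{bl:.6g}"

    left = newick(root.left, root.dist)
    right = newick(root.right, root.dist)
    return f"({left},{right});"
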
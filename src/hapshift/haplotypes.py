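"""Haplotype collapsing, diversity statistics, minimum spanning networks and
tissue-vs-eDNA concordance on a shared alignment window.

Distances throughout are Hamming distances on the trimmed window: the
marker is a protein-coding mitochondrial fragment where indels are not
expected, and columns containing gaps are removed (and logged) before any
distance computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._seq import hamming_matrix, is_unambiguous, sliding_best_match

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeSet:
    """Distinct equal-length haplotypes with per-group counts or weights.

    ``counts`` is indexed by haplotype id with one column per group label
    (e.g. ``(site, year, source)`` tuples flattened to strings); tissue
    groups hold individual counts, eDNA groups hold read-proportion
    weights — the two are never pooled in one statistic.
    """

    species: str
    haplotypes: list[tuple[str, str]]  # (haplotype_id, sequence)
    counts: pd.DataFrame
    discarded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.haplotypes}
        if len(lengths) > 1:
            raise ValueError("haplotype sequences must share one length")
        seqs = [s for _, s in self.haplotypes]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate haplotype sequences")
        if not self.counts.empty and (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def alignment_length(self) -> int:
        return len(self.haplotypes[0][1]) if self.haplotypes else 0

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.haplotypes]


@dataclass
class DiversityStats:
    pi: float
    hd: float
    n: int
    L: int


# ---------------------------------------------------------------------------
# alignment-window extraction
# ---------------------------------------------------------------------------

def extract_overlap(
    tissue_alignment: list[tuple[str, str]],
    edna_sequences: list[tuple[str, str]],
    min_overlap: int = 50,
    min_placement_identity: float = 0.75,
) -> tuple[dict[str, str], tuple[int, int]]:
    """Trim all sequences to the maximal window covered by every sequence.

    Tissue sequences come from one alignment (equal length, ``-`` padding
    allowed at the ends); each eDNA sequence is located on the alignment by
    its best ungapped placement against the first tissue sequence's
    non-gap consensus.  Returns the trimmed sequences keyed by id and the
    window as 0-based half-open coordinates in tissue-alignment space.
    """
    if not tissue_alignment or not edna_sequences:
        raise ValueError("need at least one tissue and one eDNA sequence")
    aln_len = {len(s) for _, s in tissue_alignment}
    if len(aln_len) != 1:
        raise ValueError("tissue alignment rows have unequal lengths")
    aln_len = aln_len.pop()

    spans: dict[str, tuple[int, int]] = {}
    for name, seq in tissue_alignment:
        stripped = seq.strip("-")
        if "-" in stripped:
            raise ValueError(f"internal gaps not supported: {name}")
        start = seq.index(stripped[0]) if stripped else 0
        start = len(seq) - len(seq.lstrip("-"))
        end = len(seq.rstrip("-"))
        spans[name] = (start, end)

    consensus = tissue_alignment[0][1].replace("-", "")
    cons_offset = spans[tissue_alignment[0][0]][0]
    for name, seq in edna_sequences:
        if len(seq) > len(consensus):
            raise ValueError(f"eDNA sequence {name} longer than the tissue alignment")
        matches, overlap, off = sliding_best_match(seq, consensus)
        if matches / overlap < min_placement_identity:
            raise ValueError(
                f"sequence {name} cannot be placed on the tissue alignment "
                f"(best placement identity {matches / overlap:.2f}): no usable overlap"
            )
        spans[name] = (cons_offset + off, cons_offset + off + len(seq))

    start = max(s for s, _ in spans.values())
    end = min(e for _, e in spans.values())
    if end - start < min_overlap:
        widest = sorted(spans, key=lambda n: spans[n][1] - spans[n][0])[:2]
        raise ValueError(
            f"no common window of >= {min_overlap} bp "
            f"(best window {max(0, end - start)} bp; offending sequences: {widest})"
        )

    trimmed: dict[str, str] = {}
    for name, seq in tissue_alignment:
        trimmed[name] = seq[start:end]
    for name, seq in edna_sequences:
        s0 = spans[name][0]
        trimmed[name] = seq[start - s0 : end - s0]
    return trimmed, (start, end)


# ---------------------------------------------------------------------------
# haplotype collapsing
# ---------------------------------------------------------------------------

def collapse_haplotypes(
    records: list[tuple[str, str]],
    species: str = "",
    groups: dict[str, str] | None = None,
    weights: dict[str, float] | None = None,
    prefix: str = "H",
) -> HaplotypeSet:
    """Collapse equal-length sequences by exact match.

    Sequences containing ambiguity codes (anything outside A/C/G/T) are
    discarded and logged.  Haplotype ids are assigned in descending total
    frequency (ties broken lexicographically by sequence).  ``groups``
    optionally maps record id -> group label for the count matrix;
    ``weights`` maps record id -> weight (default 1 per record).
    """
    lengths = {len(s) for _, s in records}
    if len(lengths) > 1:
        raise ValueError("collapse requires equal-length input")
    groups = groups or {name: "all" for name, _ in records}
    weights = weights or {}

    discarded = [name for name, seq in records if not is_unambiguous(seq)]
    for name in discarded:
        logger.info("discarding sequence with ambiguous bases: %s", name)
    kept = [(n, s.upper()) for n, s in records if is_unambiguous(s)]

    totals: dict[str, float] = {}
    per_group: dict[str, dict[str, float]] = {}
    for name, seq in kept:
        w = weights.get(name, 1.0)
        totals[seq] = totals.get(seq, 0.0) + w
        g = groups.get(name, "all")
        per_group.setdefault(seq, {})
        per_group[seq][g] = per_group[seq].get(g, 0.0) + w

    ordered = sorted(totals, key=lambda s: (-totals[s], s))
    haplotypes = [(f"{prefix}{i + 1}", s) for i, s in enumerate(ordered)]
    group_labels = sorted({g for gmap in per_group.values() for g in gmap})
    counts = pd.DataFrame(
        0.0, index=[h for h, _ in haplotypes], columns=group_labels
    )
    for hid, seq in haplotypes:
        for g, w in per_group[seq].items():
            counts.loc[hid, g] = w
    return HaplotypeSet(
        species=species, haplotypes=haplotypes, counts=counts, discarded=discarded
    )


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

def nucleotide_diversity(seqs: list[str]) -> float:
    """pi: mean pairwise Hamming distance over C(n,2) pairs, per site."""
    n = len(seqs)
    if n < 2:
        raise ValueError("nucleotide diversity requires n >= 2 sequences")
    L = len(seqs[0])
    dist = hamming_matrix(seqs)
    total = dist[np.triu_indices(n, k=1)].sum()
    n_pairs = n * (n - 1) / 2
    return float(total / n_pairs / L)


def haplotype_diversity(counts: list[int] | np.ndarray) -> float:
    """Unbiased haplotype diversity Hd = n(1 - sum p_i^2)/(n - 1)."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = counts / n
    return float(n * (1.0 - np.sum(p ** 2)) / (n - 1.0))


def diversity_stats(seqs: list[str]) -> DiversityStats:
    from collections import Counter

    counts = list(Counter(seqs).values())
    return DiversityStats(
        pi=nucleotide_diversity(seqs),
        hd=haplotype_diversity(counts),
        n=len(seqs),
        L=len(seqs[0]),
    )


# ---------------------------------------------------------------------------
# minimum spanning network
# ---------------------------------------------------------------------------

def minimum_spanning_network(
    haps: HaplotypeSet | list[tuple[str, str]], epsilon: int = 0
) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network over Hamming distances.

    Edge weights (unique distances) are processed in increasing order; at
    weight ``w`` every edge of weight <= ``w + epsilon`` joining two
    components — components as they stood before any weight-``w`` edge was
    added — is included.  At epsilon 0 this equals the union of all
    minimum spanning trees.
    """
    pairs = haps.haplotypes if isinstance(haps, HaplotypeSet) else list(haps)
    ids = [h for h, _ in pairs]
    seqs = [s for _, s in pairs]
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    if n <= 1:
        return g
    dist = hamming_matrix(seqs)
    edges = [
        (int(dist[i, j]), ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)
    ]
    weights = sorted({w for w, _, _ in edges})

    comp = {h: h for h in ids}  # union-find

    def find(x: str) -> str:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for w in weights:
        snapshot = {h: find(h) for h in ids}
        added = []
        for ew, u, v in edges:
            if not (w <= ew <= w + epsilon):
                continue
            if snapshot[u] != snapshot[v]:
                g.add_edge(u, v, weight=ew)
                added.append((u, v))
        for u, v in added:
            ru, rv = find(u), find(v)
            if ru != rv:
                comp[ru] = rv
        if epsilon == 0 and all(find(h) == find(ids[0]) for h in ids):
            break
    return g


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance(
    tissue: HaplotypeSet, edna: HaplotypeSet
) -> tuple[int, int, int, pd.DataFrame]:
    """Exact-sequence set comparison on the shared window.

    Returns (shared, tissue_only, edna_only, per-haplotype table).
    """
    if tissue.haplotypes and edna.haplotypes:
        if tissue.alignment_length != edna.alignment_length:
            raise ValueError(
                "haplotype sets are on different windows: "
                f"{tissue.alignment_length} vs {edna.alignment_length} bp"
            )
    t_seqs = {s: h for h, s in tissue.haplotypes}
    e_seqs = {s: h for h, s in edna.haplotypes}
    shared = set(t_seqs) & set(e_seqs)
    t_only = set(t_seqs) - shared
    e_only = set(e_seqs) - shared
    rows = []
    for seq in sorted(set(t_seqs) | set(e_seqs)):
        rows.append(
            {
                "tissue_id": t_seqs.get(seq, ""),
                "edna_id": e_seqs.get(seq, ""),
                "status": "shared"
                if seq in shared
                else ("tissue_only" if seq in t_only else "edna_only"),
                "sequence": seq,
            }
        )
    return len(shared), len(t_only), len(e_only), pd.DataFrame(rows)
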
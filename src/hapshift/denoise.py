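"""Read filtering, dereplication and abundance-skew (UNOISE-style) denoising.

The denoiser follows the published UNOISE formulation: uniques are visited
in descending abundance and a candidate with abundance ``a`` at distance
``d`` from an existing centroid of abundance ``c`` is absorbed when
``a / c <= beta(d) = 1 / 2**(alpha * d + 1)``; otherwise it seeds a new
centroid.  The skew exponent alpha defaults to 5, a setting suited to
resolving metazoan intraspecific variation on ~313 bp COI amplicons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode_many, endfree_mismatches, sliding_best_match
from .containers import ASVTable


@dataclass
class DenoiseParams:
    alpha: float = 5.0
    min_length: int = 303
    max_length: int = 323
    max_expected_error: float = 1.0
    discard_singletons: bool = True
    min_abundance: int = 8  # unoise3's default minsize for candidate uniques
    map_identity: float = 0.995

    def __post_init__(self) -> None:
        if not 0 < self.map_identity <= 1:
            raise ValueError("map_identity must be in (0, 1]")
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")


@dataclass(frozen=True)
class UniqueSequence:
    sequence: str
    total_abundance: int


def expected_error(quality: str) -> float:
    """Sum over bases of the Phred error probability 10^(-Q/10)."""
    q = np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(float) - 33.0
    return float(np.sum(10.0 ** (-q / 10.0)))


def filter_reads(
    reads: list[tuple[str, str, str]], params: DenoiseParams | None = None
) -> list[tuple[str, str, str]]:
    """Length-window and expected-error filtering of merged reads.

    Retains reads with min_length <= len <= max_length and EE <= threshold.
    """
    params = params or DenoiseParams()
    out = []
    for rec in reads:
        try:
            read_id, seq, qual = rec
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed FASTQ record: {rec!r}") from exc
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record (length mismatch): {read_id}")
        if not params.min_length <= len(seq) <= params.max_length:
            continue
        if expected_error(qual) > params.max_expected_error:
            continue
        out.append((read_id, seq, qual))
    return out


def dereplicate(
    reads: list[tuple[str, str, str]] | list[str], discard_singletons: bool = True
) -> list[UniqueSequence]:
    """Exact dereplication, sorted by abundance descending (ties lexicographic)."""
    seqs = [r if isinstance(r, str) else r[1] for r in reads]
    counts = Counter(seqs)
    uniques = [
        UniqueSequence(s, n)
        for s, n in counts.items()
        if not (discard_singletons and n == 1)
    ]
    uniques.sort(key=lambda u: (-u.total_abundance, u.sequence))
    return uniques


def beta(d: int, alpha: float) -> float:
    """UNOISE abundance-skew threshold for distance ``d``."""
    # 2.0**-x underflows to 0.0 for large distances instead of overflowing
    return 2.0 ** -(alpha * d + 1.0)


def unoise_denoise(
    uniques: list[UniqueSequence], alpha: float = 5.0, min_abundance: int = 8
) -> list[UniqueSequence]:
    """Greedy abundance-ordered denoising pass; returns centroids in input order.

    The candidate is compared against its nearest centroid (smallest
    distance; ties broken toward the most abundant, then lexicographically
    smallest, centroid).  Equal-length comparisons are Hamming; unequal
    lengths fall back to end-gap-free mismatch counting.

    Candidates below ``min_abundance`` (the denoiser's own minimum cluster
    size, 8 by default as in the reference implementation) can never seed a
    new centroid; their reads are recovered, when close enough, by the
    subsequent mapping step.  The most abundant unique is always a
    centroid.
    """
    if any(
        uniques[i].total_abundance < uniques[i + 1].total_abundance
        for i in range(len(uniques) - 1)
    ):
        raise ValueError("uniques must be sorted by abundance descending")
    if not uniques:
        return []

    centroids: list[UniqueSequence] = [uniques[0]]
    for cand in uniques[1:]:
        if cand.total_abundance < min_abundance:
            continue
        d_best, c_best = None, None
        cand_arr = None
        for cen in centroids:
            if len(cen.sequence) == len(cand.sequence):
                if cand_arr is None:
                    cand_arr = np.frombuffer(cand.sequence.encode(), dtype=np.uint8)
                cen_arr = np.frombuffer(cen.sequence.encode(), dtype=np.uint8)
                d = int(np.count_nonzero(cand_arr != cen_arr))
            else:
                d = endfree_mismatches(cand.sequence, cen.sequence)
            key = (d, -cen.total_abundance, cen.sequence)
            if d_best is None or key < d_best:
                d_best, c_best = key, cen
        d = d_best[0]
        if cand.total_abundance / c_best.total_abundance <= beta(d, alpha):
            continue  # absorbed by nearest centroid
        centroids.append(cand)
    return centroids


def map_reads_to_asvs(
    reads_by_sample: dict[str, list[tuple[str, str, str]]],
    centroids: list[UniqueSequence],
    samples: pd.DataFrame,
    map_identity: float = 0.995,
) -> ASVTable:
    """Map filtered reads back to centroids to build the ASV x sample table.

    A read is assigned to the centroid with the highest identity provided
    identity >= ``map_identity`` (ties go to the most abundant centroid);
    reads below the threshold are dropped and counted in the table log.
    """
    if not centroids:
        raise ValueError("no centroids to map against")
    asv_ids = [f"ASV_{i + 1}" for i in range(len(centroids))]
    sequences = {a: c.sequence for a, c in zip(asv_ids, centroids)}
    abundances = np.array([c.total_abundance for c in centroids])

    # vectorised assignment cache keyed by read sequence
    by_len: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    lengths = np.array([len(c.sequence) for c in centroids])
    for L in np.unique(lengths):
        idx = np.nonzero(lengths == L)[0]
        mat = encode_many([centroids[i].sequence for i in idx])
        by_len[int(L)] = (idx, mat)

    cache: dict[str, int] = {}

    def assign(seq: str) -> int:
        """Return centroid index or -1 (dropped)."""
        if seq in cache:
            return cache[seq]
        best_idx, best_identity = -1, -1.0
        L = len(seq)
        if L in by_len:
            idx, mat = by_len[L]
            q = np.frombuffer(seq.encode(), dtype=np.uint8)
            matches = (mat == q).sum(axis=1)
            identities = matches / L
            order = np.lexsort((-abundances[idx], -identities))
            best = order[0]
            best_identity = float(identities[best])
            best_idx = int(idx[best])
        # unequal-length centroids: end-gap-free fallback
        for i, c in enumerate(centroids):
            if len(c.sequence) == L:
                continue
            m, overlap, _ = sliding_best_match(seq, c.sequence)
            ident = m / max(L, len(c.sequence))
            if ident > best_identity or (
                ident == best_identity
                and best_idx >= 0
                and c.total_abundance > centroids[best_idx].total_abundance
            ):
                best_identity, best_idx = ident, i
        result = best_idx if best_identity >= map_identity else -1
        cache[seq] = result
        return result

    counts = np.zeros((len(centroids), len(reads_by_sample)), dtype=np.int64)
    dropped: dict[str, int] = {}
    sample_ids = list(reads_by_sample)
    for j, sid in enumerate(sample_ids):
        n_drop = 0
        derep = Counter(r[1] for r in reads_by_sample[sid])
        for seq, n in derep.items():
            i = assign(seq)
            if i < 0:
                n_drop += n
            else:
                counts[i, j] += n
        dropped[sid] = n_drop

    table = pd.DataFrame(counts, index=asv_ids, columns=sample_ids)
    return ASVTable(
        counts=table,
        sequences=sequences,
        samples=samples,
        log={"dropped_reads": dropped},
    ).drop_empty_asvs()


def denoise_pipeline(
    reads_by_sample: dict[str, list[tuple[str, str, str]]],
    samples: pd.DataFrame,
    params: DenoiseParams | None = None,
) -> ASVTable:
    """filter -> pool -> dereplicate -> denoise -> map, per the study workflow."""
    params = params or DenoiseParams()
    filtered = {sid: filter_reads(reads, params) for sid, reads in reads_by_sample.items()}
    pooled = [r for reads in filtered.values() for r in reads]
    uniques = dereplicate(pooled, discard_singletons=params.discard_singletons)
    centroids = unoise_denoise(
        uniques, alpha=params.alpha, min_abundance=params.min_abundance
    )
    return map_reads_to_asvs(filtered, centroids, samples, params.map_identity)
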
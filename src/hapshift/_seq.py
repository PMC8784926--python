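"""Low-level nucleotide sequence helpers shared across the pipeline.

Sequences are plain upper-case strings. Where speed matters they are
encoded as uint8 arrays of ASCII codes so Hamming distances vectorise.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
IUPAC = set("ACGTRYSWKMBDHVN")

_GAP = ord("-")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def encode_many(seqs: list[str]) -> np.ndarray:
    """Stack equal-length sequences into an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return int(np.count_nonzero(encode(a) != encode(b)))


def hamming_matrix(seqs: list[str]) -> np.ndarray:
    """All-pairs Hamming distance matrix for equal-length sequences."""
    mat = encode_many(seqs)
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(np.int64)


def sliding_best_match(query: str, target: str) -> tuple[int, int, int]:
    """Best ungapped (end-gap-free) placement of the shorter sequence on the longer.

    Slides the shorter of the two along the longer and counts matching
    columns at each offset.  Returns ``(matches, overlap_length, offset)``
    for the offset with the most matches, where ``offset`` is the 0-based
    start of the shorter sequence within the longer one.  Ties are broken
    by the smallest offset.  Indels are not modelled: the data the
    pipeline is designed around is substitution-only at this scale.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    short, long_ = (query, target) if len(query) <= len(target) else (target, query)
    s = encode(short)
    t = encode(long_)
    n, m = len(s), len(t)
    best_matches, best_off = -1, 0
    for off in range(m - n + 1):
        matches = int(np.count_nonzero(s == t[off : off + n]))
        if matches > best_matches:
            best_matches, best_off = matches, off
            if matches == n:
                break
    return best_matches, n, best_off


def identity_coverage(query: str, reference: str) -> tuple[float, float]:
    """Percent identity and query coverage of an end-gap-free alignment.

    identity = matching columns / aligned columns x 100;
    coverage = aligned query positions / query length x 100.
    A query that is a strict substring of the reference therefore scores
    (100, 100).
    """
    for s in (query, reference):
        bad = set(s.upper()) - IUPAC
        if bad:
            raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    matches, overlap, _ = sliding_best_match(query.upper(), reference.upper())
    identity = 100.0 * matches / overlap
    coverage = 100.0 * min(overlap, len(query)) / len(query)
    return identity, coverage


def endfree_mismatches(a: str, b: str) -> int:
    """Mismatch count of the best end-gap-free placement (equal lengths: Hamming)."""
    if len(a) == len(b):
        return hamming(a, b)
    matches, overlap, _ = sliding_best_match(a, b)
    return overlap - matches


def is_unambiguous(seq: str) -> bool:
    """True when the sequence contains only A/C/G/T."""
    return not (set(seq.upper()) - set(BASES))
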
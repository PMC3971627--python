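"""IUPAC-aware Hamming scanning of short motifs (primers, barcodes, adapters).

Primer and barcode matching in amplicon QC counts *mismatches* against a
possibly degenerate motif: a read base matches a motif position iff it is a
member of the IUPAC expansion of the motif character.  An ambiguous read
base ('N') matches only a motif 'N'.  Matching is anchored (no indels),
which is what "mismatches to a primer/barcode" means in the mothur/QIIME
tradition and is exactly testable against a brute-force oracle.

All scans are vectorised with a 128x128 match lookup table so that whole
reads can be screened for internal primer copies at negligible cost.
"""

from __future__ import annotations

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_iupac(motif: str) -> str:
    """Reverse complement preserving IUPAC degeneracy codes."""
    return motif.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def _build_match_table() -> np.ndarray:
    table = np.zeros((128, 128), dtype=bool)
    for motif_char, expansion in IUPAC.items():
        for read_char in expansion:
            table[ord(read_char), ord(motif_char)] = True
    return table


_MATCH = _build_match_table()


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def mismatch_profile(seq: str, motif: str) -> np.ndarray:
    """Anchored mismatch count of `motif` at every offset of `seq`.

    Returns an integer array of length ``len(seq) - len(motif) + 1``
    (empty when the motif is longer than the sequence).
    """
    m = len(motif)
    if m == 0:
        raise ValueError("empty motif")
    if len(seq) < m:
        return np.empty(0, dtype=np.int32)
    windows = np.lib.stride_tricks.sliding_window_view(_codes(seq), m)
    matches = _MATCH[windows, _codes(motif)]
    return (m - matches.sum(axis=1)).astype(np.int32)


def hamming_distance(seq: str, motif: str) -> int:
    """Mismatches between equal-length `seq` and IUPAC `motif`."""
    if len(seq) != len(motif):
        raise ValueError("hamming_distance requires equal lengths")
    return int(len(motif) - _MATCH[_codes(seq), _codes(motif)].sum())


def find_occurrences(seq: str, motif: str, max_mm: int):
    """All anchored occurrences of `motif` in `seq` with <= max_mm mismatches.

    Returns a list of (start, mismatches) sorted by start.
    """
    prof = mismatch_profile(seq, motif)
    starts = np.nonzero(prof <= max_mm)[0]
    return [(int(s), int(prof[s])) for s in starts]


def best_anchored(seq: str, motif: str, span: int):
    """Best match of `motif` anchored within the first `span` offsets of `seq`.

    Returns (start, mismatches) of the minimum-mismatch offset in
    ``[0, span]`` (leftmost on ties), or None when the motif does not fit.
    """
    prof = mismatch_profile(seq, motif)[: span + 1]
    if prof.size == 0:
        return None
    best = int(np.argmin(prof))
    return best, int(prof[best])


def greedy_nonoverlapping(hits):
    """Select non-overlapping hits greedily by (mismatches, start).

    `hits` is an iterable of objects with `start`, `end` and `mismatches`
    attributes.  Returns the selection sorted by start.
    """
    chosen = []
    occupied: list[tuple[int, int]] = []
    for hit in sorted(hits, key=lambda h: (h.mismatches, h.start)):
        if all(hit.end <= s or hit.start >= e for s, e in occupied):
            chosen.append(hit)
            occupied.append((hit.start, hit.end))
    chosen.sort(key=lambda h: h.start)
    return chosen
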
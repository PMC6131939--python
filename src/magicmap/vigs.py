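"""Silencing-fragment design: k-mer off-target scan and window selection.

The target CDS is chopped into every overlapping k-mer (k = 21 by default);
each k-mer is counted against all other transcripts within a Hamming
distance budget (1 mismatch by default, both strands).  The silencing
window (350 bp by default) minimizing the number of off-target-hitting
k-mers fully inside it is selected, ties going to the leftmost window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
UNTESTABLE = -1


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SelectedWindow:
    start: int  # 0-based offset into the target CDS
    length: int
    score: int  # number of off-target-hitting k-mers fully inside
    sequence: str


@dataclass
class KmerSpecificityReport:
    target_id: str
    target_seq: str
    k: int
    max_mismatch: int
    hits: np.ndarray  # per k-mer start: off-target occurrence count, -1 untestable
    both_strands: bool = True
    window: Optional[SelectedWindow] = None

    @property
    def n_kmers(self) -> int:
        return len(self.target_seq) - self.k + 1

    def __post_init__(self) -> None:
        self.hits = np.asarray(self.hits, dtype=np.int64)
        if len(self.hits) != self.n_kmers:
            raise ValueError("hit vector length must be L - k + 1")


def _distinct_neighborhood(kmer: str, budget: int) -> set[str]:
    """All distinct sequences within Hamming distance ``budget`` of ``kmer``."""
    out = {kmer}
    frontier = {kmer}
    for _ in range(budget):
        nxt = set()
        for seq in frontier:
            for i, base in enumerate(seq):
                for sub in "ACGT":
                    if sub != base:
                        nxt.add(seq[:i] + sub + seq[i + 1 :])
        frontier = nxt - out
        out |= nxt
    return out


def kmer_offtarget_scan(
    target_id: str,
    target_seq: str,
    transcriptome: dict[str, str],
    k: int = 21,
    max_mismatch: int = 1,
    both_strands: bool = True,
) -> KmerSpecificityReport:
    """Count off-target occurrences of every target k-mer.

    Occurrences are positions in non-target transcripts (and their reverse
    complements when ``both_strands``) within Hamming distance
    ``max_mismatch``.  K-mers containing N are marked untestable (-1).
    """
    target_seq = target_seq.upper()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(target_seq):
        raise ValueError(f"k={k} exceeds target length {len(target_seq)}")
    if not transcriptome:
        raise ValueError("transcriptome database is empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")

    # index every k-mer occurrence in the off-target sequences
    counts: dict[str, int] = {}
    for tid, seq in transcriptome.items():
        if tid == target_id:
            continue
        seq = seq.upper()
        strands = (seq, revcomp(seq)) if both_strands else (seq,)
        for strand_seq in strands:
            for i in range(len(strand_seq) - k + 1):
                kmer = strand_seq[i : i + k]
                counts[kmer] = counts.get(kmer, 0) + 1

    n_kmers = len(target_seq) - k + 1
    hits = np.zeros(n_kmers, dtype=np.int64)
    for p in range(n_kmers):
        kmer = target_seq[p : p + k]
        if set(kmer) - set("ACGT"):
            hits[p] = UNTESTABLE
            continue
        total = 0
        for neighbor in _distinct_neighborhood(kmer, max_mismatch):
            total += counts.get(neighbor, 0)
        hits[p] = total
    return KmerSpecificityReport(target_id, target_seq, k, max_mismatch, hits, both_strands)


def select_window(report: KmerSpecificityReport, window_length: int = 350) -> SelectedWindow:
    """Pick the window minimizing off-target-hitting k-mers inside it.

    A k-mer counts against a window only when fully contained.  Untestable
    k-mers do not count as hits.  Ties resolve to the leftmost window.
    """
    L = len(report.target_seq)
    if window_length < report.k:
        raise ValueError("window shorter than k")
    if L < window_length:
        raise ValueError(
            f"CDS length {L} is shorter than the requested window "
            f"{window_length}; shorten the window"
        )
    hitting = (report.hits > 0).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(hitting)])
    kmers_per_window = window_length - report.k + 1
    n_windows = L - window_length + 1
    scores = csum[kmers_per_window:] - csum[:-kmers_per_window]
    assert len(scores) == n_windows
    start = int(np.argmin(scores))  # argmin returns the first (leftmost) min
    win = SelectedWindow(
        start,
        window_length,
        int(scores[start]),
        report.target_seq[start : start + window_length],
    )
    report.window = win
    return win
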
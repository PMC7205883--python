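"""Greedy consensus read walking off an assembly's terminus.

Assemblies of linear replicons typically stop short of the physical
telomere.  Starting from the terminal sequence, reads that overlap the
current tip (on either strand, within a mismatch budget) vote on the next
base; the walk appends a base only while support and agreement stay above
threshold, and reports why it stopped.  The very last nucleotides of the
molecule may remain unrecoverable when read support thins out — the module
reports rather than guesses.

Reads are recruited lazily: an exact 62-bit integer encoding of every read
k-mer is scanned (vectorized) against the k-mers of the growing tip, so
only reads that can actually overlap the walk are ever indexed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from linearends._seq import encode, revcomp
from linearends.simulate import ReadSet


@dataclass
class ExtensionResult:
    end: str
    added_sequence: str
    per_base_support: list[int]
    stop_reason: str        # no_overlap | low_support | ambiguous | max_length
    extended_terminal: str  # oriented as the input terminal_seq


@dataclass
class ExtendParams:
    anchor_k: int = 31
    min_overlap: int = 31
    max_mismatch: int = 1
    min_support: int = 5
    min_agreement: float = 0.8
    max_extension: int = 1000


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact 2-bit packed k-mer integers (uint64) + validity mask."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    h = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j:j + n]
        valid &= c != 255
        h = (h << np.uint64(2)) | np.where(c == 255, 0, c).astype(np.uint64)
    return h, valid


class _ReadPool:
    """Lazy k-mer recruiter over a read set.

    All reads are concatenated (with separators) once; recruitment matches
    packed k-mer integers of a query sequence (both strands) against the
    packed k-mers of all reads and returns the owning read indices.
    """

    def __init__(self, reads: ReadSet, k: int):
        self.k = k
        self.seqs = [s for _, s in reads.reads]
        parts = []
        starts = []
        pos = 0
        sep = np.array([255], dtype=np.uint8)
        for s in self.seqs:
            starts.append(pos)
            parts.append(encode(s))
            parts.append(sep)
            pos += len(s) + 1
        self.starts = np.array(starts, dtype=np.int64)
        cat = (np.concatenate(parts) if parts
               else np.empty(0, np.uint8))
        self.hashes, self.valid = _kmer_codes(cat, k)
        order = np.argsort(self.hashes, kind="stable")
        order = order[self.valid[order]]
        self.sorted_hashes = self.hashes[order]
        self.sorted_pos = order

    def recruit(self, query: str) -> set[int]:
        """Read indices sharing an exact k-mer with query (either strand)."""
        out: set[int] = set()
        for q in (query, revcomp(query)):
            qh, qv = _kmer_codes(encode(q), self.k)
            qh = np.unique(qh[qv])
            lo = np.searchsorted(self.sorted_hashes, qh, side="left")
            hi = np.searchsorted(self.sorted_hashes, qh, side="right")
            for a, b in zip(lo, hi):
                if b > a:
                    idx = np.searchsorted(self.starts,
                                          self.sorted_pos[a:b], side="right") - 1
                    out.update(int(i) for i in idx)
        return out


def extend_end(terminal_seq: str, reads: ReadSet, end: str = "right",
               params: ExtendParams | None = None) -> ExtensionResult:
    """Extend one terminus by greedy per-base consensus voting.

    ``terminal_seq`` is the assembly's terminal sequence for that end; a
    left end is extended as the right end of its reverse complement and the
    result re-oriented.  Deterministic for a fixed read set and parameters.
    """
    p = params or ExtendParams()
    if len(terminal_seq) < p.anchor_k:
        raise ValueError("terminal sequence shorter than anchor_k")
    if not reads.reads:
        raise ValueError("empty read set")

    work = revcomp(terminal_seq) if end == "left" else terminal_seq
    pool = _ReadPool(reads, p.anchor_k)

    # per-offset anchor index over recruited reads (forward + RC orientation)
    index: dict[str, list[tuple[int, int]]] = {}
    indexed: set[int] = set()
    oriented: dict[int, str] = {}

    def admit(read_ids: set[int]) -> None:
        for ri in read_ids - indexed:
            indexed.add(ri)
            fwd = pool.seqs[ri]
            for key, s in ((2 * ri, fwd), (2 * ri + 1, revcomp(fwd))):
                oriented[key] = s
                for off in range(0, len(s) - p.anchor_k + 1):
                    index.setdefault(s[off:off + p.anchor_k], []).append(
                        (key, off))

    admit(pool.recruit(work[-(p.anchor_k + p.min_overlap):]))

    added: list[str] = []
    support: list[int] = []
    stop = "max_length"
    tip = work
    since_recruit = 0
    while len(added) < p.max_extension:
        if since_recruit >= p.anchor_k:
            admit(pool.recruit(tip[-(2 * p.anchor_k):]))
            since_recruit = 0
        anchor = tip[-p.anchor_k:]
        votes: dict[str, int] = {}
        any_overlap = False
        seen: set[tuple[int, int]] = set()
        for key, off in index.get(anchor, ()):
            if (key, off) in seen:
                continue
            seen.add((key, off))
            s = oriented[key]
            # read position `off` aligns to tip position len(tip)-anchor_k
            start = len(tip) - p.anchor_k - off
            overlap = len(tip) - max(start, 0)
            if overlap < p.min_overlap:
                continue
            mm = sum(1 for a, b in zip(tip[max(start, 0):],
                                       s[max(-start, 0):]) if a != b)
            if mm > p.max_mismatch:
                continue
            any_overlap = True
            nxt_idx = len(tip) - start
            if 0 <= nxt_idx < len(s):
                b = s[nxt_idx]
                votes[b] = votes.get(b, 0) + 1
        if not votes:
            stop = "no_overlap" if not any_overlap else "low_support"
            break
        total = sum(votes.values())
        base = min(votes, key=lambda b: (-votes[b], b))
        if votes[base] < p.min_support:
            stop = "low_support"
            break
        if votes[base] / total < p.min_agreement:
            stop = "ambiguous"
            break
        tip = tip + base
        added.append(base)
        support.append(votes[base])
        since_recruit += 1

    added_seq = "".join(added)
    extended = revcomp(tip) if end == "left" else tip
    return ExtensionResult(end=end, added_sequence=added_seq,
                           per_base_support=support, stop_reason=stop,
                           extended_terminal=extended)
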
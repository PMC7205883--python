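"""TIR delimitation from read-depth doubling.

On an assembly that collapses the terminal inverted repeat into a single
copy, reads from both physical TIR copies pile onto the retained copy, so
the TIR appears as a terminal region whose depth is twice the central
baseline.  This module maps reads (exact-seed + extend, mismatch-tolerant),
builds a per-base coverage profile, and calls the TIR boundary with a
two-segment least-squares change point on window means, refined to base
resolution.

Boundary geometry: full-length mapping loses reads that straddle the inner
junction of the removed copy, so depth ramps linearly from 2x to 1x over
exactly one read length, ending at the true boundary.  The change point
lands at the ramp midpoint; half a read length is therefore added back when
the read length is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from linearends._seq import encode, revcomp
from linearends.simulate import ReadSet, Replicon


@dataclass
class CoverageProfile:
    replicon_id: str
    depth: np.ndarray                 # per-position int depth
    window_size: int = 500
    read_length: int | None = None
    mapped_reads: int = 0
    unmapped_reads: int = 0

    @property
    def window_means(self) -> np.ndarray:
        n = self.depth.size // self.window_size
        if n == 0:
            return np.array([self.depth.mean()])
        return (self.depth[:n * self.window_size]
                .reshape(n, self.window_size).mean(axis=1))

    @property
    def mapping_rate(self) -> float:
        tot = self.mapped_reads + self.unmapped_reads
        return self.mapped_reads / tot if tot else 0.0


@dataclass
class TirCall:
    replicon_id: str
    end: str                          # "left" | "right"
    interval: tuple[int, int]
    depth_ratio: float
    status: str                       # "detected" | "undetected"
    baseline: float

    @property
    def size(self) -> int:
        return self.interval[1] - self.interval[0]


def map_reads(reads: ReadSet, assembly: Replicon, k: int = 31,
              max_mismatch: int = 8, window_size: int = 500) -> CoverageProfile:
    """Best-position seed-and-extend mapping onto one replicon.

    Exact k-mer seeds are tried at several offsets along the read (so a
    sequencing error in one seed does not lose the read), candidate
    placements on both strands are scored by full-length mismatch count,
    and the best placement wins; ties break to the leftmost position, then
    the forward strand.  Each mapped read increments depth over its span.
    """
    seq = assembly.sequence
    L = len(seq)
    if L == 0:
        raise ValueError("empty assembly")
    if k > reads.read_length:
        raise ValueError("seed k exceeds read length")
    index: dict[str, list[int]] = {}
    for i in range(L - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    codes = encode(seq)
    diff = np.zeros(L + 1, dtype=np.int64)
    mapped = unmapped = 0

    for _, rseq in reads.reads:
        m = len(rseq)
        if m < k:
            unmapped += 1
            continue
        offsets = range(0, m - k + 1, k)
        best: tuple[int, int, int] | None = None  # (mm, pos, strand)
        cand: set[tuple[int, int]] = set()
        for strand, s in ((0, rseq), (1, revcomp(rseq))):
            for off in offsets:
                for hit in index.get(s[off:off + k], ()):
                    pos = hit - off
                    if 0 <= pos <= L - m:
                        cand.add((pos, strand))
        rarr = {0: encode(rseq), 1: None}
        for pos, strand in sorted(cand):
            if strand == 1 and rarr[1] is None:
                rarr[1] = encode(revcomp(rseq))
            arr = rarr[strand]
            mm = int(np.count_nonzero(codes[pos:pos + m] != arr))
            if mm <= max_mismatch and (best is None or (mm, pos, strand) <
                                       (best[0], best[1], best[2])):
                best = (mm, pos, strand)
                if mm == 0:
                    break
        if best is None:
            unmapped += 1
        else:
            mapped += 1
            diff[best[1]] += 1
            diff[best[1] + m] -= 1
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(replicon_id=assembly.id, depth=depth,
                           window_size=window_size,
                           read_length=reads.read_length,
                           mapped_reads=mapped, unmapped_reads=unmapped)


def _changepoint(values: np.ndarray) -> int:
    """Index c in [1, n-1] minimizing two-segment squared error."""
    n = values.size
    c1 = np.cumsum(values)
    c2 = np.cumsum(values ** 2)
    cs = np.arange(1, n)
    left = c2[cs - 1] - c1[cs - 1] ** 2 / cs
    right = ((c2[-1] - c2[cs - 1])
             - (c1[-1] - c1[cs - 1]) ** 2 / (n - cs))
    return int(cs[np.argmin(left + right)])


def _call_end(depth: np.ndarray, window_means: np.ndarray, window: int,
              baseline: float, ratio_window: tuple[float, float],
              min_tir_length: int, read_length: int | None,
              replicon_id: str, end: str) -> TirCall:
    """Call one end on arrays oriented with that end first."""
    half = max(2, window_means.size // 2)
    w = window_means[:half]
    undetected = TirCall(replicon_id=replicon_id, end=end, interval=(0, 0),
                         depth_ratio=0.0, status="undetected",
                         baseline=baseline)
    if w.size < 2:
        return undetected
    c = _changepoint(w)
    ratio = float(w[:c].mean() / baseline)
    if not (ratio_window[0] <= ratio <= ratio_window[1]):
        return undetected
    # refine to base resolution around the window boundary
    b0 = c * window
    lo = max(1, b0 - 2 * window)
    hi = min(depth.size - 1, b0 + 2 * window)
    if hi - lo >= 2:
        b0 = lo + _changepoint(depth[lo:hi].astype(float))
    if read_length:
        b0 += read_length // 2   # ramp-midpoint correction (see module doc)
    b0 = min(b0, depth.size)
    if b0 < min_tir_length:
        return undetected
    return TirCall(replicon_id=replicon_id, end=end, interval=(0, b0),
                   depth_ratio=ratio, status="detected", baseline=baseline)


def detect_tir(profile: CoverageProfile,
               ratio_window: tuple[float, float] = (1.6, 2.4),
               min_tir_length: int = 1000) -> dict[str, TirCall]:
    """Call a TIR at each end from the depth-doubling signal.

    Baseline is the median window mean over the central 50% of the
    assembly; an end is "detected" iff its terminal segment's mean depth is
    within ``ratio_window`` times the baseline (the operational form of the
    twice-the-central-region rule) and at least ``min_tir_length`` long.
    """
    wm = profile.window_means
    n = wm.size
    central = wm[n // 4: max(n // 4 + 1, 3 * n // 4)]
    baseline = float(np.median(central))
    if baseline <= 0:
        raise ValueError("no central coverage")
    left = _call_end(profile.depth, wm, profile.window_size, baseline,
                     ratio_window, min_tir_length, profile.read_length,
                     profile.replicon_id, "left")
    rdepth = profile.depth[::-1]
    rwm = wm[::-1]
    right = _call_end(rdepth, rwm, profile.window_size, baseline,
                      ratio_window, min_tir_length, profile.read_length,
                      profile.replicon_id, "right")
    if right.status == "detected":
        L = profile.depth.size
        right.interval = (L - right.interval[1], L)
    return {"left": left, "right": right}


# ---------------------------------------------------------------------------
# exchange formats
# ---------------------------------------------------------------------------

def read_depth_tsv(path: str | Path, replicon_id: str = "",
                   window_size: int = 500) -> CoverageProfile:
    """Per-position depth TSV (pos<TAB>depth), for external mappers."""
    arr = np.loadtxt(str(path), dtype=np.int64, ndmin=2)
    depth = np.zeros(int(arr[:, 0].max()) + 1, dtype=np.int64)
    depth[arr[:, 0]] = arr[:, 1]
    return CoverageProfile(replicon_id=replicon_id, depth=depth,
                           window_size=window_size)


def write_calls(calls: dict[str, dict[str, TirCall]], bed_path: str | Path,
                tsv_path: str | Path) -> None:
    with open(bed_path, "w") as bed, open(tsv_path, "w") as tsv:
        tsv.write("replicon\tend\tsize\tdepth_ratio\tstatus\n")
        for rid, ends in calls.items():
            for end, call in ends.items():
                size = str(call.size) if call.status == "detected" else "-"
                tsv.write(f"{rid}\t{end}\t{size}\t{call.depth_ratio:.3f}"
                          f"\t{call.status}\n")
                if call.status == "detected":
                    bed.write(f"{rid}\t{call.interval[0]}\t{call.interval[1]}"
                              f"\tTIR_{end}\n")
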
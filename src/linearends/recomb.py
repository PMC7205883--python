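"""Consensus scanning for homologous recombination in colinear regions.

Terminal inverted repeats of conspecific linear chromosomes are highly
recombinogenic; mosaic structure shows up, in an alignment of colinear
regions, as runs of informative sites on which a putative recombinant
switches allegiance between two candidate parents.  Three detectors share
that substrate:

* ``maxchi``            — maximum 2x2 chi-square between flanking windows
                          (MaxChi-style);
* ``chimaera``          — the same statistic on the recombinant-centric
                          site subset (Chimaera-style);
* ``triplet_descent``   — maximum descent of the parent-match random walk
                          (a permutation-null relative of triplet tests).

Significance is always by seeded permutation of site order, multiple
testing across triplets by Bonferroni.  A two-phase protocol (cheap
exploratory scan over all ordered triplets, then a deep rescan of flagged
triplets) feeds a consensus step: events supported by at least
``min_methods`` detectors are merged, deduplicated across triplets sharing
a recombinant, and assigned the donor with maximal segment identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

STATE_A, STATE_B, STATE_O = 1, -1, 0


@dataclass
class InformativeSiteProfile:
    triplet: tuple[str, str, str]        # (recombinant, parentA, parentB)
    site_positions: np.ndarray           # alignment columns, increasing
    site_states: np.ndarray              # +1 matches-A, -1 matches-B, 0 other

    @property
    def n_sites(self) -> int:
        return int(self.site_positions.size)


@dataclass
class RecombinationEvent:
    recombinant: str
    donor: str
    breakpoints: tuple[int, int]         # alignment-column interval
    methods: frozenset
    p_values: dict = field(default_factory=dict)
    merged_from: int = 1
    triplet: tuple[str, str, str] | None = None
    stat: float = 0.0


def informative_sites(seqs: dict[str, str], recombinant: str, parent_a: str,
                      parent_b: str, chimaera: bool = False
                      ) -> InformativeSiteProfile:
    """Columns where the parents differ and the recombinant matches one.

    With ``chimaera`` the recombinant-matches-neither columns are dropped
    entirely; otherwise they are retained as neutral (state 0) positions.
    """
    r = np.frombuffer(seqs[recombinant].encode(), dtype=np.uint8)
    a = np.frombuffer(seqs[parent_a].encode(), dtype=np.uint8)
    b = np.frombuffer(seqs[parent_b].encode(), dtype=np.uint8)
    gap = ord("-")
    keep = (a != b) & (r != gap) & (a != gap) & (b != gap)
    states = np.where(r == a, STATE_A,
                      np.where(r == b, STATE_B, STATE_O)).astype(np.int8)
    if chimaera:
        keep &= states != STATE_O
    pos = np.flatnonzero(keep)
    return InformativeSiteProfile(
        triplet=(recombinant, parent_a, parent_b),
        site_positions=pos.astype(np.int64),
        site_states=states[pos])


# ---------------------------------------------------------------------------
# statistics (all vectorized over permutations)
# ---------------------------------------------------------------------------

def _chi2_profile(states: np.ndarray, window: int) -> np.ndarray:
    """2x2 chi-square at every breakpoint, rows = independent state vectors."""
    mat = np.atleast_2d(states)
    rows = mat.shape[0]
    m = mat.shape[1]
    zero = np.zeros((rows, 1))
    pa = np.concatenate([zero, np.cumsum(mat == STATE_A, axis=1)], axis=1)
    pb = np.concatenate([zero, np.cumsum(mat == STATE_B, axis=1)], axis=1)
    # breakpoints k in [window, m-window]; left window [k-window, k),
    # right window [k, k+window)
    ks = np.arange(window, m - window + 1)
    aL = pa[:, ks] - pa[:, ks - window]
    bL = pb[:, ks] - pb[:, ks - window]
    aR = pa[:, ks + window] - pa[:, ks]
    bR = pb[:, ks + window] - pb[:, ks]
    n = aL + bL + aR + bR
    num = n * (aL * bR - bL * aR) ** 2
    den = (aL + bL) * (aR + bR) * (aL + aR) * (bL + bR)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(den > 0, num / den, 0.0)
    return chi


def _walk_with_origin(states: np.ndarray) -> np.ndarray:
    mat = np.atleast_2d(states).astype(np.float64)
    zero = np.zeros((mat.shape[0], 1))
    return np.concatenate([zero, np.cumsum(mat, axis=1)], axis=1)


def _descent_stat(states: np.ndarray) -> np.ndarray:
    """Statistic only (no breakpoint recovery), for permutation nulls."""
    walk = _walk_with_origin(states)
    runmax = np.maximum.accumulate(walk, axis=1)
    return (runmax - walk).max(axis=1)


def _descent(states: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Max drop from the running maximum of the +A/-B walk, per row.

    The walk includes the origin, so a B-run at the very start of the
    sequence counts as a descent.  Returns (statistic, first site of the
    descent, last site of the descent) per row.
    """
    walk = _walk_with_origin(states)
    runmax = np.maximum.accumulate(walk, axis=1)
    drop = runmax - walk
    stat = drop.max(axis=1)
    trough = drop.argmax(axis=1)            # index into walk (site t-1)
    peak = np.empty_like(trough)
    for r in range(walk.shape[0]):
        peak[r] = int(walk[r, :trough[r] + 1].argmax())
    # convert to site indices: peak is the first site after the walk peak,
    # trough index t corresponds to site t-1
    return stat, peak, np.maximum(trough - 1, 0)


def _perm_pvalue(obs: float, null: np.ndarray) -> float:
    return float((1 + np.sum(null >= obs - 1e-12)) / (1 + null.size))


def _adaptive_pvalue(stat: float, states: np.ndarray, n_perm: int,
                     alpha: float, seed: int, stat_fn) -> float:
    """Permutation p-value with early stopping.

    A first batch of at most 1,000 permutations decides cheaply; the full
    depth is spent only when the statistic sits near the resolution floor
    of the first batch (where the extra permutations can matter for a
    Bonferroni-corrected alpha).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n1 = min(n_perm, 1000)
    null = _null_stats(states, n1, rng, stat_fn)
    p = _perm_pvalue(stat, null)
    if n1 < n_perm and p <= max(alpha, 10.0 / n1):
        null2 = _null_stats(states, n_perm - n1, rng, stat_fn)
        p = _perm_pvalue(stat, np.concatenate([null, null2]))
    return p


def _permuted(states: np.ndarray, n_perm: int,
              rng: np.random.Generator) -> np.ndarray:
    mat = np.tile(states, (n_perm, 1))
    return rng.permuted(mat, axis=1)


_PERM_CHUNK = 20_000


def _null_stats(states: np.ndarray, n_perm: int, rng: np.random.Generator,
                stat_fn) -> np.ndarray:
    """Permutation-null statistics, chunked to bound memory."""
    chunks = []
    left = n_perm
    while left > 0:
        k = min(left, _PERM_CHUNK)
        chunks.append(stat_fn(_permuted(states, k, rng)))
        left -= k
    return np.concatenate(chunks)


def _window_scan(profile: InformativeSiteProfile, window: int, n_perm: int,
                 alpha: float, seed: int, method: str
                 ) -> list[RecombinationEvent]:
    s = profile.site_states
    m = s.size
    # adaptive window: never wider than a quarter of the informative sites,
    # never narrower than 5 sites
    window = max(5, min(window, m // 4))
    if m < 2 * window:
        return []
    obs = _chi2_profile(s, window)[0]
    k = int(np.argmax(obs))
    stat = float(obs[k])
    p = _adaptive_pvalue(stat, s, n_perm, alpha, seed,
                         lambda m: _chi2_profile(m, window).max(axis=1))
    if p > alpha:
        return []
    ks = k + window   # site index of the breakpoint (right window start)
    bp = (int(profile.site_positions[ks - 1]),
          int(profile.site_positions[min(ks, m - 1)]))
    rec, pa, pb = profile.triplet
    return [RecombinationEvent(recombinant=rec, donor="unknown",
                               breakpoints=bp, methods=frozenset([method]),
                               p_values={method: p}, triplet=profile.triplet,
                               stat=stat)]


def maxchi_scan(profile: InformativeSiteProfile, window: int = 30,
                n_perm: int = 1000, alpha: float = 0.05,
                seed: int = 0) -> list[RecombinationEvent]:
    """MaxChi-style maximum chi-square scan over informative sites."""
    return _window_scan(profile, window, n_perm, alpha, seed, "maxchi")


def chimaera_scan(profile: InformativeSiteProfile, window: int = 30,
                  n_perm: int = 1000, alpha: float = 0.05,
                  seed: int = 0) -> list[RecombinationEvent]:
    """Chimaera-style scan: recombinant-centric site subset (no state-0)."""
    if np.any(profile.site_states == STATE_O):
        keep = profile.site_states != STATE_O
        profile = InformativeSiteProfile(
            triplet=profile.triplet,
            site_positions=profile.site_positions[keep],
            site_states=profile.site_states[keep])
    return _window_scan(profile, window, n_perm, alpha, seed, "chimaera")


def triplet_descent_scan(profile: InformativeSiteProfile, n_perm: int = 1000,
                         alpha: float = 0.05, seed: int = 0
                         ) -> list[RecombinationEvent]:
    """Maximum-descent random-walk scan (permutation-null triplet test)."""
    keep = profile.site_states != STATE_O
    s = profile.site_states[keep]
    pos = profile.site_positions[keep]
    if s.size < 4 or not (np.any(s == STATE_A) and np.any(s == STATE_B)):
        return []
    stat, peak, trough = _descent(s)
    stat, peak, trough = float(stat[0]), int(peak[0]), int(trough[0])
    p = _adaptive_pvalue(stat, s, n_perm, alpha, seed, _descent_stat)
    if p > alpha:
        return []
    bp = (int(pos[peak]), int(pos[trough]))
    rec, pa, pb = profile.triplet
    return [RecombinationEvent(recombinant=rec, donor="unknown",
                               breakpoints=bp,
                               methods=frozenset(["triplet_descent"]),
                               p_values={"triplet_descent": p},
                               triplet=profile.triplet, stat=stat)]


# ---------------------------------------------------------------------------
# consensus over triplets and methods
# ---------------------------------------------------------------------------

def _best_excess_window(rec: str, cand: str,
                        margin: float = 0.01) -> tuple[float, tuple[int, int], float]:
    """Maximum-scoring window of excess similarity of ``cand`` to ``rec``.

    Each position scores ``match - (overall match rate + margin)``; the
    best contiguous window (Kadane via prefix minima) is where ``cand``
    is anomalously similar to ``rec`` — for a true donor, the transferred
    segment.  Returns (excess score, window, identity inside window).
    """
    a = np.frombuffer(rec.encode(), dtype=np.uint8)
    b = np.frombuffer(cand.encode(), dtype=np.uint8)
    match = (a == b).astype(np.float64)
    base = match.mean()
    score = match - (base + margin)
    prefix = np.concatenate([[0.0], np.cumsum(score)])
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    end = int(np.argmax(gains))
    excess = float(gains[end])
    start = int(np.argmin(prefix[:end + 1]))
    n = max(1, end + 1 - start)
    ident = float(match[start:end + 1].mean())
    return excess, (start, end + 1), ident


def _segment_identity(a: str, b: str) -> float:
    n = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    if n == 0:
        return 0.0
    m = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return m / n


def consensus_events(per_method_events: Sequence[RecombinationEvent],
                     seqs: dict[str, str],
                     min_methods: int = 2,
                     breakpoint_merge_tol: int = 50,
                     donor_floor: float = 0.90) -> list[RecombinationEvent]:
    """Merge detector events into unique consensus recombination events.

    Events sharing a recombinant with breakpoints within tolerance are
    merged (methods and p-values pooled); merged events supported by fewer
    than ``min_methods`` detectors are dropped; each kept event gets the
    donor whose identity over the foreign segment is maximal, or "unknown"
    below ``donor_floor``.  The result is independent of input order.
    """
    events = sorted(per_method_events,
                    key=lambda e: (e.recombinant, e.breakpoints,
                                   sorted(e.methods)))
    merged: list[RecombinationEvent] = []
    segments: list[list[int]] = []          # [min, max] per merged event
    for ev in events:
        home = None
        for gi, g in enumerate(merged):
            if (g.recombinant == ev.recombinant
                    and segments[gi][0] - breakpoint_merge_tol
                    <= ev.breakpoints[1]
                    and ev.breakpoints[0]
                    <= segments[gi][1] + breakpoint_merge_tol):
                home = gi
                break
        if home is None:
            merged.append(RecombinationEvent(
                recombinant=ev.recombinant, donor="unknown",
                breakpoints=ev.breakpoints, methods=ev.methods,
                p_values=dict(ev.p_values), merged_from=1,
                triplet=ev.triplet))
            segments.append([ev.breakpoints[0], ev.breakpoints[1]])
        else:
            g = merged[home]
            g.methods = g.methods | ev.methods
            for k, v in ev.p_values.items():
                g.p_values[k] = min(v, g.p_values.get(k, 1.0))
            g.merged_from += 1
            segments[home][0] = min(segments[home][0], ev.breakpoints[0])
            segments[home][1] = max(segments[home][1], ev.breakpoints[1])
    keep = [i for i, e in enumerate(merged) if len(e.methods) >= min_methods]
    length = len(next(iter(seqs.values()))) if seqs else 0
    out = []
    for i in keep:
        ev = merged[i]
        # donor: the strain with the strongest excess-similarity window to
        # the recombinant.  A genuine donor is anomalously similar inside
        # the transferred segment only, whereas a sister strain is
        # uniformly similar and accrues no excess anywhere.  This is
        # independent of which side of the mosaic the detectors anchored.
        rec_seq = seqs[ev.recombinant]
        best, best_excess, best_in = "unknown", 0.0, 0.0
        for name, s in sorted(seqs.items()):
            if name == ev.recombinant:
                continue
            excess, _, ident_in = _best_excess_window(rec_seq, s)
            if excess > best_excess:
                best, best_excess, best_in = name, excess, ident_in
        ev.donor = best if best_in >= donor_floor else "unknown"
        out.append(ev)
    return out


def scan_population(seqs: dict[str, str],
                    window: int = 30,
                    n_perm_explore: int = 100,
                    n_perm: int = 1000,
                    alpha: float = 0.05,
                    min_methods: int = 2,
                    breakpoint_merge_tol: int = 50,
                    seed: int = 0,
                    bonferroni: bool = True) -> list[RecombinationEvent]:
    """Two-phase consensus scan over all ordered triplets of an alignment.

    Phase 1 flags triplets with a cheap permutation screen at the nominal
    alpha; phase 2 rescans only the flagged triplets at full permutation
    depth, Bonferroni-correcting over the number of rescanned triplets (the
    screening phase is exploratory; formal inference happens only on the
    rescan).  The consensus step returns unique events.
    """
    names = sorted(seqs)
    triplets = [(r, a, b)
                for r in names
                for a, b in itertools.combinations(
                    [n for n in names if n != r], 2)]
    rng = np.random.default_rng(seed)
    flagged: list[tuple[float, float, tuple[str, str, str],
                        tuple[int, int], int]] = []
    for r, a, b in triplets:
        s1 = int(rng.integers(2**31))
        prof = informative_sites(seqs, r, a, b)
        hit = (maxchi_scan(prof, window, n_perm_explore, alpha, s1)
               or triplet_descent_scan(prof, n_perm_explore, alpha, s1))
        if hit:
            p = min(min(e.p_values.values()) for e in hit)
            stat = max(e.stat for e in hit)
            flagged.append((p, -stat, (r, a, b), hit[0].breakpoints, s1))
    # merge flagged triplets into candidate regions per recombinant and keep
    # the best-supported triplet per region for the deep rescan; exploratory
    # p-values saturate at the permutation floor, so ties break on the
    # observed statistic (cleanest triplet geometry wins)
    flagged.sort()
    regions: list[tuple[tuple[str, str, str], tuple[int, int], int]] = []
    for p, _, trip, bp, s1 in flagged:
        dup = any(trip[0] == g[0][0]
                  and abs(bp[0] - g[1][0]) <= 4 * breakpoint_merge_tol
                  for g in regions)
        if not dup:
            regions.append((trip, bp, s1))
    # Bonferroni over every rescanned test (3 detectors per region)
    a_final = alpha / max(1, 3 * len(regions)) if bonferroni else alpha
    # keep the permutation p-value floor well below the corrected alpha
    n_deep = min(60_000, max(n_perm, int(np.ceil(10 / a_final))))
    found: list[RecombinationEvent] = []
    for (r, a, b), _, s1 in regions:
        prof = informative_sites(seqs, r, a, b)
        prof_c = informative_sites(seqs, r, a, b, chimaera=True)
        found += maxchi_scan(prof, window, n_deep, a_final, s1 + 1)
        found += chimaera_scan(prof_c, window, n_deep, a_final, s1 + 2)
        found += triplet_descent_scan(prof, n_deep, a_final, s1 + 3)
    return consensus_events(found, seqs, min_methods=min_methods,
                            breakpoint_merge_tol=breakpoint_merge_tol)


def per_strain_event_counts(events: Sequence[RecombinationEvent],
                            strains: Sequence[str] | None = None
                            ) -> dict[str, int]:
    """Unique-event count per recombinant strain (report-table ready)."""
    out = {s: 0 for s in (strains or [])}
    for ev in events:
        out[ev.recombinant] = out.get(ev.recombinant, 0) + 1
    return dict(sorted(out.items()))
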
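"""Telomere stem-loop architecture.

*Streptomyces*-type telomeres are the terminal ~180 nt of a linear replicon,
folded into an ordered array of palindromic stem-loops ("rabbit ears").  The
loop motif capping the stems (5'-GCA-3', 5'-GGA-3' or 5'-CTTG-3') is the
field's classifier for telomere type.  This module identifies that
architecture combinatorially: it enumerates every contiguous hairpin
(arm + 3-4 nt loop + reverse-complement arm, with a small mismatch and
sheared G.A allowance) and selects the non-overlapping subset that maximizes
the number of paired bases by dynamic programming.  Free-energy folding is
deliberately out of scope: the loop motifs and stem counts that matter for
typing are fully determined by the base-pairing combinatorics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from linearends._seq import revcomp

LOOP_CLASSES = ("GCA", "GGA", "CTTG")


@dataclass(frozen=True)
class Telomere:
    """Terminal telomere sequence, oriented with the physical terminus last."""

    replicon_id: str
    end: str  # "left" | "right"
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) > 180:
            raise ValueError("telomere longer than 180 nt")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("telomere contains non-ACGT characters")


@dataclass(frozen=True)
class Hairpin:
    """One contiguous stem-loop: arm5 + loop + arm3, arm3 ~ revcomp(arm5)."""

    arm5_interval: tuple[int, int]
    arm3_interval: tuple[int, int]
    loop_seq: str
    arm_len: int
    mismatches_in_stem: int
    sheared_GA_pairs: int

    @property
    def start(self) -> int:
        return self.arm5_interval[0]

    @property
    def end(self) -> int:
        return self.arm3_interval[1]

    @property
    def paired_bases(self) -> int:
        # canonical pairs count 2 bases; sheared purine-purine pairs are
        # weaker and count 1, so canonical stems dominate tie-breaking
        canonical = self.arm_len - self.mismatches_in_stem - self.sheared_GA_pairs
        return 2 * canonical + self.sheared_GA_pairs


@dataclass
class TelomereStructure:
    """Selected non-overlapping hairpins plus the majority loop class."""

    hairpins: list[Hairpin] = field(default_factory=list)
    total_paired_bases: int = 0
    loop_class: str = "other"


def extract_terminal(sequence: str, end: str, n: int = 180,
                     replicon_id: str = "") -> Telomere:
    """Take the terminal ``n`` bases of one end, reading inward -> terminus.

    The right terminus is returned verbatim; the left terminus is
    reverse-complemented so both ends present the telomere in the same
    orientation (physical 3' terminus last).
    """
    if not sequence:
        raise ValueError("empty sequence")
    if end == "right":
        seq = sequence[-n:]
    elif end == "left":
        seq = revcomp(sequence[:n])
    else:
        raise ValueError(f"end must be 'left' or 'right', got {end!r}")
    return Telomere(replicon_id=replicon_id, end=end, sequence=seq)


def find_hairpins(telomere: Telomere | str,
                  min_arm: int = 3,
                  max_arm: int = 15,
                  loop_lens: Iterable[int] = (3, 4),
                  max_stem_mismatch: int = 1,
                  allow_sheared_GA: bool = True) -> list[Hairpin]:
    """Exhaustively enumerate candidate hairpins.

    A candidate occupies a contiguous window ``[i, i + 2a + l)``: an arm of
    length ``a`` in [min_arm, max_arm], a loop of length ``l`` in
    ``loop_lens`` and the returning arm.  Stem positions pair canonically
    (Watson-Crick); up to ``max_stem_mismatch`` positions may not, and
    sheared G.A purine-purine pairs are tolerated without counting as
    mismatches when ``allow_sheared_GA`` (they keep the stem paired, as in
    nuclease-protection assays of archetypal telomeres).  Sheared pairing
    is defined on the telomere strand: its complementary-strand image T.C
    is not a protective pair, so folding with sheared pairs enabled is
    intentionally not reverse-complement symmetric; disable them for a
    strand-symmetric canonical model.
    """
    seq = telomere.sequence if isinstance(telomere, Telomere) else telomere
    n = len(seq)
    out: list[Hairpin] = []
    loop_lens = tuple(loop_lens)
    for i in range(n):
        for a in range(min_arm, max_arm + 1):
            for l in loop_lens:
                j = i + 2 * a + l
                if j > n:
                    continue
                arm5 = seq[i:i + a]
                arm3 = seq[i + a + l:j]
                mism = 0
                sheared = 0
                for p in range(a):
                    x, y = arm5[p], arm3[a - 1 - p]
                    if y == complement(x):
                        continue
                    if allow_sheared_GA and {x, y} == {"G", "A"}:
                        sheared += 1
                    else:
                        mism += 1
                if mism <= max_stem_mismatch:
                    out.append(Hairpin(
                        arm5_interval=(i, i + a),
                        arm3_interval=(i + a + l, j),
                        loop_seq=seq[i + a:i + a + l],
                        arm_len=a,
                        mismatches_in_stem=mism,
                        sheared_GA_pairs=sheared,
                    ))
    return out


_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


def complement(b: str) -> str:
    return _COMP1[b]


def _sort_key(h: Hairpin) -> tuple:
    return (h.end, h.start, h.arm_len, h.loop_seq)


def fold_telomere(telomere: Telomere | str,
                  candidates: Sequence[Hairpin] | None = None,
                  gna_rule: bool = True,
                  **hairpin_params) -> TelomereStructure:
    """Select the non-overlapping hairpin subset maximizing paired bases.

    Weighted interval scheduling over candidates ordered by their 3' end.
    Ties are broken toward fewer hairpins, then leftmost intervals, so the
    result is deterministic.
    """
    if candidates is None:
        candidates = find_hairpins(telomere, **hairpin_params)
    import bisect

    cands = sorted(candidates,
                   key=lambda h: (h.start, h.end, h.arm_len, h.loop_seq))
    m = len(cands)
    if m == 0:
        return TelomereStructure()
    starts = [h.start for h in cands]
    # nxt[k]: first candidate starting at or after the end of candidate k
    nxt = [bisect.bisect_left(starts, cands[k].end) for k in range(m)]
    # best_score[k]: (paired bases, -hairpin count) achievable from cands[k:]
    best_score: list[tuple[int, int]] = [(0, 0)] * (m + 1)
    take: list[bool] = [False] * m
    for k in range(m - 1, -1, -1):
        skip = best_score[k + 1]
        sub = best_score[nxt[k]]
        took = (cands[k].paired_bases + sub[0], sub[1] - 1)
        # >= so that on a full tie the leftmost-starting chain is kept
        if took >= skip:
            best_score[k] = took
            take[k] = True
        else:
            best_score[k] = skip
            take[k] = False
    chosen: list[Hairpin] = []
    k = 0
    while k < m:
        if take[k]:
            chosen.append(cands[k])
            k = nxt[k]
        else:
            k += 1
    total = sum(h.paired_bases for h in chosen)
    st = TelomereStructure(hairpins=chosen, total_paired_bases=total)
    st.loop_class = classify_loops(st, gna_rule=gna_rule)
    return st


def classify_loops(structure: TelomereStructure, gna_rule: bool = True) -> str:
    """Majority loop-motif class of a folded telomere.

    Loops are binned as GCA, GGA or CTTG; with ``gna_rule`` (default) other
    5'-GNA-3' loops (GAA, GTA) collapse into the GGA class, matching the
    field's "GNA (mostly GGA)" convention; GCA keeps its own archetypal
    class.  The strict majority over all selected hairpins wins, otherwise
    "other".
    """
    if not structure.hairpins:
        return "other"
    counts = {c: 0 for c in LOOP_CLASSES}
    for h in structure.hairpins:
        loop = h.loop_seq
        if loop in counts:
            counts[loop] += 1
        elif gna_rule and len(loop) == 3 and loop[0] == "G" and loop[2] == "A":
            counts["GGA"] += 1
    n = len(structure.hairpins)
    best = max(counts, key=lambda c: counts[c])
    if counts[best] * 2 > n:
        return best
    return "other"


def render_dotbracket(telomere: Telomere | str,
                      structure: TelomereStructure) -> str:
    """Dot-bracket text rendering of the selected hairpins."""
    seq = telomere.sequence if isinstance(telomere, Telomere) else telomere
    marks = ["."] * len(seq)
    for h in structure.hairpins:
        for p in range(*h.arm5_interval):
            marks[p] = "("
        for p in range(*h.arm3_interval):
            marks[p] = ")"
    return seq + "\n" + "".join(marks)
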
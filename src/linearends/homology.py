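"""Terminal-protein (Tap/Tpg, GtpA/GtpB) homologue detection.

Linear-replicon telomeres are capped by a terminal protein (Tpg) primed by
a telomere-associated protein (Tap); non-archetypal systems use the
GtpA/GtpB pair.  This module finds homologues of user-supplied query
proteins in a replicon's ORF set with exact Smith-Waterman alignment
(BLOSUM62, gap -11/-1) filtered at identity/coverage cutoffs (defaults 50%
identity, 98% query coverage), pairs same-strand adjacent hits into
operons, and offers a purely advisory helix-turn-helix consensus flag.

Hits falling just under the identity cutoff (45-50% by default) are kept in
a separate review tier rather than silently dropped — terminal proteins
diverge fast and borderline homologues are biologically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from linearends._seq import revcomp
from linearends.simulate import Replicon

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfRecord:
    replicon_id: str
    interval: tuple[int, int]      # 0-based half-open, forward-strand coords
    strand: str                    # "+" | "-"
    protein: str

    @property
    def orf_id(self) -> str:
        return f"{self.replicon_id}:{self.interval[0]}-{self.interval[1]}({self.strand})"


@dataclass
class HomologyHit:
    query_id: str
    subject: OrfRecord
    percent_identity: float
    query_coverage: float
    aligned_length: int
    tier: str = "hit"              # "hit" | "review"


@dataclass
class OperonCall:
    members: tuple[HomologyHit, ...]
    classification: str            # type_I_tap_tpg | type_II_tap_tpg | gtpBA | unpaired
    gap: int


def find_orfs(replicon: Replicon, min_len_codons: int = 100,
              starts: Iterable[str] = ("ATG", "GTG")) -> list[OrfRecord]:
    """All stop-terminated ORFs on both strands, first qualifying start per
    stop-to-stop segment.  Coordinates are on the forward strand."""
    starts = set(starts)
    seq = replicon.sequence
    L = len(seq)
    out: list[OrfRecord] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            start_pos: int | None = None
            for i in range(frame, L - 2, 3):
                codon = s[i:i + 3]
                if start_pos is None and codon in starts:
                    start_pos = i
                elif codon in STOPS and start_pos is not None:
                    n_codons = (i - start_pos) // 3
                    if n_codons >= min_len_codons:
                        prot = str(Seq(s[start_pos:i]).translate())
                        a, b = start_pos, i + 3
                        if strand == "-":
                            a, b = L - b, L - a
                        out.append(OrfRecord(replicon_id=replicon.id,
                                             interval=(a, b), strand=strand,
                                             protein=prot))
                    start_pos = None
                elif codon in STOPS:
                    start_pos = None
    out.sort(key=lambda o: (o.interval, o.strand))
    return out


def _protein_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def find_homologues(queries: Sequence[tuple[str, str]],
                    orfs: Sequence[OrfRecord],
                    id_cutoff: float = 50.0,
                    cov_cutoff: float = 0.98,
                    review_band: tuple[float, float] = (45.0, 50.0)
                    ) -> list[HomologyHit]:
    """Smith-Waterman homology search at identity/coverage cutoffs.

    Identity is computed over aligned columns (gaps included); coverage is
    the aligned fraction of the query.  One best hit per query x ORF.
    Near-misses inside ``review_band`` (passing coverage) are returned with
    tier "review".
    """
    if not queries or not orfs:
        return []
    aligner = _protein_aligner()
    hits: list[HomologyHit] = []
    for qid, qseq in queries:
        for orf in orfs:
            try:
                alns = aligner.align(qseq, orf.protein)
                if len(alns) == 0:
                    continue
                aln = alns[0]
            except (ValueError, OverflowError):
                continue
            ra, rb = str(aln[0]), str(aln[1])
            cols = len(ra)
            if cols == 0:
                continue
            matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
            ident = 100.0 * matches / cols
            qcov = sum(1 for x in ra if x != "-") / len(qseq)
            if qcov < cov_cutoff:
                continue
            if ident >= id_cutoff:
                tier = "hit"
            elif review_band[0] <= ident < review_band[1]:
                tier = "review"
            else:
                continue
            hits.append(HomologyHit(query_id=qid, subject=orf,
                                    percent_identity=ident,
                                    query_coverage=qcov,
                                    aligned_length=cols, tier=tier))
    return hits


def _family(query_id: str) -> str:
    q = query_id.lower()
    for fam in ("gtpb", "gtpa", "tap", "tpg"):
        if fam in q:
            return fam
    return "other"


def _subtype(query_id: str) -> str:
    q = query_id.lower()
    if "ii" in q or "type2" in q or "_2" in q:
        return "II"
    if "i" in q.replace("ii", "") or "type1" in q or "_1" in q:
        return "I"
    return ""


_PAIRS = {frozenset(("tap", "tpg")): "tap_tpg",
          frozenset(("gtpb", "gtpa")): "gtpBA"}


def call_operons(hits: Sequence[HomologyHit],
                 max_gap: int = 200) -> list[OperonCall]:
    """Pair adjacent same-strand tap+tpg or gtpB+gtpA hits into operons.

    Hits are grouped per replicon and strand, sorted by position; a pair
    within ``max_gap`` bp of intergenic distance becomes one operon call;
    everything else is reported unpaired.
    """
    real = [h for h in hits if h.tier == "hit"]
    by_group: dict[tuple[str, str], list[HomologyHit]] = {}
    for h in real:
        by_group.setdefault((h.subject.replicon_id, h.subject.strand),
                            []).append(h)
    calls: list[OperonCall] = []
    for key in sorted(by_group):
        group = sorted(by_group[key], key=lambda h: h.subject.interval)
        used = [False] * len(group)
        for i in range(len(group) - 1):
            if used[i]:
                continue
            a, b = group[i], group[i + 1]
            fams = frozenset((_family(a.query_id), _family(b.query_id)))
            gap = b.subject.interval[0] - a.subject.interval[1]
            if fams in _PAIRS and 0 <= gap <= max_gap:
                kind = _PAIRS[fams]
                if kind == "tap_tpg":
                    sub = _subtype(a.query_id) or _subtype(b.query_id) or "I"
                    kind = f"type_{sub}_tap_tpg"
                calls.append(OperonCall(members=(a, b), classification=kind,
                                        gap=gap))
                used[i] = used[i + 1] = True
        for i, h in enumerate(group):
            if not used[i]:
                calls.append(OperonCall(members=(h,),
                                        classification="unpaired", gap=-1))
    return calls


def hth_flag(protein: str, pattern: str,
             threshold: float = 0.8) -> tuple[bool, int]:
    """Advisory helix-turn-helix flag by consensus-pattern scan.

    ``pattern`` is a consensus string ('x' = any residue); each window is
    scored as its fraction of matching positions, and the best-scoring
    window is flagged if it reaches ``threshold``.  Returns (flag, offset);
    offset is -1 when not flagged.
    """
    if len(protein) < 40:
        raise ValueError("protein shorter than 40 aa")
    w = len(pattern)
    if w == 0 or w > len(protein):
        return False, -1
    best, best_pos = -1.0, -1
    pat = pattern.upper()
    for i in range(len(protein) - w + 1):
        win = protein[i:i + w]
        score = sum(1 for a, b in zip(win, pat)
                    if b == "X" or a == b) / w
        if score > best:
            best, best_pos = score, i
    if best >= threshold:
        return True, best_pos
    return False, -1
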
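"""Synthetic population of conspecific linear replicons.

Emulates a sympatric population of *Streptomyces*-like strains: linear
chromosomes with long terminal inverted repeats (TIRs), 180-nt palindromic
telomeres, sub-clade structure, and the rearrangement events that reshape
chromosome ends — break-induced-replication (BIR) homogenization of the two
arms, telomere swaps with linear plasmids, HGT mosaics, indels, inversions
and translocations.  Every strain carries a complete ground-truth
annotation (TIR intervals, telomere sequences, event log, true tree), so
downstream detection stages can be scored without any external data.

Desk-scale defaults (200-kb chromosome, 20-kb TIR) keep simulation cheap;
real-scale presets (Mb chromosomes, hundreds-of-kb TIRs) are a config away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from linearends._seq import decode, encode, random_dna, revcomp

TELOMERE_LEN = 180

#: loop motifs by sub-clade, mirroring the population this simulator emulates:
#: one clade with CTTG-capped telomeres, two with GNA/GGA, one plasmid-like GCA
DEFAULT_CLADE_MOTIFS = ("CTTG", "GGA", "GGA", "GCA")

# spacers/padding use a two-letter, non-self-complementary alphabet (C-rich to
# mimic high GC): no window made only of {C,A} can pair with itself, so the
# constructed stems are provably the only inverted repeats in the telomere.
_PAD_ALPHABET = ("C", "A")
_PAD_WEIGHTS = (0.72, 0.28)


class ConstructionOverflow(ValueError):
    """Requested stems cannot fit in the telomere length."""


@dataclass(frozen=True)
class EvolutionEvent:
    """One rearrangement applied to one strain after tree derivation.

    kind:
      substitution_burst  extra substitutions in [position, position+length)
      terminal_indel      deletion (length<0) or random insertion (length>0)
                          at position
      bir_homogenize      copy the donor arm's terminal `length` bases onto
                          the other arm (reverse-complemented); payload is
                          the donor end ("left"/"right")
      telomere_swap       replace the terminal 180 nt of `payload[1]` end
                          with the telomere of donor replicon payload[0]
      hgt_insert          payload ("replace", donor_id) overwrites
                          [position, position+length) with the donor's
                          homologous segment; payload ("insert", seq)
                          inserts seq at position
      translocation       move [position, position+length) to payload (bp)
      inversion           reverse-complement [position, position+length)
                          in place
    """

    kind: str
    strain: str
    position: int = 0
    length: int = 0
    payload: object = None


@dataclass
class TruthAnnotation:
    tir_interval_left: tuple[int, int]
    tir_interval_right: tuple[int, int]
    telomere_left: str
    telomere_right: str
    event_log: list[EvolutionEvent] = field(default_factory=list)
    true_tree: str = ""
    collapsed_end: str | None = None

    @property
    def tir_length_left(self) -> int:
        return self.tir_interval_left[1] - self.tir_interval_left[0]

    @property
    def tir_length_right(self) -> int:
        return self.tir_interval_right[1] - self.tir_interval_right[0]


@dataclass
class Replicon:
    id: str
    sequence: str
    topology: str = "linear"
    truth: TruthAnnotation | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty replicon sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    reads: list[tuple[str, str]]  # (id, sequence); constant-quality FASTQ
    read_length: int
    coverage_target: float
    seed: int

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class PopulationConfig:
    n_strains: int = 11
    chromosome_length: int = 200_000
    tir_length: int = 20_000
    gc_content: float = 0.72
    telomere_motif: str | dict[int, str] | None = None  # None -> clade defaults
    n_stems: int = 6
    subclade_assignment: dict[str, int] | None = None
    substitution_rate: float = 5e-4
    event_list: list[EvolutionEvent] = field(default_factory=list)
    seed: int = 0
    homogenize_tirs: bool = True
    strain_names: list[str] | None = None
    plasmids: list[dict] = field(default_factory=list)
    tree_newick: str | None = None

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if 2 * self.tir_length >= self.chromosome_length:
            raise ValueError("TIRs must leave a single-copy center")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if self.tir_length and self.tir_length < TELOMERE_LEN:
            raise ValueError("telomere (180 nt) must fit inside the TIR")


# ---------------------------------------------------------------------------
# telomere construction
# ---------------------------------------------------------------------------

def _pad(n: int, rng: np.random.Generator) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(_PAD_ALPHABET, size=n, p=_PAD_WEIGHTS))


def _attempt_telomere(motif: str, n_stems: int, stem_range: tuple[int, int],
                      spacer_range: tuple[int, int],
                      rng: np.random.Generator) -> str:
    if n_stems == 0:
        return _pad(TELOMERE_LEN, rng)
    arms = list(rng.integers(stem_range[0], stem_range[1] + 1, size=n_stems))
    spacers = list(rng.integers(spacer_range[0], spacer_range[1] + 1,
                                size=max(0, n_stems - 1)))

    def total() -> int:
        return sum(2 * a + len(motif) for a in arms) + sum(spacers)

    # shrink sampled arms/spacers toward their minima if the draw overflows
    while total() > TELOMERE_LEN:
        shrunk = False
        for lst, lo in ((arms, stem_range[0]), (spacers, spacer_range[0])):
            for i, v in enumerate(lst):
                if total() <= TELOMERE_LEN:
                    break
                if v > lo:
                    lst[i] = v - 1
                    shrunk = True
        if not shrunk:
            raise ConstructionOverflow(
                f"{n_stems} stems of arm >= {stem_range[0]} bp with "
                f"{len(motif)}-nt loops cannot fit in {TELOMERE_LEN} nt")
    parts = []
    for i, a in enumerate(arms):
        arm = random_dna(int(a), 0.72, rng)
        parts.append(arm + motif + revcomp(arm))
        if i < len(spacers):
            parts.append(_pad(int(spacers[i]), rng))
    core = "".join(parts)
    return _pad(TELOMERE_LEN - len(core), rng) + core


def build_telomere(motif: str, n_stems: int,
                   stem_range: tuple[int, int] = (4, 8),
                   spacer_range: tuple[int, int] = (2, 6),
                   seed: int = 0) -> str:
    """Construct a 180-nt telomere with ``n_stems`` loop-capped hairpins.

    Stems sit flush against the physical terminus (last base), mirroring the
    terminal palindome arrays of linear-replicon telomeres.  The returned
    sequence folds back to exactly ``n_stems`` hairpins, all capped with
    ``motif``; this postcondition is verified constructively against the
    folding module and the padding re-sampled (deterministically) in the
    rare case a junction window forms an accidental palindrome.
    """
    from linearends import struct as _struct

    if len(motif) not in (3, 4):
        raise ValueError("loop motif must be 3 or 4 nt")
    if not 0 <= n_stems <= 12:
        raise ValueError("n_stems must be in [0, 12]")
    min_total = (n_stems * (2 * stem_range[0] + len(motif))
                 + max(0, n_stems - 1) * spacer_range[0])
    if min_total > TELOMERE_LEN:
        raise ConstructionOverflow(
            f"{n_stems} stems cannot fit in {TELOMERE_LEN} nt")
    for attempt in range(64):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, attempt])
        telo = _attempt_telomere(motif, n_stems, stem_range, spacer_range, rng)
        assert len(telo) == TELOMERE_LEN
        if n_stems == 0:
            return telo
        st = _struct.fold_telomere(telo)
        if (len(st.hairpins) == n_stems
                and all(h.loop_seq == motif for h in st.hairpins)):
            return telo
    raise RuntimeError("telomere construction failed to converge")


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def default_subclades(n: int) -> list[int]:
    """Clade index per strain; mirrors a 4+3+2+2 population at n=11."""
    if n <= 3:
        return [0] * n
    pattern = [4, 3, 2, 2]
    sizes: list[int] = []
    i = 0
    left = n
    while left > 0:
        s = min(pattern[i % 4], left)
        sizes.append(s)
        left -= s
        i += 1
    out = []
    for clade, s in enumerate(sizes):
        out.extend([clade] * s)
    return out


def _caterpillar(names: Sequence[str]) -> str:
    t = names[0]
    for nm in names[1:]:
        t = f"({t}:1,{nm}:1)"
    return t


def _default_tree(names: Sequence[str], clades: Sequence[int]) -> str:
    groups: dict[int, list[str]] = {}
    for nm, c in zip(names, clades):
        groups.setdefault(c, []).append(nm)
    subtrees = [_caterpillar(groups[c]) if len(groups[c]) > 1 else groups[c][0]
                for c in sorted(groups)]
    if len(subtrees) == 1:
        tree = subtrees[0]
    else:
        tree = subtrees[0]
        for s in subtrees[1:]:
            tree = f"({tree}:1,{s}:1)"
    return tree + ";"


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes.copy()
    out = codes.copy()
    hit = np.flatnonzero(rng.random(out.size) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _mirror_tirs(seq: str, tir_len: int) -> str:
    """Overwrite the left arm with the reverse complement of the right arm."""
    if tir_len == 0:
        return seq
    return revcomp(seq[-tir_len:]) + seq[tir_len:]


def _truth_for(seq: str, tir_len: int, tree: str) -> TruthAnnotation:
    L = len(seq)
    n = min(TELOMERE_LEN, L)
    return TruthAnnotation(
        tir_interval_left=(0, tir_len),
        tir_interval_right=(L - tir_len, L),
        telomere_left=revcomp(seq[:n]),
        telomere_right=seq[-n:],
        true_tree=tree,
    )


def simulate_population(config: PopulationConfig) -> list[Replicon]:
    """Derive a strain population (chromosomes + optional plasmids).

    An ancestral chromosome is generated at the configured GC with exact
    reverse-complement TIRs and loop-capped telomeres; strains descend along
    a fixed sub-clade tree with per-branch substitutions, clade-specific
    telomeres are planted, and the configured rearrangement events applied
    in order.  Chromosomes come first in the returned list, plasmids after.
    """
    rng = np.random.default_rng(config.seed)
    L, T = config.chromosome_length, config.tir_length
    names = config.strain_names or [f"strain{i+1:02d}"
                                    for i in range(config.n_strains)]
    if len(names) != config.n_strains:
        raise ValueError("strain_names length != n_strains")
    if config.subclade_assignment is not None:
        clades = [config.subclade_assignment[nm] for nm in names]
    else:
        clades = default_subclades(config.n_strains)
    tree = config.tree_newick or _default_tree(names, clades)

    def clade_motif(c: int) -> str:
        if isinstance(config.telomere_motif, str):
            return config.telomere_motif
        if isinstance(config.telomere_motif, dict):
            return config.telomere_motif[c]
        return DEFAULT_CLADE_MOTIFS[c % len(DEFAULT_CLADE_MOTIFS)]

    # ancestor: [revcomp(right TIR)] + center + [right TIR]; telomere last
    telo_seed = int(rng.integers(2**31))
    if T:
        anc_telo = build_telomere(clade_motif(0), config.n_stems,
                                  seed=telo_seed)
        right_tir = (random_dna(T - TELOMERE_LEN, config.gc_content, rng)
                     + anc_telo)
        center = random_dna(L - 2 * T, config.gc_content, rng)
        ancestor = revcomp(right_tir) + center + right_tir
    else:
        ancestor = random_dna(L, config.gc_content, rng)

    # derive leaves: substitutions accumulate along the path root->leaf;
    # path length = clade depth proxy (2 branches within clade + clade edge)
    anc_codes = encode(ancestor)
    clade_ids = sorted(set(clades))
    clade_codes: dict[int, np.ndarray] = {}
    for c in clade_ids:
        clade_codes[c] = _mutate(anc_codes, config.substitution_rate, rng)
    clade_telos = {c: build_telomere(clade_motif(c), config.n_stems,
                                     seed=telo_seed + 1 + c)
                   for c in clade_ids} if T else {}

    strains: list[Replicon] = []
    for nm, c in zip(names, clades):
        codes = _mutate(clade_codes[c], config.substitution_rate, rng)
        seq = decode(codes)
        if T:
            # plant the clade telomere at the right arm, then mirror so the
            # TIR copies stay identical (continual BIR homogenization)
            seq = seq[:-TELOMERE_LEN] + clade_telos[c]
        if config.homogenize_tirs and T:
            seq = _mirror_tirs(seq, T)
        truth = _truth_for(seq, T, tree)
        strains.append(Replicon(id=nm, sequence=seq, truth=truth))

    plasmids: list[Replicon] = []
    for pc in config.plasmids:
        plen = pc.get("length", 20_000)
        ptir = pc.get("tir_length", 2_000)
        pmotif = pc.get("telomere_motif", "GCA")
        pseed = int(rng.integers(2**31))
        if ptir:
            ptelo = build_telomere(pmotif, pc.get("n_stems", config.n_stems),
                                   seed=pseed)
            rt = random_dna(ptir - TELOMERE_LEN, config.gc_content, rng) + ptelo
            pseq = revcomp(rt) + random_dna(plen - 2 * ptir,
                                            config.gc_content, rng) + rt
        else:
            pseq = random_dna(plen, config.gc_content, rng)
        plasmids.append(Replicon(id=pc["id"], sequence=pseq,
                                 truth=_truth_for(pseq, ptir, "")))

    by_id = {r.id: r for r in strains + plasmids}
    for ev in config.event_list:
        _apply_event(by_id, ev)
    return strains + plasmids


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _apply_event(by_id: dict[str, Replicon], ev: EvolutionEvent) -> None:
    rep = by_id[ev.strain]
    seq, tr = rep.sequence, rep.truth
    L = len(seq)
    rng = np.random.default_rng(
        [abs(hash(ev.strain)) % (2**31), ev.position & 0x7FFFFFFF])

    if ev.kind == "substitution_burst":
        a, b = ev.position, ev.position + ev.length
        if not (0 <= a <= b <= L):
            raise ValueError("burst outside replicon bounds")
        codes = encode(seq)
        codes[a:b] = _mutate(codes[a:b], 0.05, rng)
        rep.sequence = decode(codes)

    elif ev.kind == "terminal_indel":
        p = ev.position
        if ev.length < 0:
            d = -ev.length
            if not (0 <= p and p + d <= L) or d >= L:
                raise ValueError("deletion outside bounds or destroys replicon")
            rep.sequence = seq[:p] + seq[p + d:]
            lt = tr.tir_length_left - _overlap((p, p + d), tr.tir_interval_left)
            rt = tr.tir_length_right - _overlap((p, p + d),
                                                tr.tir_interval_right)
            Ln = L - d
            tr.tir_interval_left = (0, max(0, lt))
            tr.tir_interval_right = (Ln - max(0, rt), Ln)
        else:
            if not (0 <= p <= L):
                raise ValueError("insertion outside bounds")
            ins = random_dna(ev.length, 0.72, rng)
            rep.sequence = seq[:p] + ins + seq[p:]
            lt, rt = tr.tir_length_left, tr.tir_length_right
            if p < lt:
                lt += ev.length
            if p > L - rt:
                rt += ev.length
            Ln = L + ev.length
            tr.tir_interval_left = (0, lt)
            tr.tir_interval_right = (Ln - rt, Ln)

    elif ev.kind == "bir_homogenize":
        d = ev.length or ev.position
        donor_end = ev.payload or "right"
        if not 1 <= d < L // 2:
            raise ValueError("BIR breakpoint must keep a single-copy center")
        if donor_end == "right":
            rep.sequence = revcomp(seq[L - d:]) + seq[d:]
        else:
            rep.sequence = seq[:L - d] + revcomp(seq[:d])
        tr.tir_interval_left = (0, d)
        tr.tir_interval_right = (L - d, L)
        n = min(TELOMERE_LEN, L)
        tr.telomere_left = revcomp(rep.sequence[:n])
        tr.telomere_right = rep.sequence[-n:]

    elif ev.kind == "telomere_swap":
        donor_id, end = ev.payload
        donor = by_id[donor_id]
        telo = donor.truth.telomere_right
        if end == "right":
            rep.sequence = seq[:-len(telo)] + telo
            tr.telomere_right = telo
        else:
            rep.sequence = revcomp(telo) + seq[len(telo):]
            tr.telomere_left = telo

    elif ev.kind == "hgt_insert":
        mode, data = ev.payload
        p = ev.position
        if mode == "replace":
            donor = by_id[data]
            seg = donor.sequence[p:p + ev.length]
            if len(seg) != ev.length or p + ev.length > L:
                raise ValueError("replacement outside bounds")
            rep.sequence = seq[:p] + seg + seq[p + ev.length:]
        else:
            if not 0 <= p <= L:
                raise ValueError("insertion outside bounds")
            rep.sequence = seq[:p] + data + seq[p:]
            Ln = L + len(data)
            lt, rt = tr.tir_length_left, tr.tir_length_right
            if p < lt:
                lt += len(data)
            if p > L - rt:
                rt += len(data)
            tr.tir_interval_left = (0, lt)
            tr.tir_interval_right = (Ln - rt, Ln)

    elif ev.kind == "translocation":
        p, d, dest = ev.position, ev.length, int(ev.payload)
        if not (0 <= p and p + d <= L and 0 <= dest <= L - d):
            raise ValueError("translocation outside bounds")
        seg = seq[p:p + d]
        rest = seq[:p] + seq[p + d:]
        rep.sequence = rest[:dest] + seg + rest[dest:]

    elif ev.kind == "inversion":
        p, d = ev.position, ev.length
        if not (0 <= p and p + d <= L):
            raise ValueError("inversion outside bounds")
        rep.sequence = seq[:p] + revcomp(seq[p:p + d]) + seq[p + d:]

    else:
        raise ValueError(f"unknown event kind {ev.kind!r}")
    tr.event_log.append(ev)


# ---------------------------------------------------------------------------
# collapsed assemblies and reads
# ---------------------------------------------------------------------------

def collapse_assembly(replicon: Replicon, collapse_end: str = "right") -> Replicon:
    """Remove one TIR copy, emulating an NGS assembly that collapses the
    terminal duplication into a single copy."""
    if replicon.truth is None:
        raise ValueError("collapse requires a truth annotation")
    tr = replicon.truth
    L = len(replicon.sequence)
    if collapse_end == "right":
        cut = tr.tir_length_right
        seq = replicon.sequence[:L - cut] if cut else replicon.sequence
        new = TruthAnnotation(
            tir_interval_left=tr.tir_interval_left,
            tir_interval_right=(len(seq), len(seq)),
            telomere_left=tr.telomere_left,
            telomere_right=tr.telomere_right,
            event_log=list(tr.event_log),
            true_tree=tr.true_tree,
            collapsed_end="right" if cut else None,
        )
    elif collapse_end == "left":
        cut = tr.tir_length_left
        seq = replicon.sequence[cut:] if cut else replicon.sequence
        Ln = len(seq)
        new = TruthAnnotation(
            tir_interval_left=(0, 0),
            tir_interval_right=(Ln - tr.tir_length_right, Ln),
            telomere_left=tr.telomere_left,
            telomere_right=tr.telomere_right,
            event_log=list(tr.event_log),
            true_tree=tr.true_tree,
            collapsed_end="left" if cut else None,
        )
    else:
        raise ValueError("collapse_end must be 'left' or 'right'")
    return Replicon(id=replicon.id + "_asm", sequence=seq, truth=new)


_MIN_READ = 31


def simulate_reads(replicon: Replicon, coverage: float, read_length: int = 300,
                   error_rate: float = 1e-3, seed: int = 0) -> ReadSet:
    """Uniform shotgun reads from a linear molecule.

    Fragment starts are uniform over ``[-(read_length-1), L-1]`` and reads
    are clipped at the molecule boundaries (minimum clipped length 31 nt),
    so per-base coverage is uniform all the way to the physical termini —
    the fragmentation of a linear molecule produces fragments abutting its
    ends.  Strand is Bernoulli(0.5); substitution errors are i.i.d. at
    ``error_rate``.  Byte-identical output for a fixed seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    L = len(replicon.sequence)
    if read_length > L:
        raise ValueError("read_length exceeds replicon length")
    rng = np.random.default_rng(seed)
    n = int(round(coverage * L / read_length))
    starts = rng.integers(-(read_length - 1), L, size=n)
    strands = rng.random(n) < 0.5
    codes = encode(replicon.sequence)
    reads: list[tuple[str, str]] = []
    for i in range(n):
        a = max(0, int(starts[i]))
        b = min(L, int(starts[i]) + read_length)
        if b - a < _MIN_READ:
            continue
        arr = codes[a:b].copy()
        if error_rate > 0:
            hit = np.flatnonzero(rng.random(arr.size) < error_rate)
            if hit.size:
                arr[hit] = (arr[hit] + rng.integers(1, 4, size=hit.size)) % 4
        if strands[i]:
            arr = (3 - arr)[::-1]
        reads.append((f"{replicon.id}_r{i}", decode(arr)))
    return ReadSet(reads=reads, read_length=read_length,
                   coverage_target=coverage, seed=seed)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fasta(replicons: Sequence[Replicon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in replicons:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), 80):
                fh.write(r.sequence[i:i + 80] + "\n")


def read_fasta(path: str | Path) -> list[Replicon]:
    from Bio import SeqIO

    return [Replicon(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in readset.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path, read_length: int | None = None,
               coverage: float = 0.0, seed: int = 0) -> ReadSet:
    from Bio import SeqIO

    reads = [(rec.id, str(rec.seq).upper())
             for rec in SeqIO.parse(str(path), "fastq")]
    rl = read_length or (max(len(s) for _, s in reads) if reads else 0)
    return ReadSet(reads=reads, read_length=rl, coverage_target=coverage,
                   seed=seed)


def write_truth(replicons: Sequence[Replicon], json_path: str | Path,
                bed_path: str | Path | None = None) -> None:
    """Ground truth as JSON plus TIR intervals as BED (0-based half-open)."""
    obj = {}
    for r in replicons:
        if r.truth is None:
            continue
        t = r.truth
        obj[r.id] = {
            "length": len(r.sequence),
            "tir_interval_left": list(t.tir_interval_left),
            "tir_interval_right": list(t.tir_interval_right),
            "telomere_left": t.telomere_left,
            "telomere_right": t.telomere_right,
            "true_tree": t.true_tree,
            "events": [{"kind": e.kind, "strain": e.strain,
                        "position": e.position, "length": e.length,
                        "payload": repr(e.payload)} for e in t.event_log],
        }
    Path(json_path).write_text(json.dumps(obj, indent=1))
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in replicons:
                if r.truth is None:
                    continue
                t = r.truth
                for end, (a, b) in (("left", t.tir_interval_left),
                                    ("right", t.tir_interval_right)):
                    if b > a:
                        fh.write(f"{r.id}\t{a}\t{b}\tTIR_{end}\n")
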
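# Methods

This note records the models, parameter choices and numerical decisions
behind `linearends`, and what the simulator-based tests do and do not
demonstrate about real data.

## Population simulator

The simulator emulates a sympatric population of conspecific strains with
linear replicons. An ancestral chromosome is drawn at a configurable GC
content (default 0.72, typical of high-GC actinobacteria) with exact
reverse-complement TIRs (`left arm = revcomp(right arm)`) and a telomere
occupying the terminal 180 nt of each arm. Strains descend along a fixed
tree — by default, sub-clades of 4+3+2+2 strains joined as caterpillars —
with i.i.d. per-site substitutions on each branch (default 5×10⁻⁴ per
site per branch). Each sub-clade is assigned a telomere built from its own
loop motif (defaults CTTG, GGA, GGA, GCA), planted identically in every
member; this mirrors the empirical observation that telomeres are
invariant within sub-clades but barely alignable between them.

After tree derivation, TIR copies are re-mirrored (`homogenize_tirs`,
default on): biologically, recurrent BIR keeps the two arms identical,
and the 2× depth signal that TIR detection relies on only exists for
near-identical copies. Rearrangement events are then applied in order:
substitution bursts, terminal indels, BIR homogenization
(`bir_homogenize` with breakpoint *d* copies one arm's terminal *d* bases
onto the other arm, reverse-complemented, so a breakpoint upstream of the
TIR grows both copies), telomere swaps (terminal 180 nt replaced by a
donor replicon's telomere; following with `bir_homogenize` propagates the
new telomere to both ends), homologous replacements (`hgt_insert` in
"replace" mode overwrites a segment with the donor strain's homologous
segment), insertions, inversions and translocations. Ground truth (TIR
intervals, inward-oriented telomere sequences, event log, true tree) is
carried on every replicon.

**Telomere construction.** `build_telomere` packs *n* stems (arms 4–8 bp,
loops = the motif) against the terminal end of a 180-nt window, separated
by 2–6-nt spacers. Spacers and padding are drawn from the two-letter
alphabet {C, A} (C-rich, matching the high GC): no window of {C, A} can
pair with itself, so the planted stems are provably the only inverted
repeats in the padding. Junction windows can still form accidental
candidates, so construction verifies its own postcondition against the
folding module and deterministically resamples (up to 64 attempts) until
the fold returns exactly *n* hairpins, all capped with the motif.

**Reads.** Fragment starts are uniform over `[-(L_read-1), L-1]` and
reads are clipped at the molecule boundaries (minimum clipped length
31 nt). This models the fragmentation of a linear molecule, whose
fragments abut the physical ends — without it, the expected depth at the
final base of full-length-only reads is `coverage/read_length` (≈0.2× at
50×/300 bp) and no read-walking method could ever reach the telomere.
Interior coverage is uniform at the nominal depth; expected read count is
`coverage·L/read_length`. Errors are i.i.d. substitutions (default 10⁻³);
no indel errors, no pairing, constant quality strings. Defaults of 300-bp
reads at 50× reflect the short-read regime the analysis is designed for.

What the simulator does **not** model: real base-quality profiles, indel
sequencing errors, coverage biases (GC, origin-proximity), within-TIR
divergence between arms, and gene content. Tests passing on this
generator demonstrate the correctness and calibration of the algorithms
under the stated model, not performance on any particular instrument's
error profile.

## TIR detection

Reads are mapped by exact 31-mer seeding at multiple offsets with
full-length mismatch scoring (default budget 8), best position winning;
ties break leftmost, then forward strand. Depth is accumulated over
aligned spans. Window means (500-bp windows) feed a two-segment
least-squares change point per end; the baseline is the median window
mean over the central 50% of the assembly. An end is called `detected`
iff the terminal segment's mean is within [1.6, 2.4]× the baseline — the
operational form of the twice-the-central-region rule, with a window
rather than a point threshold to absorb sampling noise — and at least
1 kb long (the `undetected` status covers replicons that genuinely lack
TIRs). The boundary is refined to base resolution in a ±2-window
neighborhood, then shifted inward by half a read length: full-length
mapping drops reads straddling the removed copy's inner junction, so
depth ramps linearly from 2× to 1× over exactly one read length ending at
the true boundary, and the change-point estimator lands at the ramp
midpoint. The residual error at desk scale (95th percentile over 50
replicates) is ≈110 bp, inside the one-read-length uncertainty that the
depth signal fundamentally carries.

## Terminal extension

Greedy consensus walking: reads sharing an exact 31-mer with the growing
tip are recruited lazily (vectorized 2-bit k-mer matching over the read
pool), aligned by anchor offset, filtered to ≥31-nt overlap with ≤1
mismatch, and vote on the next base. A base is accepted at support ≥5 and
agreement ≥0.8; otherwise the walk stops with a reason (`no_overlap`,
`low_support`, `ambiguous`, or `max_length` at 1,000 nt). Left ends are
extended as the right end of the reverse complement. The walk is
deterministic for a fixed read set. Near the physical terminus support
falls to the clipped-read count; the module reports what it could not
recover rather than guessing.

## Telomere structure

Thermodynamic folding is deliberately replaced by base-pair-maximizing
combinatorics: the quantities that type a telomere — stem count and loop
motif — are determined by palindrome structure, not by free energy.
Candidates are every contiguous `arm(3–15) + loop(3–4) + revcomp(arm)`
with ≤1 stem mismatch; sheared G·A pairs are tolerated separately and
score 1 paired base against 2 for a canonical pair, so canonical stems
dominate tie-breaks. Selection is weighted interval scheduling (maximize
paired bases; ties → fewer hairpins, then leftmost), verified against
exhaustive subset search on short inputs. Sheared pairing is defined on
the telomere strand: its complementary-strand image T·C is not a
protective pair, so folding with sheared pairs enabled is intentionally
not reverse-complement symmetric; the symmetric invariant holds for the
canonical (sheared-disabled) model. Loop classification takes the strict
majority among GCA, GGA (with other 5′-GNA-3′ loops folded into the GGA
class) and CTTG; anything else, including ties, is `other`.

## Telomere phylogeny

Progressive alignment with fixed scores (match +1, mismatch −1, gap open
−5, extend −1), UPGMA guide tree on pairwise p-distances, profile–profile
merges with sum-of-pairs column scores — fully deterministic. Columns
with non-gap fraction strictly below 0.80 are removed (the boundary case,
exactly 80%, is kept). K2P distances use pairwise deletion; pairs whose
log arguments vanish are flagged saturated and excluded from NJ unless
overridden (bootstrap replicates cap saturated distances at twice the
finite maximum to stay total). NJ is Saitou–Nei with lexicographic
tie-breaking on the Q criterion and negative branch lengths clamped to
zero, the deficit moved to the sister branch. Bootstrap support is the
percentage of 100 column-resampled replicates containing each internal
bipartition.

Congruence: bipartitions are compared after collapsing (near-)zero-length
internal edges — identical within-clade telomeres make those resolutions
tie-break artifacts, not signal. A leaf is reported incongruent when
pruning it strictly reduces the conflicting-bipartition count; cherry
partner changes are reported alongside. A telomere replacement is only
topologically detectable when the recipient has close relatives: swapping
the telomere of a strain with no sister (a singleton sub-clade) lengthens
a branch without moving any bipartition, and an entirely alien telomere
(for example from an unrelated plasmid) saturates all distances and lands
arbitrarily. The detectable — and empirically observed — scenario is
acquisition of another lineage's telomere, which pulls the recipient into
the donor's cluster.

## Recombination scanning

Within a colinear alignment, for each ordered triplet the informative
sites are biallelic parent-differing columns. MaxChi slides a breakpoint
with flanking windows of 30 sites (shrunk adaptively to a quarter of the
informative sites, floor 5) and takes the maximum 2×2 χ²; Chimaera does
the same after removing recombinant-matches-neither sites; the descent
statistic is the maximum drop from the running maximum of the ±1 walk
(origin included, so leading segments count). All p-values are seeded
permutations of site order; site order is exchangeable under the no-
recombination null, making the tests exact. Population scans are
two-phase: a cheap exploratory screen over all ordered triplets flags
candidate (recombinant, region) pairs; the best-supported triplet per
region is rescanned at full permutation depth with Bonferroni correction
over all rescanned tests (3 detectors × regions), the permutation depth
scaled so its resolution floor sits below the corrected alpha (adaptive
escalation keeps the cost at ~1,000 permutations for clear rejections).
Events from different detectors merge when their breakpoint intervals
overlap within 50 columns; events seen by ≥2 detectors survive. The donor
is the strain with the largest excess-similarity window to the
recombinant (Kadane's maximum-subarray on per-site match minus the
overall match rate plus a 1% margin): a genuine donor is anomalously
similar inside the transferred segment only, whereas a sister strain is
similar everywhere and accrues no excess; `unknown` is reported below a
90% identity floor. Detection is symmetric between donor and recipient
(both carry the shared segment), so reciprocal events can appear; scans
of simulated populations recover planted transfers with correct
recombinant and donor and stay empty on transfer-free controls at a
per-branch substitution rate of 1% (a few percent parental divergence,
the regime in which window statistics have power at desk scale).
Population scans exclude the terminal ~200 nt by default: the planted
clade telomere is itself a legitimate exchange signal, but it belongs to
the phylogeny stage, and leaving it in puts a breakpoint at the telomere
boundary of every between-clade triplet.

## Terminal-protein homology

ORFs (ATG/GTG starts, ≥100 codons, stop-terminated, both strands; first
qualifying start per stop-to-stop segment) are searched with exact
Smith–Waterman (BLOSUM62, gap −11/−1). Identity is computed over aligned
columns and coverage over the query; hits require ≥50% identity and ≥98%
query coverage. Because local alignment trims diverged termini, coverage
and identity interact near the cutoffs; borderline homologues at 45–50%
identity are kept in a separate `review` tier rather than silently
dropped — terminal proteins diverge fast and real homologues sit near
this boundary. Adjacent same-strand tap+tpg or gtpB+gtpA hits within
200 bp pair into operon calls. The helix-turn-helix flag is a plain
consensus-pattern scan (fraction of matching positions ≥0.8) and is
advisory only.

## Pipeline

Stages run in dependency order with per-stage seeds derived as
`sha256(global_seed, stage) mod 2³¹`, so any stage can be rerun in
isolation. Every artifact is checksummed into a manifest;
identical config + seed reproduces identical checksums. The report joins
stage outputs per strain (TIR size/status per end, telomere class,
incongruence flag, TP systems, recombination counts); absent stages yield
"—", never fabricated values. In pipeline runs the terminal extension
stage first truncates the assembly terminus by a configurable few tens of
nucleotides (default 60) before walking it back — emulating the common
situation where a published assembly stops short of the physical end.

## Problem sizes

Defaults are desk scale — 200-kb chromosomes with 20-kb TIRs, 20–30-kb
toys in unit tests, 50 replicates in calibration suites — chosen so the
full test suite and the acceptance script each complete in minutes on one
CPU while leaving every signal-to-noise regime (depth doubling, support
thresholds, permutation resolution) representative of the real, Mb-scale
setting, which is a configuration preset away.
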
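# Methods

This note documents the models, defaults and numerical choices behind
`crfkit`, and what its synthetic benchmark does and does not demonstrate.

## Motif models

**Degenerate patterns.** The AP2/ERF DNA-binding core is represented as the
25-symbol consensus `AAEIRD**RR*R*WLGT*DTAEEAA`, where `*` matches any
residue and the WLG block (positions 13–15, 0-based) must match exactly: it
is essential for DNA binding, so no mismatch budget can excuse it.  The
remaining 17 fixed positions tolerate up to `max_mismatches` substitutions
(default 2).  Pattern hits score the negated mismatch count so that "higher
is better" holds for every hit kind.  `X` (unknown residue) matches only
wildcard positions.  Each AP2 hit is tagged ERF-type or CBF/DREB-type by
comparing its first six residues to `AAEIRD` and `VAEIRE` (fewer mismatches
wins; ties count as ERF-type), since that hexamer determines GCC-box versus
DRE/CRT binding.  The SP[TV]SVL phosphorylation motif is the same machinery
with a two-member residue set and no mismatch allowance.

**Profiles.** The CRF core (~40 aa) and the TEH region (~13 aa) vary too
much across land plants for a single exact consensus, and their residue-level
content is supplied by the user as seed alignments.  A seed alignment is
turned into a per-position log-odds matrix in bits:

    score_c(r) = log2( (n_c(r) + κ·b_r) / (N_c + κ) / b_r )

with `n_c(r)` the count of residue `r` in kept column `c`, `N_c` the number
of counted (non-gap, non-`X`) rows in that column, `κ` the pseudocount
(default 1) and `b` the background frequencies (default uniform 1/20, which
keeps null calibration analytic).  Columns gapped in more than half the rows
are dropped; minority gaps and `X` are simply excluded from the counts, so
`N_c` varies per column.  Zero pseudocount is allowed only when every
residue is observed in every kept column.

**Scanning and thresholds.** Profile scanning scores every window and
reports those at or above the profile threshold, keeping only the
best-scoring hit among overlapping same-kind windows (ties go to the
leftmost; this makes output deterministic).  Two thresholding routes exist:

* `calibrate_threshold` draws `n_null ≥ 1000` i.i.d. background windows and
  returns the empirical `1 − FPR` score quantile — the principled choice
  when the tolerable per-window false-positive rate is known;
* the default pipeline instead sets the threshold to **half the profile's
  maximum attainable score**.  For domain-sized profiles built from
  low-divergence seeds, the null score distribution sits far below half the
  maximum (tens of standard deviations for a 40-column profile), so false
  positives are vanishingly rare while substantial divergence from the seed
  consensus is still detected.  This keeps the default independent of any
  particular null sample size.

## Architecture rules

A protein is called CRF when its best-scoring CRF-core/AP2 hit pair has the
core N-terminal to the AP2 and a spacer (core end → AP2 start) within
`[spacer_min, spacer_max]`.  Defaults are 20–120 residues around the
canonical ~60: no variance is established for the spacer, so the band is
deliberately wide; ordered pairs outside it are flagged `SPACER_ATYPICAL`
and not called CRF.  Candidate pairs are ranked by summed hit score with
ties broken toward the smallest core start, favoring the canonical
N-terminal placement.  Clade A requires a TEH hit ending within
`teh_gap_max` residues (default 5) of the chosen core start — the TEH
immediately precedes the core, with a little slack for boundary jitter.
Both knobs are exposed because neither adjacency nor spacer spread has a
published estimate.  A `PHOS_MOTIF` hit only counts toward the
`PHOS_MOTIF_PRESENT` flag when it lies downstream of the chosen AP2 end,
matching the motif's C-terminal placement.  A CRF core with no AP2 hit
anywhere contradicts the family model (the CRF domain is never found
without an AP2 domain) and yields `UNCLASSIFIED` plus
`CRF_WITHOUT_AP2_ANOMALY` instead of a silent call.

## Phylogeny

Only domain columns enter the tree: hit spans (TEH when present, CRF core,
AP2) are lifted through each row's gap structure to alignment columns, and
the union of those columns over all CRF calls is kept, in original order;
non-CRF rows are dropped.

Distances are uncorrected p-distances with pairwise deletion — columns
gapped in either row of a pair are skipped, and a pair with no comparable
columns is an error (and, inside the bootstrap, grounds to redraw the
replicate).  Poisson-corrected distances were considered and rejected for
the default: at the within-family divergences involved the correction is
nearly monotone, so it cannot change NJ input orderings enough to justify a
nonlinearity the user did not ask for.

Neighbor joining follows Saitou–Nei exactly: minimize
`Q(i,j) = (m−2)·d(i,j) − r_i − r_j`, join, assign limb lengths, reduce.
Two choices the algorithm leaves open are fixed deterministically: Q ties
(compared at 1e-12) go to the lexicographically smallest taxon pair, each
cluster being represented by its smallest member label; negative limb
lengths are clamped to zero with the deficit moved to the sister limb, which
preserves the joined pair's path length.  On additive inputs the original
topology and all branch lengths are recovered exactly (checked to 1e-6
against random 4–8 taxon trees).

Bootstrap support resamples alignment columns with replacement, rebuilds
distance + NJ per pseudoreplicate, and annotates each internal edge of the
tree built on the original block with its bipartition frequency as an
integer percent.  Supports are computed on unrooted bipartitions; rooting
is applied afterwards.  All supports are recorded; those below 50 carry a
`below_threshold` annotation, mirroring the convention of displaying only
majority support.  Default replicate count is 1000 (configurable; tests and
examples use 25–100 to stay fast).  Outgroup rooting splits the subtending
edge's length equally; a non-monophyletic outgroup roots above its smallest
containing clade and records `NON_MONOPHYLETIC_OUTGROUP`.

Newick output prints branch lengths to six decimals and supports as
internal-node labels, so a round trip preserves topology exactly, supports
exactly, and each branch length to 5·10⁻⁷.

## Synthetic benchmark

The generator emulates the CRF architecture, not plant evolution.  Category
proportions default to 0.4 / 0.2 / 0.2 / 0.2 (clade A / clade B / ERF-only /
background), realizing the ~2:1 A:B abundance observed within sequenced
genomes.  Clade sequences are `[N-flank][TEH 13][core 40][spacer][AP2 25]
[C-flank]`; clade B carries a random segment in the TEH slot.  The spacer is
one draw from Normal(60, 10) truncated at ≥ 20; flank lengths are uniform on
[10, 80]; background sequences are uniform-residue strings of length 150–350.
Flank and spacer lengths are drawn **once per simulation** and shared by all
CRF sequences, so the CRF set doubles as a gap-free pseudo-alignment whose
domain columns are known exactly — the property the phylogeny tests need;
gap handling is exercised separately on hand-built fixtures.  The CRF core
and TEH consensus are random draws per seed (synthetic stand-ins for curated
seed material), and 8-row seed alignments at 10% divergence accompany them.
Domain residues (TEH, core, AP2) are substituted with uniform random
residues at `substitution_rate` (default 0.1, matching the seed divergence);
the SP[TV]SVL hexamer, embedded with probability 0.5 downstream of the AP2,
is exact by definition and not mutated.  A CRF core is never emitted without
an AP2 domain.

What passing tests show: the detectors and rules recover exactly the
architecture the generator embeds, with perfect sensitivity and specificity
at zero substitution and graceful, monotone degradation as domains diverge
from the seed consensus.  What they do not show: performance on real
proteomes, where backgrounds are compositionally biased, domains drift in
length (the generator has no indels), flanks contain homologous repeats, and
the true CRF/TEH consensus differs from a random string.  Real use requires
curated seed alignments and, ideally, threshold calibration against a
realistic background.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere, including TSV output.
* The residue alphabet is the 20 standard amino acids plus `X`; B/Z/U/J are
  rejected with a position-numbered error rather than silently recoded.
* Profile scores use log base 2 so worked examples have closed forms.
* All stochastic operations (threshold calibration, bootstrap, simulation)
  take explicit integer seeds and are bit-reproducible given them.
* CLI outputs are written atomically (temp file + rename) and carry a
  header comment with version, config hash and seed; no partial files are
  left on error.
* Test and example problem sizes (hundreds of proteins, 8-taxon bootstrap
  blocks, 25–200 replicates) are chosen so the full suite runs in well under
  a minute while every code path is exercised; the library itself has no
  size limits beyond the O(n³) cost of NJ.
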
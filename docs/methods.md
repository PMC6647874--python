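# Methods

This note documents the models, conventions and tunable parameters behind
`t3mine`, the design choices made where the underlying screening tradition
leaves room, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and promoter extraction

All genomic coordinates are 1-based inclusive (the GenBank/GFF3
convention); the arithmetic lives in `genome.py` alone.  An upstream
(promoter) region is returned on the coding strand of its gene, 5′→3′,
ending at the base immediately before the start codon; for minus-strand
genes this is the reverse complement of the genomic segment after the
annotated end.  Windows truncate at contig edges but **not** at neighboring
CDS by default — the screen is a plain fixed-window scan, and operons with
short intergenic gaps would otherwise silently lose hits; a
`truncate_at_cds` switch restores the conservative behavior.  Annotated
translations are taken verbatim; computed translations use the bacterial
code (table 11) and drop the terminal stop, matching common flat-file
practice.

## hrp-box scanning

A motif pattern is an ordered list of fixed IUPAC blocks and variable
spacers.  Two renderings of the hrp box circulate and disagree; both ship:

- `hrp_box_screen` (default): `N GGAAC N — spacer 15–16 — CCAC N N A G`,
  the form used for genome screening, with `x` read as any base;
- `hrp_box_consensus`: `GGAACC — spacer 15/16 — CCACNNA`, the shorter
  classical consensus.

The scanner enumerates **every** (start, spacer-length) assignment —
overlapping matches are all reported, deduplicated only when bit-identical —
and is tested for equality with a brute-force enumerator.  A genomic `N`
matches no motif symbol, including wildcards: ambiguous assembly bases never
create hits.  `gene_distance` is the gap between the last matched base and
the base before the start codon; the biological screen keeps
30 ≤ gene_distance ≤ 300 bp.  The scan window defaults to
`max_dist + max motif span` (331 nt for the default pattern) so a motif
ending exactly at the distance cap is still findable.  Scanning is
coding-strand only (the sigma factor reads the promoter directionally).  A
per-element mismatch allowance exists for exploring divergent boxes but
defaults to 0; published screens show divergent positions without stating a
mismatch budget, so none is guessed.

One degenerate case deserves a note: with either shipped tail
(`CCACxxAG`/`CCACNNA`) a 15- and a 16-spacer match can never share a 5′
anchor — the tail conflicts with its own one-base shift — so multi-spacer
hits at one anchor only arise for shift-compatible custom tails; the test
suite demonstrates the enumeration with one.

## N-terminal effector features

Features are computed over the first `window` = 50 aa (initiator Met =
position 1), the convention of the N-terminal secretion-signal literature;
the criteria themselves name no window.  Residue sets are configurable
because the tradition never fixes them; defaults are
aliphatic = {I, L, V, A, P} and polar = {S, T, N, Q, C, Y, G, H}.
"Abundance" thresholds default to `ser_frac ≥ 0.10` and
`polar_frac ≥ 0.40` and are printed in every report, since no numeric
thresholds are published.  The acidic rule is genuinely ambiguous in the
literature — "one acidic residue in the first 12 positions" versus an
"abundance" of acidic residues — so it is a config enum
(`at_most_one` (default) | `none` | `at_least_one`), and the mode in force
is logged on every run rather than silently resolved.  A gene is a putative
effector iff every enabled criterion passes **and** it is hrp-box-positive;
per-criterion flags are always emitted so alternative thresholds can be
replayed from the feature table without rescanning.  Proteins shorter than
4 aa (position 3/4 undefined) are recorded as unevaluable, never dropped.

## Component search and cluster chaining

Each gene product is aligned to every panel entry by optimal local
(Smith–Waterman) alignment with affine gaps — BLOSUM62, gap open 11,
extend 1 by default, where a gap of length L costs `open + (L−1)·extend`.
Percent identity is identical columns over aligned columns (the BLAST
convention) and coverage is the spanned fraction of the reference entry.
A gene keeps only its best-scoring component; hits below 30% identity or
0.5 coverage are dropped — 30% mirrors the lower end of the similarity
range observed between cluster components of related strains.  Hits are
chained by single linkage along each contig with inter-gene gaps capped at
`max_gap` = 5 kb; intervening non-panel genes do not break a chain.  Each
cluster reports its first-to-last-member span (the boundary convention is
otherwise unstated in the screening tradition), the roles present, and
which of the conserved core — rscV, rscN, rscQAB, rscR, rscS, rscT, rscU,
rscC, rscJ, rspL, rspR — it lacks.

The packaged panel (`data/t3ss_panel.synthetic.fasta`) carries the real
component names and role vocabulary but **synthetic** residues generated
once from a fixed seed: no curated component sequences are redistributed,
and any FASTA with `name|role` headers can be swapped in.  Consequently
absolute alignment scores against real proteomes are meaningless with the
default panel; within the synthetic benchmark the panel is the ground
truth itself.

## Distance phylogenetics

Nucleotide distances use the Kimura two-parameter model,
`d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)` with P/Q the transition/transversion
fractions over comparable columns; protein distances use the 20-state
Jukes–Cantor correction `d = −(19/20) ln(1−20p/19)`.  Gap and ambiguous
columns are pairwise-deleted by default (complete deletion is a switch):
pairwise deletion maximizes comparable sites on sparse alignments.  A log
argument ≤ 0 raises a saturation error; inside a matrix the pair is flagged
and set infinite instead.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion.  Ties are broken deterministically by the lexicographically
smallest pair of cluster representatives (a cluster is represented by its
smallest leaf label); the Q matrix is computed so that float symmetry is
exact, making tie detection reliable.  Negative branch lengths are clamped
to zero and the total clamped deficit recorded — the simplest defensible
rule, without redistributing the deficit.  Bootstrap supports resample
alignment columns with replacement; support of a bipartition is the
percentage of successful replicates whose NJ tree contains it.  Replicates
with a saturated pair are skipped and counted.  For an all-identical
alignment the tie-broken topology is reproduced by every replicate, so its
(arbitrary) splits carry 100% support — a documented convention, not a
statement about resolution.  Supports are rounded to integers for Newick
internal labels; raw fractions are kept in the JSON report.  Alignments are
consumed pre-aligned (any aligner's multi-FASTA); alignment construction is
out of scope.

## Synthetic genomes and what they show

The generator plants, in one genome: plain conformant hrp boxes; near-miss
decoys that are wrong in exactly one respect (spacer 13/14/17/18, distance
outside 30–300 bp, or a one-base core mutation); effector ORFs whose first
50 aa exceed every default threshold with ≥ 0.05 margin in each fraction;
effector decoys violating exactly one named criterion; and a contiguous
run of panel homologs mutated at a configurable per-residue rate (default
0.20) with ~15 kb span at the default pitch.  Defaults for the benchmark
genome are 2 Mb, GC 0.60 (Pseudomonas-like), 5 conformant boxes, 10 box
decoys, 10 effectors, 10 effector decoys, 20 background genes.  The
background is i.i.d. sequence scrubbed of accidental motif cores in both
orientations, gene pitches keep every scan window inside scrubbed
intergenic sequence, and non-effector genes are constructed to fail the
position-3/4 criterion, so the manifest is the complete truth and
precision = recall = 1.0 is the expected outcome, not a statistical one.
Generation is bit-for-bit reproducible from (config, seed) and
self-verifies against its own manifest before returning.

What passing these benchmarks shows: the scanner, filter, aligner, chainer
and tree builder implement their definitions exactly.  What it does not
show: performance on real genomes — real promoters are not i.i.d.
background, real effectors hug the thresholds instead of clearing them
with margin, real annotations contain fuzzy and frame-shifted features,
and real hit counts depend on the exact assembly and annotation screened.
Headline counts from published screens of real strains (tens of box
genes funneling to 10–15 effectors; 18–26 kb clusters) require those
assemblies and are deliberately not asserted anywhere.

The alignment simulator evolves sequences along a given tree under K80
(κ configurable, default 4) or 20-state JC using the models' exact
finite-time substitution probabilities, so distance-estimator consistency
and topology-recovery tests have known truth.

## Problem sizes in tests and acceptance

Unit and acceptance runs use: 300-kb and 2-Mb synthetic genomes, 1,000
random regions ≤ 200 nt for scanner-oracle equivalence, 500 random pairs
≤ 30 aa for aligner-oracle equivalence, 100 random additive trees ≤ 12
taxa for NJ exactness, and 100 bootstrap replicates for determinism and
the two-clade support check.  These sizes make the whole suite run in well
under a minute while every check remains exact rather than statistical.

## Known limitations

- No mismatch-tolerant PWM scoring; the motif model is presence/absence.
- No gene calling: unannotated contigs need external annotation first.
- Fuzzy GenBank locations (`<`, `>`) and cross-contig joins are rejected.
- The default panel is synthetic (see above); real screens should supply a
  curated panel FASTA.
- NJ is the only tree method; no likelihood or Bayesian inference.
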
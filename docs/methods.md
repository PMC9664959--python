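# Methods

This note documents the models and procedures implemented in `pypfam`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic data does and does not establish.

## Pairwise alignment and search statistics (`pypfam.align`)

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment are computed
by Gotoh's three-state dynamic program under BLOSUM62 with affine gap cost
`gap(k) = gap_open + k·gap_extend`, defaults 11/1 (BLAST's convention: a
length-1 gap costs 12). All scores are integers, so optimality and
tie-breaking are exact; traceback ties resolve diagonal > up > left, making
alignments deterministic. The inner loops are numba-compiled; correctness is
pinned by two independent routes in the tests — exhaustive enumeration of
every alignment for short sequences, and Biopython's `PairwiseAligner` under
the identical scoring model for longer ones.

E-values use the Karlin–Altschul formula `E = K·m·n·exp(−λS)` with the
standard gapped-BLOSUM62 constants λ = 0.267, K = 0.041 (overridable); the
search space defaults to the product of the two sequence lengths. Bit scores
are `(λS − ln K)/ln 2`.

Coverage is computed separately for query and subject as aligned span over
full length, and the network filter requires **both** to pass the threshold
— the stricter of the readings of a one-sided "coverage ≥ 80%" filter, and
the domain-sane one.

Redundancy reduction is greedy incremental clustering in the CD-HIT style:
longest sequence first (ties by id), each sequence joins the first
representative with global-alignment identity ≥ the threshold (identity =
identical columns / alignment length, gap columns included), else founds a
new cluster. 95% is used before the all-vs-all step, 80% inside HMM
training rounds.

## Similarity network and Markov clustering (`pypfam.simnet`)

The network is unweighted: an undirected edge joins two sequences if at
least one direction survives the coverage/E-value filter; the surviving
directed hits are kept for cluster-graph weighting. MCL follows the standard
recipe: self-loops of weight 1 (aperiodicity), column normalization, then
iterated expansion (matrix power, default 2), inflation (entrywise power
*I*, then renormalization), and pruning of entries < 1e−5 with
renormalization. Convergence is max-abs change < 1e−6, capped at 200
iterations; non-convergence returns the current iterate's clustering with a
warning and flag. Clusters come from the attractor structure of the limit
matrix (nodes with positive diagonal, connected through shared support);
nodes attracted to several clusters go to the largest (tie: lowest cluster
id). Cluster ids are 1..k by decreasing size, ties broken by smallest
member index, matching the size-ordered numbering used in similarity-network
figures. Inflation 1.0 makes the inflation step a no-op and is reported
flagged (non-convergent or a single cluster per component), which is the
expected degenerate behavior of the sweep.

Cluster-graph conventions: node display size `log10(size)`; edge weight
between clusters A ≠ B is observed directed inter-cluster hits divided by
all possible mutual hits, `2·|A|·|B|` ("mutual" read as ordered pairs in
both directions; the alternative `|A|·|B|` denominator is a one-line
override).

## Reference mapping and the family rule (`pypfam.refmap`)

Reference numbering is 1-based position on the supplied reference sequence
(the *H. halophila* PYP numbering for the real protein). A homolog is
globally aligned to the reference; each reference position maps to the
aligned residue or a gap. Maps scoring below 20 bits are flagged unreliable
and excluded from calling and MSA building — below that floor the position
map is noise. A substitution label `{ref}{pos}{obs}` is emitted whenever the
observed residue differs (gaps written `-`); *functional* is defined as
cysteine at position 69 — without it there is no thioester and no
chromophore, so a gap there also forces non-functional.

The star MSA merges the pairwise reference alignments: reference positions
are shared columns; insertions relative to the reference occupy left-aligned
insert blocks (one per inter-reference slot, as wide as the longest
insertion). Conservation profiles are computed over reference-anchored
columns only, per group, as frequencies over the 20 residues plus gap.

The classifier's perfect precision/recall guarantee is scoped to sequences
with global identity ≥ 0.5 to the reference: below that, the alignment
itself can misplace a position (observed at roughly one sequence in 200
among the deliberately diverged non-functional subgroup), which is a
property of reference mapping at extreme divergence, not of the rule.

## Profile HMM (`pypfam.phmm`)

A simplified profile HMM in the HMMER tradition, glocal: every match state
must be traversed (via match or delete); sequence flanks are absorbed by
free insert states at both ends. Alignment columns with non-gap occupancy
≥ 50% become match states (the knob `match_occupancy`). Match emissions are
`(counts + w·background)/(n + w)` with background-mixture pseudocount
weight w = 1.0 by default; insert states emit the background, so inserts
cost only transitions. Transitions are counted from each row's observed
state path and smoothed by adding w to every legal option; the topology has
no I↔D edges and observed I→D/D→I steps (possible in arbitrary MSAs) are
dropped from the counts. Scores are log2-odds (bits) against the background
residue model; forward sums paths, Viterbi maximizes with ties broken
M > D > I. Both are verified against explicit path enumeration on small
models in probability space, and forward ≥ Viterbi is asserted on random
pairs. There is no E-value calibration: the model is used with per-model
bit-score cutoffs, as family models with gathering thresholds are.

Cutoffs derive from Cys69 conservation: TC (trusted) is the lowest score of
a functional training member, NC (noise) the highest score of any scored
non-functional sequence (0 bits if none), and GA (gathering) the TC/NC
midpoint floored at NC. The iterative build repeats align → reduce
redundancy at 80% → build → search → union GA hits into the training set,
stopping when the hit set repeats (flagged oscillating if it matches a
round earlier than the last) or after `max_rounds` (default 5).

## Gene neighborhoods and phyletic census (`pypfam.genomics`)

"Within five genes" counts gene-index offsets on the same contig, both
directions and both strands, clipped at contig ends. Coordinates are
1-based inclusive and intergenic distance is
`downstream.start − upstream.end − 1`, so book-ended genes are 0 bp apart
and overlaps are negative. Operon co-membership requires one strand across
the path and every consecutive gap ≤ 100 bp (configurable; a common
prokaryotic heuristic — the choice only shifts the operon flag, not the
window census). Neighbor-category fractions count, per category, the
fraction of functional family genes with ≥1 such neighbor in the window.

The census applies two rules per phylum: *displayed* iff ≥ 10 genomes are
available **and** ≥ 5 contain a functional family gene; *HGT-flagged* iff
the carrier count is positive but below 5 — few carriers in an otherwise
well-sampled phylum are better explained by horizontal transfer than by
vertical descent.

## Phylogeny (`pypfam.phylo`)

Distances are Poisson-corrected mismatch fractions, `d = −ln(1−p)`, with
pairwise gap deletion; p ≥ 0.95 is capped at `−ln(0.05)` and flagged. This
replaces maximum-likelihood inference under an empirical substitution model
deliberately: it is closed-form, dependency-free, and sufficient for
clade-level structure on data of this divergence; it is not a substitute
for ML on real, deeply diverged families. Neighbor joining is the classic
Saitou–Nei agglomeration; ties in the Q-criterion take the first minimal
pair in working order, and negative branch lengths are clamped to zero with
the deficit moved to the sister branch (sums preserved). Additive matrices
are reproduced exactly (tested at 4 and 5 taxa, and against scikit-bio's
`nj` by topology). Clade assignment gives each leaf the clade of its
nearest anchor by path length; exact ties are left unassigned. On real
data anchors are user-supplied exemplars; the pipeline run on synthetic
data takes two exemplars per planted clade in their stead.

## Synthetic data (`pypfam.synthdata`)

The generator emulates the statistical structure the analysis assumes, not
any real taxon's sequences:

* **Families.** Ancestors are drawn i.i.d. from BLOSUM62 background
  frequencies (length 125, the PYP length scale). Evolution runs along a
  random Kingman-coalescent-shaped bifurcating tree rescaled to a
  root-to-leaf depth (default 0.15 substitutions/site within a clade), with
  per-branch per-site substitution probability `1 − e^(−t)` and uniform
  replacement — the simplest process giving graded similarity for MCL.
  The three planted clades diverge from a common family root (0.35
  subs/site) before diversifying; decoy families are unrelated ancestors
  with the same length and internal depth. Indels are disabled by default
  so motif positions map exactly; the reference is the family root.
* **Motifs and substitutions.** All clades keep Y42/E46/S50/C69; clades A
  and B keep F92/F96/W119; clade C keeps M100 instead — the clade-signature
  pattern of the real family. Labeled substitutions are planted per
  sequence at configured rates (defaults Y42F 0.10, E46Q 0.05, C69S 0.16,
  i.e. 84% of members keep Cys69). A 42- and a 46-substitution are never
  planted together, emulating the observed mutual exclusion of those sites
  in functional homologs. Sequences that lose Cys69 additionally receive
  0.30 subs/site of extra divergence: in the real family the
  Cys69-substituted homologs are an overall-diverged subgroup, and the
  conservation-based cutoff procedure presupposes that non-functional
  sequences are score-separable — without this the NC/GA/TC ordering is
  unachievable in principle, since one residue cannot move a bit score.
* **Genomes.** Genome counts per phylum are exact; each genome carries a
  family gene with its phylum's prevalence. Defaults give ~400 genomes in
  12 phyla shaped like the real census: four well-sampled carrier phyla,
  six sparse-carrier (HGT-regime) phyla, one zero-prevalence phylum, and
  one phylum under the 10-genome display floor, with *Myxococcota* the
  densest. Carrier contigs hold 15 genes with lengths U[300, 1500] bp,
  random strands, and intergenic gaps U[−30, 300] bp (so overlaps occur);
  neighbor categories (TAL, pCL, HMOX, DLD, MCP, GGDEF, EAL, HK, RR) are
  placed independently within the ±5 window at the configured frequencies,
  default 0.2–0.4.
* **Determinism.** Every draw flows from named `numpy` generators derived
  from the config seed; a fixed config reproduces byte-identical FASTA,
  TSV, and GFF3 output.

What passing tests do **not** show about real data: the generator has no
indel process by default, no compositional biases, no domain fusions, no
paralogy, and its decoys are unrelated rather than distantly related — so
the measured perfect cluster separation and recovery rates are upper bounds
for well-separated families, not predictions for Pfam-scale inputs.

## Pipeline problem sizes and reproducibility

The default pipeline conditions process ~270 sequences (≈70 family members
sized by the carrier draw, 4 × 50 decoys) across ~400 genomes; the tree
stage caps at 80 leaves. These sizes keep the complete run in seconds while
leaving every statistical check well-powered (binomial checks use 300–500
draws). The pipeline writes a manifest of parameter values and SHA-256
checksums of every artifact; rerunning a config reproduces the checksums
byte-for-byte, which is asserted in the tests.

## Known limitations

* Alignment has no heuristic seeding or composition statistics; it is exact
  DP, quadratic per pair — appropriate at desk scale, not database scale.
* HMM scores have no E-value calibration and no multi-domain parsing.
* The operon rule is a gap-and-strand heuristic, not a model of
  transcription units.
* Clade anchoring requires exemplars; on real data their choice is the
  user's scientific decision.
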
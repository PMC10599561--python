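# Methods

## The procedure

`pleomine` implements a marker-based procedure for recovering
pleolipovirus-like genomes from assembled metagenomes and organizing them
into five genera. The chain is:

1. **Marker database.** For each conserved gene a seed set of proteins is
   searched against a protein database; hits with e-value < 10⁻⁵ and score
   > 50 join the family and are re-searched, recursively, until a fixed
   point (no new significant hit). A position-specific scoring model is
   built from the family and calibrated on true-positive scores (family
   members) and true-negative scores (unrelated proteins): the acceptance
   threshold is `max(min TP, max TN + 10)`, pass inclusive. A warning is
   recorded whenever the rule excludes a true positive (it can, when TP and
   TN score ranges overlap).
2. **Screen.** ORFs (≥ 90 codons, ATG-initiated, stop-terminated, both
   strands) are scanned against the calibrated profiles. Contigs ≥ 2 kb with
   ≥ 1 passing core marker are candidates; contigs ≥ 4.5 kb carrying all
   four core markers, one strand, canonical order, every adjacent inter-gene
   gap ≤ 4.5 kb, are high-confidence. Among multiple valid marker subsets
   the smallest span wins.
3. **Completeness.** A genome is complete iff it has a direct or inverted
   terminal repeat (exact, ≥ 20 bp; DTR precedence on ties), is a complete
   integrated provirus (≥ 2 non-viral genes strictly on *both* flanks of the
   viral region plus an integrase hit inside it), or carries an external
   completeness score of exactly 100. Evidence is accumulated, not
   overwritten, so a call lists every satisfied clause.
4. **Dereplication.** ANI is computed by slicing one genome into 500 bp
   windows, aligning each into the other genome by edit distance (windows
   below 70 % identity count as unaligned), averaging identity over aligned
   windows, and taking the better direction; the aligned fraction is
   measured on the shorter genome. Clustering is greedy longest-first at
   ANI ≥ 95 % and aligned fraction ≥ 0.85 — the standard species-rank
   convention for uncultivated virus genomes. The aligned-fraction threshold
   is a package choice (exposed as a parameter); the identity threshold is
   the species convention.
5. **Taxonomy.** Replication hallmarks take precedence: polB → gamma,
   RCRE → alpha; Rep-positive genomes are beta or delta according to the
   smallest clade of the concatenated ORF7+ORF8 neighbor-joining tree that
   has bootstrap support ≥ 0.95 and contains references of exactly one
   genus; hallmark-free genomes are epsilon only when that clade is the
   epsilon reference clade. Two or more replication hallmarks on one genome
   is a conflict → unassigned; so is failure to place. Distances are
   p-distances over mutually ungapped columns with Poisson correction
   d = −ln(1 − p) (p clipped below 1); pairs with zero mutually ungapped
   columns are reported and excluded.
6. **Host calls.** CRISPR spacer matches (substitutions only, ≤ 1 mismatch
   by default, either strand) take precedence over integrated host scores:
   the spacer-matched host with the most distinct matching spacers wins
   (ties: higher score, then lexicographic host id); with no spacer
   evidence, the best score wins if ≥ 90; otherwise no call. The score
   threshold is applied inclusively (≥ 90). Integrated scores are inputs,
   not computed — upstream host-prediction machinery is out of scope.
7. **Network.** Protein clusters are connected components of the
   reciprocal-significant-hit graph (both directions e ≤ 10⁻³ under a
   Karlin–Altschul-style e-value on the database size); genomes are linked
   when they share ≥ 2 clusters. The association report runs
   Wilcoxon(degree | integrase), Wilcoxon(length | integrase) and
   Pearson + Spearman(degree, length), two-sided throughout.

## Search engines

The expansion procedure is engine-agnostic behind a `(queries, database) →
hits` contract. The reference engine is exact Smith–Waterman (BLOSUM62,
gap 11/1) with bit scores `(λS − ln K)/ln 2` (gapped BLOSUM62 constants
λ = 0.267, K = 0.041) and e-value `m·n·2^(−bits)`. A profile engine scores
the database against a model built from the current family, with a Gumbel
null fitted by moments on random background sequences; the pipeline runs one
Smith–Waterman round from the seeds and then profile rounds, mirroring the
usual blastp-then-HMM recursion. No seeding or SIMD heuristics are
implemented; databases here are small enough for exact search. Two
candidate-generation prefilters (shared 4-mers for protein cluster pairs,
shared 16-mers for genome ANI pairs) skip alignments that could not reach
the significance thresholds anyway; tests compare against oracle
implementations without the prefilters.

## The profile model

Profiles are per-column log₂-odds over a uniform 1/20 background with
pseudocount 0.5, scored ungapped: the shorter of profile and target slides
along the longer and the best window sum (in bits) is the score. Mixed-
length families are aligned with MAFFT first; equal-length families stack
directly. This is deliberately simpler than a full profile HMM — the
calibration rule and the fixed-point iteration are the substance here, and
the engine is pluggable — but it gives bit-scaled scores on which the
"+10 units" calibration clause is meaningful, separates true families from
decoys by hundreds of bits at the default divergence, and is exactly
reproducible.

## The synthetic halovirome

The generator plants the statistical structure the procedure assumes, with
ground truth for every stage:

- **Core cassette.** Every genome carries ORF4-, ORF6-, ORF7-, ORF8-like
  genes in canonical order on one strand, separated by uniform intergenic
  gaps (20–400 bp). Default core gene lengths 280/140/120/230 aa.
- **Marker evolution.** Each marker has a root consensus. ORF7 and ORF8
  have genus-keyed sub-consensuses (0.35 divergence from the root) and then
  evolve along one *shared* per-genus genealogy (branch rate divergence/6),
  so their trees tell the same story — the within-genus topologies estimated
  from the two genes agree to within ~10 % of the maximum Robinson–Foulds
  distance. The spike gene (ORF4) instead follows host-keyed consensuses
  (0.4 divergence), so its tree tracks the host, not the taxonomy — the
  simulated analogue of host-driven spike evolution. ORF6 and the hallmarks
  diverge per member. Member divergence defaults to 0.3; a mutated site
  always changes residue (uniform over the other 19).
- **Hallmarks.** alpha → RCRE, beta → Rep, delta → a Rep variant from a
  delta-keyed sub-consensus (so beta and delta are only separable
  phylogenetically, which is the point), gamma → polB, epsilon → none.
- **Integrase and cargo.** With probability `p_integrase` (default 0.3) a
  genome carries an integrase plus cargo genes adding ~4 kb, placed after
  the accessory genes so the integrase bounds the viral region. This plants
  the integrase–genome-length association the statistics are expected to
  find. Proviruses are only emitted for integrase-carrying genomes —
  integrated proviruses without an integrase would be undetectable by the
  stated rule and are biologically incoherent.
- **Contig classes.** Each genome becomes exactly one of: full genome with
  DTR (terminal repeat length uniform 20–100 bp), full genome with ITR,
  provirus (embedded in a decoy host contig with ≥ 2 host genes per flank),
  or a 5'/3' fragment keeping 35–85 % of the genome (fragments can lose core
  genes; whether the cassette survived is recorded in the truth table).
  Default class mix 45/15/20/20.
- **Decoys.** Six decoy protein families (8 members each) populate decoy
  host contigs and serve as the true-negative calibration set, standing in
  for unrelated cellular proteins.
- **CRISPR arrays.** Each host's spacers are exact 35 nt substrings (either
  strand) of its own viruses; every virus is targeted by exactly one host
  except a designated broad-range virus targeted by `broad_range_k` hosts
  (default 3, configurable up to the host count — the emulation of a virus
  crossing host-family boundaries). Fabricated integrated host scores put
  the true host in 91–99.5 and all others in 20–85.
- **Defaults.** 100 genomes in a 25/25/10/20/20 genus split (balanced
  enough to exercise every genus incl. clade-based calls), 8 hosts, 12
  spacers per host, 25 decoy contigs. Identical (config, seed) reproduce
  byte-identical outputs; all randomness flows through tagged substreams of
  one seed.

What the generator does *not* emulate: haloarchaeal GC content and codon
usage (codons are uniform over synonyms), sequencing error, assembly
artifacts, gene content variation beyond the planted families, and realistic
protein substitution processes (mutations are uniform swaps, not
BLOSUM-like). Passing tests therefore demonstrate that the *procedure* is
implemented correctly and behaves as designed under its assumptions — not
that it would achieve the same recall on real metagenomes, where divergence
is structured and gene callers disagree.

## Numerical and design notes

- Coordinates are 0-based half-open internally; GFF3 output converts to
  1-based inclusive.
- "≤ 4.5 kb apart" is enforced per adjacent inter-gene gap, not on the total
  cassette span (a 4-gene cassette bounded by 4.5 kb total would contradict
  ~10 kb genomes). Both the 2 kb candidate and 4.5 kb high-confidence length
  floors are parameters.
- NJ breaks Q-matrix ties by first minimum in row-major order, so
  ultrametric ties resolve by fixed taxon order; branch lengths are clamped
  at 0. Bootstrap support is attached to splits (canonicalized by the side
  not containing the lexicographically smallest leaf).
- The rank-sum test enumerates all C(n+m, n) rank assignments when
  n + m ≤ 12 without ties; otherwise a normal approximation with midranks,
  tie correction and 0.5 continuity correction. All-tied data yield p = 1
  with a note rather than a division by zero.
- On the default synthetic data the four core families are shared by every
  genome, so the gene-sharing network is near-complete and the
  degree-vs-integrase contrast is flat (the report returns p = 1 with a
  zero-variance note, and degree–length correlations are undefined). The
  degree statistics are validated on constructed networks where degrees
  vary; the planted, testable association on synthetic data is
  length ~ integrase.
- Provirus flank counting uses genes strictly outside the viral region;
  genomes are laid out margin-first so full genomes never present flanking
  genes on both sides.
- The calibration threshold uses the full family as true positives, so a
  member admitted by expansion always passes its own profile; recall loss
  can only come from genes the expansion itself missed.

## Problem sizes

Tests and the acceptance script run 100-genome simulations (≈ 125 contigs,
≈ 1,000 proteins), 100 bootstrap replicates, 1,000-replicate null
calibrations for the rank-sum test, and 10,000-case decision-rule oracles;
the full pipeline completes in well under a minute on one CPU at these
sizes, which are comfortable desk-scale stand-ins for the procedure's
behavior.
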
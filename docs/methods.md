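# Methods

This note documents the models and procedures kinfamscan implements, the
parameters that matter, what the synthetic benchmark does and does not
emulate, and the numerical choices a maintainer would want to know.

## The survey pipeline

### Identification funnel

Candidates are screened against a query family set with Smith–Waterman
local alignment (BLOSUM62; gap of length L costs `open + extend·L`,
defaults 10/1 for protein, match 2 / mismatch −3 / gap 5/2 for
nucleotide). A candidate passes at identity ≥ 0.50, where identity is
**matches / alignment columns of the optimal local hit**. The 50% rule
could equally be read over the query length; the hit-based reading
(BLASTP semantics) is the default and the denominator choice is
deliberately confined to one place in `align`. A consequence worth
knowing: unrelated proteins occasionally clear the naive screen through
short, high-identity local hits (about 15% of length-300 random decoys
in the benchmark). That is not a defect of the funnel — the subsequent
hallmark validation removes them all — but it is why a screen-then-check
design is necessary at all, and the near-miss decoys in the generator
probe exactly this boundary.

Redundancy removal links two sequences when their global alignment has
identity ≥ 0.98 and mutual coverage ≥ 0.98 (coverage of a sequence =
both-residue columns / its length), takes single-linkage clusters, and
keeps the longest member (ties to the smallest id). The 0.98/0.98
defaults are meant to collapse only near-identical database duplicates,
not paralogs; duplication partners in the benchmark diverge ~6% at the
protein level precisely so they survive this stage.

Hallmark validation requires every pattern in
`data/hallmarks.yaml` to match at least once. The packaged patterns are
operational kinase-subdomain motifs (glycine-rich ATP loop + VAIK
lysine; HRD catalytic loop; HRD..DFG core) written in PROSITE grammar.
They are deliberately not the official PROSITE entries: the real
kinase-domain entry is a profile, not a pattern, so the file is treated
as opaque, swappable config rather than transcribed ground truth.

### Subfamily classification

Signatures are strict (no mismatch tolerance): the ZIK literal, and the
MEKK/Raf consensus patterns with `x` meaning any of the 20 standard
residues. The MEKK and Raf patterns overlap (e.g. `GTPAWMAPEV` satisfies
both); precedence ZIK > MEKK > Raf resolves the overlap most-specific
first, and the `ambiguous` flag preserves the information. The kinase
domain span is operationalized as leftmost-to-rightmost hallmark match;
its midpoint in the first/last third of the protein gives the
N-terminal/C-terminal label, else central.

### pI and Mw

Net charge is the standard sum of Henderson–Hasselbalch terms over
N-terminus, C-terminus and the C/D/E/H/K/R/Y side chains. The pK set
(`data/pk_bjellqvist.yaml`) is the Bjellqvist/ExPASy set, including the
N- and C-terminal variants by terminal residue; both data files are
pinned by checksum in the tests. Charge is strictly decreasing in pH, so
the zero is unique; bisection on [0, 14] iterates until the interval
*and* the midpoint charge are both below 1e-4 — the interval condition
alone can leave a visible charge on lysine-rich sequences, while the
charge condition alone stops early on shallow curves (peptides whose
groups all sit far from the pI). Reports round to 2 decimals, matching
the display precision of the usual web tools. Mw uses average isotopic
residue masses + one water; monoisotopic masses and redox/PTM
corrections are out of scope.

### Phylogeny

Progressive MSA: pairwise global alignments give p-distances for an NJ
guide tree; profiles merge in guide-tree post-order by profile–profile
DP with sum-of-pairs BLOSUM62 column scores and a linear gap (cost =
gap_open + gap_extend). Distances on the final MSA are p-distances
(mismatches over both-residue columns) — the simplest defensible choice
where a distance correction is not prescribed; Poisson/JTT corrections
would only rescale branch lengths, not the topology claims the tests
make. NJ follows Saitou–Nei with Q = (n−2)d − r_i − r_j, joins the
Q-minimal pair (ties broken by the lexicographically smallest leaf-label
pair, which makes runs reproducible), computes branch lengths by the
rate-corrected split formula, and clamps negative estimates to zero
(counted on the tree object). Bootstrap resamples alignment columns with
replacement, rebuilds p-distance + NJ per replicate, and reports
per-edge bipartition frequency as a percentage. The conventional 1000
replicates are the pipeline default; the test suite uses 100 for the
sanity checks, which is ample for the 95%-support assertions it makes.

### Gene structure

Loci are found by exact 20-nt seeds (one per ~100 nt of cDNA, both
orientations); the chromosome/strand with most seed hits wins and ties
are flagged `ambiguous locus` rather than silently resolved — relevant
when a near-identical duplicate locus exists. Seed hits are clustered
(gap > 1.5 kb splits clusters) so a tandem duplicate on the same
chromosome cannot stretch the candidate window into two loci. Exon
chains are greedy maximal exact matches: extend until first mismatch,
re-anchor the next 20-mer at least `min_intron` (20 nt) downstream; the
chain must cover 100% of the cDNA. This is exact-match chaining, not
spliced alignment with substitutions: the procedure aligns identical
sequence pairs (the cDNA against its own locus), so mismatch tolerance
would only mask upstream errors. GT..AG conformity is checked but only
warned about. For minus-strand genes the inference runs in transcript
orientation on the reverse-complemented window and coordinates are
mapped back to the forward strand.

### Duplication

All unordered cDNA pairs are evaluated by global nucleotide alignment —
brute force is the specification at family scale. A pair is reported iff
coverage of the longer gene (both-residue columns / longer length)
> 0.8 **and** identity > 0.8, both strict. Two provably lossless
prefilters keep this fast: a length-ratio bound (matches and aligned
length cannot exceed the shorter sequence) and a score bound computed
without traceback under a reduced scoring in which every penalized
column costs |mismatch| — any alignment with identity > t and m > t·L
matches then scores above `t·(match − |mismatch|·(1−t)/t)·L`, so pairs
at or below the bound cannot qualify. Same-chromosome pairs within the
linkage window count as tandem and are merged single-linkage into one
duplication event; "tightly linked" has no standard definition, so the
window is an explicit parameter (default 25 kb, chosen to separate
adjacent planted pairs from unlinked same-chromosome genes at the
benchmark's genome scale).

### Expression

Reads map to a transcript when the read or its reverse complement is an
exact substring (strandedness is not assumed); reads shorter than 20 nt
are rejected, honoring the ≥20-nt signature convention. Multi-mapping
reads are discarded entirely — the strict reading of "uniquely aligned";
no fractional assignment. RPKM is computed exactly as printed above; ΣC
= N holds by construction and is asserted on every run. A gene is called
expressed when any tissue has C ≥ 1 — no threshold is prescribed, and
the generator's silent genes receive exactly zero reads, so one unique
read is the information-theoretic boundary; the parameter is
configurable. Ovule preference uses strict RPKM inequality between
0-DPA and 3-DPA, ties labelled `equal/NA`.

## The synthetic benchmark

The packaged profile (`data/paper_profile.yaml`) plants 78 family genes
(12 ZIK / 22 MEKK / 44 Raf) plus 200 decoys (25% near-miss), on 13
chromosomes with chromosome 6 carrying 11 genes, chromosome 10 three,
and ZIK/MEKK restricted to 10 of the 13; exon counts span 1..23 with
the ZIK layouts following the published 2/7/8-exon pattern; 12
duplication pairs (2 tandem); 60 genes expressed, with 11 Raf genes
planted higher in 0-DPA ovules and 8 higher in 3-DPA.

Generator construction, and the reasoning behind the dials:

* **Proteins.** Each subfamily has a random ancestor (450/520/600 aa
  for ZIK/MEKK/Raf) consisting of a flank pool plus a kinase block whose
  motif islands satisfy the hallmark patterns. Members point-mutate the
  ancestor at `mutation_rate = 0.25` per position, never touching
  planted motifs, and realize their own signature from the subfamily
  consensus (Raf realizations are resampled until they do not satisfy
  the higher-precedence MEKK pattern). The rate balances three
  constraints: member-to-query local identity (~0.75) must clear the
  0.50 screen; non-partner same-subfamily cDNA identity (~0.72) must
  stay below the 0.8 duplication threshold; and duplication partners
  (derived from each other at 0.06 divergence, cDNA identity ~0.96)
  must pass it while staying below the 0.98 redundancy cutoff.
* **Domain placement.** The kinase block sits N-terminally for ZIK,
  C-terminally for Raf, and at a uniformly drawn offset for MEKK.
  Because the query set emulates a multi-species query collection, the
  MEKK ancestor is realized at three placements (N/central/C);
  otherwise a member whose block sits far from the single query's block
  pays enough gap columns to dip below the 50% screen.
* **Genome.** CDS = deterministic reverse translation (one fixed codon
  per residue, `data/codons.yaml` — codon-usage realism is a non-goal;
  determinism is the point). Exons split the CDS at points ≥ 25 nt
  apart, nudged so the base starting each downstream exon differs from
  the splice donor's first base (G); with introns forced to start GT
  and end AG this makes the greedy exact-match chain unique, so the
  structure round-trip can be asserted *exactly*. Introns draw 50–300
  nt, intergenic spacers 3–8 kb, strands are random, tandem partners
  are placed adjacently and dispersed partners on different
  chromosomes.
* **Reads.** Error-free, single-end, 50 nt, sense strand; per tissue,
  30 000 reads drawn multinomially with weight RPKM × length and
  uniform positions. Planted abundances are log-uniform on [5, 500]
  RPKM; designated preference genes use a 4× ovule ratio; a 15%
  per-tissue dropout gives non-designated genes tissue-specific
  patterns. Silent genes get exactly zero reads.

What the benchmark does **not** emulate — and hence what passing tests
do not show about real data: sequencing error and quality (the mapper's
mismatch policy is never exercised), indels within gene families
(alignment handles them; the generator never produces them except via
block placement), UTRs and alternative splicing (cDNA = CDS),
paralogs at the redundancy/duplication threshold boundary (margins are
engineered to be comfortable), codon usage, GC bias, and polyploidy.
Recovery being exactly 100% at every stage is a property of these
planted margins, not a general claim about the method on noisy genomes.

## Problem sizes and runtime

The test suite runs one full benchmark pipeline (shared session
fixture, tree stage exercised separately on a reduced family of 12 to
keep the suite under ~2 minutes), 500 alignment-oracle trials, 200
random-tree NJ recoveries, 200 grid-search pI comparisons and the
duplication brute-force comparisons; the acceptance script re-runs
simulate → identify → classify → express on the full profile in about a
minute. These sizes are the package's own choices for a reproducible
desk-scale benchmark; every one of them is a config parameter.

## Known limitations

* The identity screen has no E-value model; significance of a local hit
  is not assessed (by design — the hallmark stage carries specificity).
* PROSITE profiles (as opposed to patterns) are not scored; the kinase
  domain check is a pattern stand-in behind a config file.
* `infer_exons` assumes the cDNA matches its locus exactly; a
  mismatch-tolerant spliced aligner is out of scope.
* NJ tie-breaking and the guide-tree heuristic make the MSA
  deterministic but not optimal; no iterative refinement is attempted.
* Duplication events use single-linkage over tandem pairs only;
  dispersed pairs are never merged, matching the "one event per tightly
  linked cluster" rule but leaving segmental-event inference (synteny)
  out of scope.
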
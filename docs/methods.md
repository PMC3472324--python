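# Methods

This note records the models implemented in `regulonkit`, the defaults
that matter, the design decisions taken where several constructions were
defensible, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and sequence handling

Internal coordinates are 0-based half-open on the forward strand
everywhere; GenBank input and GFF3 output use their native 1-based
inclusive convention and are converted only at the file boundary.  The
DNA alphabet is `ACGTN`: `N` is accepted and scores as background in
every scanner (a log-odds contribution of exactly 0 bits); other IUPAC
ambiguity codes are rejected at read time.  Circular genomes wrap
across the origin during upstream extraction.

Upstream regions run from at most `max_upstream_nt` (default 300 nt,
chosen to cover bacterial promoter placement while keeping scans local)
upstream of a transcription unit's lead gene, truncated at the nearest
annotated feature boundary on either strand, plus the first
`gene_prefix_nt` (default 20) bases of the gene — binding sites
frequently straddle the start codon, so the gene prefix is part of the
searchable region.  Operons are formed by joining consecutive
same-strand genes with intergenic gaps ≤ 50 nt, a conventional bacterial
heuristic; the threshold is a configuration knob, and the grouping rule
is deliberately simple because no richer information (e.g. terminator
placement) is assumed at this stage.

Gene calling on bare DNA is a deliberately naive stand-in for a real
gene finder: maximal ORFs on six frames with starts ATG/GTG/TTG and
≥ 50 codons, flagged `naive_orf_caller` in all outputs.  Start codons of
such calls (never of annotated genes) are moved to the in-frame
alternative within ±30 nt whose upstream window carries the strongest
Shine-Dalgarno match.

## PWM scoring and exact p-values

`build_pspm` turns aligned sites into per-position base probabilities
with additive smoothing `(count + c) / (n + 4c)`.  Conversion to a
scoring matrix regularizes toward the background,
`p' = (p + c·b) / (1 + c)` with `c = 0.01` by default, and scores in
log2 (bits); the base of the logarithm is a pure convention and bits
were chosen for interpretability.

The null score distribution is computed by dynamic programming over a
discretized lattice: every matrix entry is rounded to the nearest
1/1000 bit and the exact distribution of the rounded sum under the
background is obtained column by column.  The same lattice serves three
purposes — p-value→score thresholds (the smallest achievable score
whose upper-tail mass does not exceed the requested p-value, hence
conservative at the stated granularity), per-hit exact p-values, and
the hit/no-hit comparison during scanning — so threshold, scanner and
reported p-values can never disagree with one another.  Granularity is
configurable; at 1/1000 bit the rounding perturbs a width-18 motif
score by at most 0.009 bits.

Default scan cutoff is p ≤ 1e-5 per motif, with per-entry overrides
carried in the library file.  Gapped sites of the `TGTAA-N6-TGTAA` kind
are represented as full-width matrices whose spacer columns hold
background-like frequencies; no explicit gap state is modelled, which
matches what alignment-based motif builders emit for such collections.
When several source-organism site collections exist for one TF, a
combined motif is built by pooling the sites into one matrix rather
than averaging matrices — pooling keeps per-column counts meaningful
and needs no alignment of the matrices themselves.

The motif library format is MEME-minimal text with one extension: a
comment line `# cutoff_pvalue=` after each MOTIF header.  Rows off
unity by ≤ 1e-3 (e.g. from 6-decimal rounding) are renormalized on
read, with a warning when the deviation exceeds rounding noise; larger
deviations are treated as corrupt input.

## Promoter model

The promoter model is two 6-bp PWMs with a spacer-window constraint:
boxes are scanned independently at a permissive per-box p-value
(default 1e-3 — promoter boxes are weak motifs, and combined evidence
rather than single-box significance drives ranking), then every
(−35, −10) pair with a spacer of 16–18 nt becomes a complete call
scored by the sum of the box scores.  Box hits that enter no legal
pairing are reported as incomplete promoters, since a lone convincing
−10 is still useful cartographic information.  The spacer window is the
only "duration" structure retained from richer promoter HMMs; with no
defensible topology or training set for an HMM component, the two-PWM
model was chosen and its spacer constraint treated as the duration
prior.  The TSS is placed 10 nt downstream of the −10 box start
(4 nt past the hexamer), configurable.

The packaged −35/−10 site collections (Gram-positive and Gram-negative
flavours, selecting between slightly different column variability) are
synthetic assemblies around the canonical TTGACA/TATAAT consensus,
constructed for this package and labelled as such in the data files;
they are not a curated promoter compilation.  Models are rebuilt from
the site files at run time through the ordinary `build_pspm` path, so
replacing the collections re-parameterizes the predictor without code
changes.

## RBS and terminators

RBS detection scores 6-bp windows against an AGGAGG-seeded matrix in
the 4–15 nt window upstream of the start codon, reporting the best
window at ≥ 5 bits (ties broken toward the start codon).  Terminator
calling is a simplified hairpin-plus-tail scorer: stems of 4–12 bp
(Watson-Crick plus GU wobble, mismatches disallowed, GU implicitly
penalized by its low pair score), loops of 3–9 nt, hairpin score
= Σ pair scores (GC 3, AT 2, GU 1) − loop length, tail score = the
T-richness of the 8 nt past the stem weighted `1 − i/8` by distance,
and a reporting threshold of 12 on the total.  For each hairpin
interval only the best-scoring stem/loop decomposition is kept.  This
is an intentionally transparent scorer, not a thermodynamic model: no
nearest-neighbour free energies, no competing-structure analysis.

## Motif discovery

Discovery fits a ZOOPS mixture per width (6–18 by default): a sequence
either contains exactly one motif occurrence at a uniformly distributed
offset and strand, or is pure background; OOPS is available where every
sequence is known to contain a site.  EM runs to a log-likelihood
tolerance of 1e-4 with the per-sequence responsibilities computed in a
numerically shifted form.  Seeding is deterministic — EM restarts from
the most frequent exact words of each width (ties lexicographic) — so
a run is bit-reproducible without random restarts; the `rng_seed` field
exists for forward compatibility and does not currently influence the
result.  The reported site list is the hard posterior ≥ 0.5 assignment
and the reported matrix is rebuilt from those sites, so sites and
matrix agree by construction.

Cross-width ranking uses `evalue_like`, a BIC-penalized likelihood
ratio `exp(−(LLR − 1.5·w·ln N))` with `N` the total input length:
lower is stronger, wider motifs pay for their extra free parameters.
It is a surrogate for ranking within this package and is **not**
numerically comparable to MEME's E-values.  Discovered motifs are
compared to known library entries by the best mean per-column Pearson
correlation over ungapped alignments of the two matrices (both strands,
minimum 4 overlapping columns) — the mechanized version of curating
discovered motifs against experimentally verified sites.

## Homology

Protein comparison is exact Smith-Waterman with affine gaps (BLOSUM62,
open 11, extend 1: a gap of length k costs 10 + k) over the whole
proteome — no seeding heuristics, masking or composition-based
statistics, which is affordable at the scales this tool targets and
removes a whole class of approximation artifacts.  Significance uses
the analytic Karlin-Altschul form `E = K·m·n·exp(−λS)` with the gapped
BLOSUM62 parameters λ = 0.267, K = 0.041 and `n` the total residue
count of the target proteome.  These E-values approximate (not
reproduce) what a full BLAST reports; ortholog tiers are therefore
bands, not sharp claims: strong ≤ 1e-50 < moderate ≤ 1e-20 < weak
≤ 1e-5 < absent, anchored on the conventional 1e-20 "high similarity"
cutoff.  The alignment engine is Biopython's `PairwiseAligner`; its
scores are cross-checked in the tests against an independently written
affine-gap DP.

## The all-in-one flow

`mine_regulon` unions the homology pool (Ia) and the TFBS pool (Ib)
before motif refinement, and final membership (pool II) additionally
requires a refined-motif site at p ≤ 1e-5.  Union-then-gate was chosen
over intersection because the two channels fail independently (a
diverged protein may keep its site; a conserved protein may have lost
it) and the motif gate already suppresses the union's false positives;
`pool_mode="intersection"` is available.  The candidate unit is the
operon (the lead gene's upstream region), since regulation acts on
transcription units.  When the known TFBS is present its width ±2
bounds the discovery width range — the refined motif is a corrected
version of the known one, not an unrelated signal.  With fewer than
two candidate regions discovery is impossible and the known-TFBS hit is
used as the gate.  The background model for all scanning inside the
pipeline is the base composition of the target's own upstream regions,
the natural analogue of an all-intergenic-regions background.

## The synthetic genome generator

`simulate_genome` emulates exactly the structures the pipeline
consumes: a circular genome of 50 genes (defaults) in transcription
units on both strands, ~20% of non-regulon units carrying a second
gene 20 nt downstream, intergenic spacers of ~200 nt, a regulon of 8
single-gene units whose proteins diverge from a common ancestor at 0.2
substitutions/site (both in the target genome and in the "source
organism" definition), a planted 15-bp TFBS (sharp consensus with one
50/50 degenerate position, emulating a W-containing box) sampled per
site with 5% per-position mutation and placed 45 nt upstream of each
member's start, plus consensus promoter boxes (spacer 17) and an
AGGAGG RBS in every unit.  Intergenic spacers have a 190-nt floor so
that every planted site falls inside its own unit's upstream scan
window and no neighbouring unit's — the planted truth stays
unambiguous, which a precision measurement requires.  Everything is a
pure function of `rng_seed`.

What the generator does **not** emulate: realistic codon usage and GC
skew, overlapping genes, regulatory sites shared by divergently
transcribed pairs, multi-operon regulon members, pseudogenes, and
sequencing artifacts.  Passing the end-to-end benchmark therefore
demonstrates that the machinery is correct and well-calibrated on
clean planted signal, not that real-genome accuracy matches it;
scanning real genomes will face compositional biases the uniform-ish
synthetic background does not produce.

## Benchmark sizes and numerical choices

The self-checks in `scripts/acceptance.py` use problem sizes chosen to
finish in about a minute while still exercising every code path at
meaningful scale: 50 random PWMs × 3 p-values against full 4^w
enumeration (widths 4–8); 100 random (motif, 2-kb sequence) scans
against a naive per-window scorer; 1000 random 500-nt promoter scans
plus 100 planted and 100 spacer-25 constructs; EM recovery on 50 ×
200-nt sequences with a 10%-mutated planted 10-mer; 1000 short protein
pairs against an independent alignment DP; and 20 simulated genomes end
to end.  Ties and degenerate inputs are resolved deterministically
throughout (lexicographic subject ids in homology searches, proximal
window in RBS ties, first-by-position ordering of equal-score calls),
so repeated runs are byte-identical.

## Known limitations

* Promoter prediction covers the sigma70 −35/−10 architecture only;
  alternative sigma factor sites are handled as ordinary TFBS library
  motifs, not by the promoter model.
* The terminator scorer is structural, not thermodynamic, and its
  conservative threshold favours precision over recall.
* E-values approximate BLAST's statistics; counts of regulon members
  recovered at a fixed E-value cutoff can differ by a member near the
  boundary compared with other aligners.
* The discovery module reports a single best motif per width, with no
  iterative erasure for secondary motifs.
* Zeroth-order background only; dinucleotide or higher-order models are
  out of scope.
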
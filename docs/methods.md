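# Methods

This note documents the models, algorithms and numerical choices behind
the package, what the synthetic-data generators do and do not emulate,
and the problem sizes used by the automated checks.

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`.  GenBank's
1-based inclusive locations are converted on read.  Genomes are treated
as circles; rotating a genome moves the origin without changing any
biology, and a feature that comes to span the origin of a rotated copy
keeps a single interval with `end > len(seq)` (interpreted modulo the
genome length) rather than being split.  Nucleotide ambiguity codes
other than `N` are mapped to `N` on input with a warning; `N` is treated
as missing data everywhere (it breaks SSR runs, terminates repeat
extension, and is invalid for the diversity estimator).

## Quadripartite structure detection

A typical plastid genome is LSC → IRb → SSC → IRa on a circle, with IRa
the exact reverse complement of IRb.  `detect_inverted_repeats` finds the
maximal pair of exact inverted repeats by hashing k-mers (k = 20, or the
requested minimum if smaller) of the circular reverse complement,
scanning the forward sequence for shared k-mers, and extending each seed
match maximally in both directions on the circle.  Seeds landing on an
already-extended diagonal are skipped, so the big IR pair costs one
extension.  Copies are not allowed to overlap, and a pair must reach
`min_ir_len` (default 1,000 bp — long enough to ignore tRNA-scale
inverted pairs, far shorter than any real plastome IR).  Mismatch-free
matching is deliberate: assemblers emit the two IR copies of a plastome
as identical sequences, so exact matching reproduces exactly what the
assembly contains.  Ties between distinct maximal pairs are broken by
the smallest canonical rotation, with a warning.

The longer of the two inter-IR segments is labelled LSC, and all
coordinates are rotated so LSC starts at 0.  The partition invariants —
the four intervals tile the genome in order, `revcomp(IRb) == IRa`,
`len(LSC) > len(SSC)` — are asserted on every output.

Per-region GC is `100·(G+C)/(A+C+G+T)` with `N` excluded from the
denominator, the two IR copies pooled, and values reported to two
decimals.  The weighted mean of region GCs equals total GC to 1e-9
before rounding (tested).

Junction offsets follow the IRscope convention: for each of the four
junctions (JLB, JSB, JSA, JLA) the nearest tracked gene (default rps19,
rpl2, trnH, ycf1, trnN, ndhF) is reported with a signed distance —
positive for the gap between gene and junction, negative for the number
of gene bases lying inside the IR when the gene straddles the junction.

## Repeat scanning

**SSRs.**  Maximal perfect tandem repeats of 1–6 bp units, with MISA's
threshold convention: minimum 11 copies for mononucleotide motifs, 6 for
di-, 5 for tri-, 4 for tetra- and 3 for penta- and hexanucleotide
motifs.  Runs are found per unit length from the boolean array
`seq[x] == seq[x+u]`, so each maximal run is seen exactly once; a run is
assigned to the smallest unit that generates it (a poly-A run is never
reported as stacked "AA" units — the motif's minimal period must equal
the unit length).  SSRs separated by at most 100 bp (the MISA default;
the interruption threshold is configurable) merge into one compound
record.  Whether a compound counts as one SSR or as its components is an
explicit switch in `count_ssrs`, since published per-species totals are
ambiguous on this point.

**Dispersed repeats.**  Maximal exact repeat pairs of ≥ 30 bp in four
orientation classes: forward (copy2 = copy1), reverse (copy2 = reversed
copy1), complement (base-wise complement, same order) and palindromic
(reverse complement).  Each class reduces to finding maximal common
substrings between the sequence and a transformed copy (identity,
reversal, complement, reverse complement), done by k-mer seeding at the
minimum length and maximal extension, with per-diagonal deduplication.
"Longer than 30 bp" is implemented with ≥ semantics (length 30 reported).
Matching is exact (0 mismatches) by default because the original repeat
finder's mismatch setting is undocumented; exactness is reproducible.
Self-pairs and pairs whose copies overlap are excluded; pairs whose two
copies both sit inside a longer same-class pair are suppressed.  With a
partition available the scan runs on the canonical LSC+IRb+SSC segment,
which excludes IRa and therefore the genome-scale IRa/IRb pair itself.

Both scanners are validated against independent quadratic brute-force
oracles (direct per-position tandem checking; full diagonal run scans
over all alignments of the sequence with its transform) on sequences up
to 2 kb.

## Gap-aware nucleotide diversity and hotspot calling

For each alignment column, let `v` be the number of valid characters
(A/C/G/T; gaps and N are missing), `c = v(v−1)/2` the comparable pairs
and `d` the differing pairs.  Nucleotide diversity over any column
interval is the ratio of sums

    pi = ( Σ_cols d ) / ( Σ_cols c ),

the pixy-style estimator: columns with missing data contribute fewer
pairs rather than being dropped, which keeps the estimate unbiased under
missingness.  `pi` is undefined (NA) when no column has two comparable
characters.  Note the region value is a ratio of sums, *not* the mean of
window values — the tests assert this distinction and the concatenation
identity `pi[a,c) = (D1+D2)/(C1+C2)`.

Sites are classified as parsimony-informative (≥ 2 distinct valid bases
each occurring ≥ 2 times), singleton (variable but not informative),
invariant, or invalid (fewer than 2 valid characters).  Gaps are never a
fifth state.

Windows of 600 columns advance by 200 (both configurable).  A window qualifies as hypervariable when `pi > 0.01`
*and* the parsimony-informative count `> 25` — strictly, so
boundary-equal windows do not qualify.  Maximal runs of consecutive
qualifying windows merge into one region spanning from the first
window's start to the last window's end; because windows overlap,
adjacent runs can produce overlapping spans, which are merged to keep
the output disjoint.  Region statistics (length, singleton and
informative counts, pi) are recomputed column-wise on the merged span.

Regions are reported in alignment columns; `name_region` optionally
projects a region onto a chosen reference row (skipping the reference's
gap columns) and labels it by flanking/overlapping genes as
`geneL-geneR`, a single gene name when one gene covers it, or
`unplaced` when the region maps entirely into a reference gap.

## Branch-model dN/dS

Codon evolution follows Goldman–Yang (GY94) on the 61 sense codons of
the bacterial/plastid genetic code (NCBI table 11; configurable).  Rates
between codons differing at one nucleotide are
`q_ij = π_j · κ^[transition] · ω^[nonsynonymous]`, zero otherwise, with
the generator scaled so branch lengths are expected substitutions per
codon.  Equilibrium frequencies use F3x4 (positional nucleotide
frequencies multiplied, stops removed, renormalized) estimated from the
gene's alignment — the CODEML default.  The model is time-reversible;
transition matrices come from one symmetric eigendecomposition per ω
class per likelihood evaluation, reused across branches.

Likelihoods are computed by Felsenstein pruning over site patterns
(identical columns collapsed) with per-node rescaling against underflow.
Gap/ambiguous codons are missing data: their partial likelihood is 1
over all 61 states (cleandata=0 behaviour), never deleted columns.
Pruning is checked against exhaustive ancestral-state summation on 3-
and 4-taxon fixtures to 1e-10, and against the pulley principle
(rerooting invariance).

The one-ratio model (single ω) is nested in the two-ratio branch model
(separate ω on a designated foreground clade: every branch whose
descendant leaves all belong to the foreground set, including the stem).
Both models re-optimize κ, ω(s) and all branch lengths per gene by
L-BFGS-B in log space (bounds: κ ∈ [1e-3, 500], ω ∈ [1e-4, 100],
t ∈ [1e-7, 30]) from three ω starts (0.1, 0.5, 1.5) with seeded jitter
on the branch lengths; a previous fit can warm-start the optimizer,
which is how the alternative model is refit from the null (this also
guarantees the nesting inequality numerically).  The LRT statistic
`2(lnL_alt − lnL_null)` is clipped at zero and referred to χ²₁;
verdicts follow the standard classification: significant with ω_f > 1 is
positive selection, significant with ω_b < ω_f ≤ 1 is fast-evolving.

## Synthetic data

The generators are seed-deterministic and emit ground-truth records so
every scanner can be tested against planted coordinates.

* **Plastomes** — random sequence at a target GC (default 0.35, the
  plastome ballpark) in an LSC/IRb/SSC backbone with IRa written as the
  exact reverse complement of IRb; default region lengths (82 kb /
  18.5 kb / 23.7 kb) match real plastomes.  Planted SSRs, dispersed
  repeats and gene features are placed at spaced offsets inside their
  regions.  The bases flanking every planted element (and the IR copies
  themselves) are forced to mismatch the element's periodic or
  class-specific continuation, so planted elements are *exactly* maximal
  — without this, one-in-four chance extensions would shift the truth
  coordinates.
* **Alignments** — an ancestral row mutated independently per sample and
  column (uniform different base) at a background probability, elevated
  inside hotspot intervals, with i.i.d. gaps.  Defaults: 22 samples,
  150,000 columns, background 0.002, hotspot 0.03, gaps 0.01.  The
  substitutions are star-like and i.i.d., not tree-structured: adequate
  for the tree-free diversity estimator, but it under-produces
  parsimony-informative sites relative to real lineage-structured
  variation.  The hotspot probability is therefore set well above the
  real hotspot diversity so that planted hotspots clear the
  informative-sites threshold the way real (phylogenetically
  correlated) hotspots do; passing tests demonstrate correct estimator
  and merge behaviour, not realism of the variation process.
* **Codon alignments** — root codons drawn from the equilibrium
  frequencies, evolved along each branch by the GY94 transition matrix
  of that branch's ω class.  This is the oracle for the selection
  module's parameter-recovery and calibration experiments.

## Problem sizes in the automated checks

The simulation studies use sizes chosen to give stable statistics:
IR-architecture recovery on 50 plastomes with randomized region lengths
(3–6 kb LSC scale); estimator-vs-oracle comparisons on 100 random gapped
alignments (≤ 10 × 200) and 2 kb repeat sequences; ω recovery at 2,000
codons and detection power at 500 codons × 20 replicates on an 8-taxon
tree (foreground = one 4-taxon clade); null LRT calibration at 400
replicates of 300 codons on a 3-taxon tree, where the null fit uses a
single ω start and the alternative warm-starts from the null — on
null-true data the likelihood surface is well-behaved and single-start
fits agree with multi-start fits to within optimizer tolerance, while
keeping 800 optimizations affordable.  The calibration acceptance band
(5% ± 3% at α = 0.05) is roughly ±3 binomial standard errors at 400
replicates.

## Known limitations

* IR detection assumes the two IR copies are identical (true of
  assembler output, not necessarily of raw biology) and does not handle
  IR loss or isomeric SSC orientation flips.
* The repeat scanner has no mismatch tolerance by default and no
  approximate-tandem (TRF-style) scoring.
* The diversity module computes within-sample-set diversity only — no
  dxy/Fst, no haplotype statistics, no VCF input.
* The selection module implements branch models only (no site or
  branch-site models); two-ratio foreground specification is by leaf
  set, so a non-monophyletic foreground marks only the branches of its
  maximal contained clades.
* The whole-genome aligner and tree inference are out of scope:
  alignments and trees are consumed as inputs.
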
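# Methods

## Signature-gene grouping

Proteins from the selected genomes are compared all-vs-all. The external
engine is NCBI BLASTP (tabular output, E ≤ 10 retained at the search
stage, matching the pre-calculation convention of signature-gene
servers); the internal engine is a local alignment via Biopython's
`PairwiseAligner` (BLOSUM62, gap open 11 / extend 1) with Karlin–Altschul
statistics (gapped constants λ = 0.267, K = 0.041, search space
m·n = qlen·slen), chosen to match BLASTP defaults so that E-value
cut-offs transfer between engines. Self-hits are excluded; one HSP (the
first reported, i.e. best) is kept per ordered pair.

Filtering applies a user E-value cut-off (inclusive, ≤) and an alignment
coverage cut-off (inclusive, ≥), where coverage = 100·L/((qlen+slen)/2)
with L the alignment length in columns (gaps included). Among surviving
hits, the *best hit* per (query gene, subject genome) is kept: lowest
E-value, ties broken by higher bit score, then lexicographic subject id.
Best hits are directional, not reciprocal-best: grouping is by connected
components (single linkage) over the undirected graph of qualifying
hits, the most inclusive reading of "shared amongst multiple genomes".
Paralogs from one genome may co-occur in a group; a component whose
members all come from one genome is discarded (a signature gene must
span ≥ 2 genomes). Group ids are assigned in order of each component's
smallest member gene id; output is sorted by genome span, then id, so
grouping is invariant to hit order.

## Consensus and conserved regions

Group member proteins are aligned with MAFFT (`--auto`, default
settings; the aligner executable is configurable), then back-translated:
each aligned residue is replaced by the gene's own codon and each gap by
`---`. The terminal stop codon is trimmed before back-translation, so
each alignment row ungaps exactly to the protein-coding part of the CDS.
Designing on this alignment rather than on a codon-usage consensus is
what guarantees that accepted primers match every member exactly.

The consensus at a 100 % identity threshold maps each column to the
minimal IUPAC code covering all observed bases; a column containing any
gap becomes `-` (regions containing gaps are excluded from design
anyway, and per-column propagation keeps the exclusion rule local and
testable). Columns holding input ambiguity codes (e.g. N) contribute
their whole base set and can never be conserved. A column is *conserved*
iff all members carry the same plain base.

Conserved regions: for each conserved column *i*, the next 19 columns
are scanned; if further conserved columns exist there, the span from *i*
to the furthest such column *j*, extended by 5 columns on each side, is
a candidate region. This yields unclipped lengths of 12–30 columns
(minimum 2-base span + 10 flank; maximum 20 + 10). The scan repeats at
every conserved base and identical spans are deduplicated; overlapping
regions are all kept, since uniqueness is enforced later at the primer
sequence level. Flanks are clipped at the consensus termini, and a
clipped region is kept only if it still reaches the configured minimum
primer length (default 10).

## Primer properties

Candidates are all windows of length 10–28 (configurable) sliding one
base at a time within each region; reverse candidates carry the reverse
complement of the window, with coordinates always kept on the consensus.

Degenerate sequences are handled conservatively throughout:

- **degeneracy** — product of per-position IUPAC code sizes;
- **GC %** — expectation over the pool (S counts 1, R counts ½, …);
- **GC clamp** — count of *guaranteed* G/C codes (G, C, S) among the
  five 3'-terminal bases; the screen passes clamp ≤ 3 by default (a
  minimum is configurable and 0 by default);
- **Tm** — reported as (min, max, mid): the pool is resolved to its
  weakest (A/T-preferring) and strongest (G/C-preferring)
  disambiguations and the formula evaluated at both. Three estimators:
  Wallace 2(A+T)+4(G+C) below 14 nt and 64.9 + 41(G+C−16.4)/N above;
  the conventional salt-adjusted forms (short: basic −16.6 log₁₀ 0.05 +
  16.6 log₁₀[Na⁺]; long: 81.5 + 16.6 log₁₀[Na⁺] + 0.41·GC% − 675/N);
  and the unified nearest-neighbor model (1998 parameter set, shipped
  as `data/nn_unified_1998.tsv` with ΔH, ΔS and ΔG₃₇ per stack plus
  terminal initiation terms), Tm(K) = 1000·ΔH/(ΔS + R ln(C_T/4)) with
  R = 1.987 cal mol⁻¹ K⁻¹, corrected by +16.6 log₁₀[Na⁺]. Defaults:
  [Na⁺] = 0.05 M, C_T = 2.5×10⁻⁷ M.
- **3' stability** — NN ΔG₃₇ summed over the four stacks of the last
  five bases, most stable disambiguation (dynamic programme over
  per-position base choices); the floor is −9 kcal/mol and both primers
  of a pair must satisfy it (the published rule names pair acceptance,
  so it is enforced on both).
- **complementarity** — "can-pair" semantics: two codes pair if any
  disambiguation pair is Watson–Crick. Self-/cross-dimer runs are the
  longest consecutive pairable stretch over all ungapped offsets of one
  sequence against the other read 3'→5'; hairpins additionally require
  a loop of ≥ 3 nt (the physical minimum; unstated in the published
  rule set). Runs must stay < 5. A *minimum ΔG* is reported as the NN
  ΔG₃₇ of the most stable stretch found (self-dimer or hairpin stem)
  but is not filtered on, since the published rule set names the
  quantity without defining a threshold.

## Pairing

Eligible pairs have the forward window strictly upstream of the reverse
window, a consensus product size (reverse stop − forward start + 1)
within range, both 3' ΔG values at or above the floor, and a cross-dimer
run within the limit. Ranking is by |ΔTm| (nearest-neighbor mid by
default), ties by smaller degeneracy product, then coordinates — a total
deterministic order. The report is truncated to the top 100 pairs by
default (configurable), with the number of eligible combinations logged;
because the ranking depends only on cheap per-candidate quantities, the
costly screens are evaluated lazily down the ranked order, which yields
output identical to exhaustive screening.

Every reported pair is checked in silico against every alignment member:
IUPAC-aware matching of the forward primer at its consensus columns and
of the reverse primer's complement at its columns, plus the
member-specific (ungapped) amplicon length. For a 100 %-identity
consensus this check must report zero mismatches; the test suite and the
acceptance script verify this property on dozens of simulated families.

## Synthetic genome sets

The simulator emulates the intended use case: several small (~40 kb by
default) annotated dsDNA phage genomes, each carrying one ortholog of
every planted gene family (default 6 families of 300 aa at 60 %
pairwise amino-acid identity — the regime of conserved genes among
related phage genera), on alternating strands with random intergenic
DNA. Orthologs descend independently from a random ancestor; a residue
mutates per branch with probability p = 1 − √(target identity)
(substitutions uniform over the other 19 residues), giving expected
pairwise identity (1−p)² plus a small coincidence term, and synonymous
codon swaps occur at the same per-branch rate so nucleotide divergence
tracks protein divergence. A manifest records the planted membership as
the truth set. Everything derives from one integer seed and outputs are
byte-identical across runs.

What the simulator does not emulate: real gene-length variation, indels
within genes, genome rearrangement, mobile elements, codon-usage bias,
or annotation errors. Passing the recovery and grouping tests therefore
shows correctness of the algorithms under clean orthology, not
robustness to noisy annotation.

Problem sizes used by the test suite and acceptance script: grouping is
exercised on the default 4-genome/6-family sets (10 seeds); the primer
recovery guarantee on 3-genome single-family sets of 100-aa genes at
90 % amino-acid identity (50 seeds in the tests, 20 in the script) —
identity high enough that conserved regions, and hence primer pairs,
exist in every replicate, matching the conserved-marker use case.

## Numerical and design choices

- Translation uses the bacterial/phage code (table 11); terminal stops
  are dropped, internal stops tolerated with a warning (annotations
  vary in the wild). Coordinates are 1-based inclusive in all files and
  reports, 0-based half-open internally.
- Cut-off comparisons are inclusive on both E-value and coverage.
- The case-study defaults E ≤ 10⁻³ and coverage ≥ 10 % are the
  documented CLI defaults.
- Primer windows of both orientations are enumerated per region;
  a forward and a reverse window may not overlap.
- Exit codes: 0 success, 2 usage error, 1 runtime error.

## Known limitations

- No genome-wide specificity screening (e-PCR) of candidate pairs
  against non-target genomes.
- No mismatch/dangling-end nearest-neighbor corrections and no divalent
  cation salt correction; Tm values are standard first-order estimates.
- The external aligner is run with default settings; no alignment
  trimming or masking is applied before consensus building.
- Reproducing the published T7-like counts requires the exact annotation
  versions of the eight genomes; newer RefSeq annotation revisions can
  shift group counts slightly, which is why the group report lists the
  per-group membership for inspection.
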
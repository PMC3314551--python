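# phisigns

Signature-gene identification in phage genomes and degenerate PCR primer
design.

Phages have no universally conserved gene, so studies of uncultured phage
communities rely on *signature genes*: homologous genes conserved within a
group of related phages (e.g. the DNA polymerase of T7-like podophages, or
*g20*/*g23* of T4-like myophages) that can be PCR-amplified from
environmental samples with degenerate primers. `phisigns` automates the
whole path from annotated genomes to ranked primer pairs:

1. **Identify.** All-vs-all BLASTP of every protein in the selected
   genomes; hits are filtered by E-value (≤ *E*) and alignment coverage
   (100·L/((q+s)/2) ≥ *c* %), reduced to the best hit per (query gene,
   subject genome), and clustered into connected components. Components
   spanning ≥ 2 genomes are the signature gene groups.
2. **Design.** The proteins of a group are aligned (MAFFT, default
   settings) and back-translated codon-by-codon into their *original*
   nucleotide sequences, so an IUPAC consensus at a 100 % identity
   threshold represents every member exactly. Conserved regions —
   runs anchored by ≥ 2 invariant bases within 19 columns of each other,
   extended by 5-base flanks, gap-free, 12–30 nt — are enumerated into
   candidate primers (10–28 nt sliding windows) and screened on
   degeneracy (∏ per-base code sizes), GC content, GC clamp (≤ 3
   guaranteed G/C among the last five 3' bases), melting temperature
   (Wallace/Marmur basic, salt-adjusted, and unified nearest-neighbor
   Tm = ΔH·10³/(ΔS + R ln(C/4)) − 273.15 + 16.6 log₁₀[Na⁺]), 3'-end
   stability (NN ΔG₃₇ of the last five bases ≥ −9 kcal/mol), and
   self-dimer/hairpin complementarity (< 5 consecutive pairable bases).
   Forward/reverse candidates are paired by minimising ΔTm subject to
   product-size and cross-dimer constraints.

Because primers come from the consensus of the actual member sequences
(not a codon-usage model), every emitted pair matches every member gene
with zero mismatches under IUPAC semantics — the package verifies this
*in silico* for each reported pair.

## Worked example

```sh
phisigns simulate --genomes 3 --families 2 --identity 0.9 \
    --genome-len 3000 --gene-len 100 --seed 11 --out demo/sim
phisigns identify --genomes demo/sim --evalue 1e-3 --coverage 10 --out demo/ident
phisigns design --genomes demo/sim --group SG001 --out demo/primers
```

prints

```
3 genomes, 2 planted families -> demo/sim
2 signature gene groups -> demo/ident/groups.tsv
100 primer pairs (of 6351993) -> demo/primers/primers.tsv
```

The simulator plants two homologous gene families (one ortholog per
genome, ~90 % amino-acid identity) in three 3-kb genomes; `identify`
recovers exactly those two families as groups SG001–SG002; `design`
aligns group SG001, extracts conserved regions from its consensus and
reports the 100 best-ranked primer pairs (of ~6.4 M ΔTm-eligible
combinations). The first line of `primers.tsv`,

```
rank  fwd_seq       fwd_start ... rev_seq        ... product_size  delta_tm  cross_dimer_run
1     TAGAGCCCTAGA  21        ... GTCRKRGTACATA  ... 112           0.00      4
```

gives, for each primer of the top pair: position on the consensus,
length, degeneracy, GC %, GC clamp, the three Tm estimates as
min/mid/max over the degenerate pool, 3' ΔG, and the self-dimer/hairpin
run lengths, followed by the consensus product size, the pair's ΔTm in
°C, and its cross-dimer run.

To reproduce the published T7-like case study, download the eight core
T7-like genomes from NCBI (accessions listed in
`tests/test_acceptance.py`) into `data/t7_genomes/` and run `identify`
at `--evalue 1e-3 --coverage 10`: the group table contains 58 signature
genes (24 spanning all eight genomes), and designing on the
primase/helicase group yields the published degenerate pair
5'-ACHGARGGYGARATHG-3' / 5'-CVCCTTGYTGRTTDC-3' around an ~838 bp
product.

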
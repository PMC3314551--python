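"""Synthetic phage genome sets with planted homologous gene families.

The generator emulates the situation the pipeline is built for: several
small (~40 kb) double-stranded DNA phage genomes, each carrying one
ortholog of every planted gene family, diverged to a target amino-acid
identity, embedded in random intergenic DNA on alternating strands. The
manifest records the planted family membership — the truth set against
which grouping is evaluated.

Divergence model: each ortholog descends independently from a random
ancestral protein; a site mutates on a branch with probability
p = 1 - sqrt(target identity), substitutions uniform over the other 19
residues, so the expected pairwise identity between two orthologs is
(1-p)^2 plus a small coincidence term. Codons mutate synonymously at the
same per-branch rate, so nucleotide identity tracks amino-acid identity
the way purifying selection would leave it.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

from phisigns.genome_io import (
    DEFAULT_TRANSLATION_TABLE,
    GeneRecord,
    PhageGenome,
    genbank_record,
    reverse_complement,
    translate,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_TABLE = unambiguous_dna_by_id[DEFAULT_TRANSLATION_TABLE]
# aa -> sorted list of codons, stop codons excluded
CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    CODONS_FOR.setdefault(aa, []).append(codon)
STOP_CODON = "TAA"


@dataclass
class PlantedSet:
    """Truth record for one generated genome set."""
    genomes: list[PhageGenome]
    genes: dict[str, list[GeneRecord]]       # genome_id -> genes
    families: dict[str, list[str]] = field(default_factory=dict)  # family_id -> gene ids
    paths: dict[str, Path] = field(default_factory=dict)          # genome_id -> GenBank path

    @property
    def all_genes(self) -> list[GeneRecord]:
        return [g for gs in self.genes.values() for g in gs]

    def family_genes(self, family_id: str) -> list[GeneRecord]:
        wanted = set(self.families[family_id])
        return [g for g in self.all_genes if g.gene_id in wanted]


def _random_protein(rng, length: int) -> str:
    aas = rng.choice(list(AA_ALPHABET), size=length - 1)
    return "M" + "".join(aas)


def _mutate_protein(rng, protein: str, p: float) -> str:
    out = list(protein)
    for i in range(1, len(out)):  # keep the start Met
        if rng.random() < p:
            choices = [a for a in AA_ALPHABET if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _encode(rng, protein: str, ancestor_codons: list[str] | None, p_syn: float) -> list[str]:
    """Codons for *protein*; unchanged residues keep the ancestral codon except
    for synonymous swaps at rate p_syn."""
    codons = []
    for i, aa in enumerate(protein):
        anc = ancestor_codons[i] if ancestor_codons else None
        if anc is not None and translate(anc) == aa:
            if rng.random() < p_syn and len(CODONS_FOR[aa]) > 1:
                alts = [c for c in CODONS_FOR[aa] if c != anc]
                codons.append(alts[rng.integers(len(alts))])
            else:
                codons.append(anc)
        else:
            opts = CODONS_FOR[aa]
            codons.append(opts[rng.integers(len(opts))])
    return codons


def generate_phage_set(n_genomes: int = 4, n_families: int = 6, aa_identity: float = 0.6,
                       genome_len: int = 40000, gene_len_aa: int = 300,
                       seed: int = 42, out_dir=None, prefix: str = "PHG") -> PlantedSet:
    """Generate a reproducible set of annotated genomes with planted families.

    When *out_dir* is given, one GenBank file per genome plus a manifest
    TSV (family_id, genome_id, gene_id) are written there; outputs are
    byte-identical for a fixed seed.
    """
    if not (0 < aa_identity <= 1):
        raise ValueError("aa_identity must be in (0, 1]")
    if n_families < 1 or n_genomes < 1:
        raise ValueError("need at least one family and one genome")
    gene_nt = 3 * gene_len_aa + 3
    spacer = 60
    needed = n_families * (gene_nt + spacer) + spacer
    if needed > genome_len:
        raise ValueError(
            f"{n_families} genes of {gene_nt} nt do not fit in genome_len {genome_len}")
    rng = np.random.default_rng(seed)
    p = 1.0 - math.sqrt(aa_identity)

    ancestors = []
    for _ in range(n_families):
        prot = _random_protein(rng, gene_len_aa)
        ancestors.append((prot, _encode(rng, prot, None, 0.0)))

    genomes: list[PhageGenome] = []
    genes: dict[str, list[GeneRecord]] = {}
    families: dict[str, list[str]] = {f"F{k + 1}": [] for k in range(n_families)}
    slack = genome_len - n_families * gene_nt
    for gi in range(n_genomes):
        genome_id = f"{prefix}{gi + 1:02d}"
        # gene start offsets: evenly spread the slack, jittered
        gaps = rng.integers(spacer, max(spacer + 1, slack // (n_families + 1)), size=n_families + 1)
        seq_parts: list[str] = []
        pos = 0
        genome_genes: list[GeneRecord] = []
        for k in range(n_families):
            inter = "".join(rng.choice(list("ACGT"), size=int(gaps[k])))
            seq_parts.append(inter)
            pos += len(inter)
            anc_prot, anc_codons = ancestors[k]
            prot = _mutate_protein(rng, anc_prot, p) if aa_identity < 1 else anc_prot
            cds = "".join(_encode(rng, prot, anc_codons, p)) + STOP_CODON
            strand = "+" if k % 2 == 0 else "-"
            genomic = cds if strand == "+" else reverse_complement(cds)
            start, stop = pos + 1, pos + len(cds)
            seq_parts.append(genomic)
            pos += len(cds)
            gene_id = f"{genome_id}_g{k + 1}"
            genome_genes.append(GeneRecord(
                gene_id=gene_id, genome_id=genome_id, start=start, stop=stop,
                strand=strand, nt_seq=cds, aa_seq=prot,
                annotation=f"planted family F{k + 1} protein"))
            families[f"F{k + 1}"].append(gene_id)
        tail_len = genome_len - pos
        if tail_len > 0:
            seq_parts.append("".join(rng.choice(list("ACGT"), size=tail_len)))
        genome = PhageGenome(genome_id=genome_id, name=f"Synthetic phage {genome_id}",
                             sequence="".join(seq_parts))
        genomes.append(genome)
        genes[genome_id] = genome_genes

    result = PlantedSet(genomes=genomes, genes=genes, families=families)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for genome in genomes:
            path = out_dir / f"{genome.genome_id}.gbk"
            SeqIO.write([genbank_record(genome, genes[genome.genome_id])], str(path), "genbank")
            result.paths[genome.genome_id] = path
        with open(out_dir / "manifest.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["family_id", "genome_id", "gene_id"])
            for fam in sorted(families, key=lambda f: int(f[1:])):
                for gid in families[fam]:
                    genome_id = gid.rsplit("_", 1)[0]
                    w.writerow([fam, genome_id, gid])
    return result
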
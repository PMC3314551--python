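"""All-vs-all protein comparison, hit filtering, and signature-gene grouping.

A signature gene group is a connected component of the graph whose edges
are the best qualifying pairwise protein hits between genes of the
selected genomes, restricted to components spanning at least two
genomes. Hits come from the external BLASTP executable when available,
from a local Smith-Waterman search otherwise, or from a user-supplied
BLAST tabular file.
"""

from __future__ import annotations

import csv
import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from phisigns.genome_io import GeneRecord, write_fasta

log = logging.getLogger("phisigns")

# gapped Karlin-Altschul constants for BLOSUM62, gap open 11 / extend 1,
# matching the external engine's defaults so E-value cut-offs transfer
KA_LAMBDA = 0.267
KA_K = 0.041

PRECALC_EVALUE = 10.0  # widest E-value retained at the all-vs-all stage


@dataclass(frozen=True)
class PairwiseHit:
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    aln_len: int
    qlen: int
    slen: int


@dataclass
class SignatureGeneGroup:
    group_id: str
    members: list[str]           # gene ids, sorted
    genome_span: int
    annotations: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def alignment_coverage(hit: PairwiseHit) -> float:
    """Alignment length as a percentage of the mean query/subject length."""
    if hit.qlen <= 0 or hit.slen <= 0:
        raise ValueError("query/subject lengths must be positive")
    return 100.0 * hit.aln_len / ((hit.qlen + hit.slen) / 2.0)


# --- hit computation ---------------------------------------------------------

def compute_pairwise_hits(proteins: list[GeneRecord], engine: str = "auto",
                          evalue_max: float = PRECALC_EVALUE) -> list[PairwiseHit]:
    """All-vs-all protein hits among *proteins* at E <= evalue_max.

    engine="external" shells out to blastp; engine="internal" runs a local
    Smith-Waterman (BLOSUM62, open 11/extend 1) with Karlin-Altschul
    E-values; "auto" prefers the external tool. Self-hits (query ==
    subject) are excluded; both directions of each pair are reported.
    """
    genomes = {p.genome_id for p in proteins}
    if len(genomes) < 2:
        raise ValueError("need proteins from at least 2 genomes")
    if engine == "auto":
        engine = "external" if shutil.which("blastp") else "internal"
    if engine == "external":
        return _blastp_hits(proteins, evalue_max)
    if engine == "internal":
        return _internal_hits(proteins, evalue_max)
    raise ValueError(f"unknown engine {engine!r}")


def _blastp_hits(proteins: list[GeneRecord], evalue_max: float) -> list[PairwiseHit]:
    for exe in ("makeblastdb", "blastp"):
        if shutil.which(exe) is None:
            raise RuntimeError(
                f"external search engine not found: {exe!r} is not on PATH "
                "(install NCBI BLAST+ or use engine='internal')")
    lengths = {p.gene_id: len(p.aa_seq) for p in proteins}
    with tempfile.TemporaryDirectory(prefix="phisigns_blast_") as tmp:
        faa = Path(tmp) / "proteins.faa"
        write_fasta([(p.gene_id, p.aa_seq) for p in proteins], faa)
        subprocess.run(["makeblastdb", "-in", str(faa), "-dbtype", "prot"],
                       check=True, capture_output=True)
        out = Path(tmp) / "hits.tsv"
        subprocess.run(
            ["blastp", "-query", str(faa), "-db", str(faa), "-out", str(out),
             "-evalue", str(evalue_max), "-outfmt",
             "6 qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore qlen slen"],
            check=True, capture_output=True)
        return parse_blast_tabular(out, lengths)


def parse_blast_tabular(path, lengths: dict[str, int] | None = None) -> list[PairwiseHit]:
    """Parse 12-column BLAST tabular output; qlen/slen read from columns 13-14
    when present, otherwise taken from the *lengths* mapping."""
    hits: list[PairwiseHit] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path} line {lineno}: expected >=12 tab-separated columns")
            q, s = f[0], f[1]
            if q == s:
                continue
            key = (q, s)
            if key in seen:  # keep only the best (first-reported) HSP per pair
                continue
            seen.add(key)
            if len(f) >= 14:
                qlen, slen = int(f[12]), int(f[13])
            elif lengths is not None and q in lengths and s in lengths:
                qlen, slen = lengths[q], lengths[s]
            else:
                raise ValueError(
                    f"{path} line {lineno}: no qlen/slen columns and no gene records for {q}/{s}")
            hits.append(PairwiseHit(query_id=q, subject_id=s, evalue=float(f[10]),
                                    bitscore=float(f[11]), aln_len=int(f[3]),
                                    qlen=qlen, slen=slen))
    return hits


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _aligner = a
    return _aligner


def _internal_hits(proteins: list[GeneRecord], evalue_max: float) -> list[PairwiseHit]:
    aligner = _get_aligner()
    hits: list[PairwiseHit] = []
    items = sorted(proteins, key=lambda p: p.gene_id)
    for i, p in enumerate(items):
        for q in items[i + 1:]:
            if p.gene_id == q.gene_id:
                continue
            alns = aligner.align(p.aa_seq, q.aa_seq)
            if len(p.aa_seq) == 0 or len(q.aa_seq) == 0 or alns.score <= 0:
                continue
            aln = alns[0]
            aln_len = aln.length  # columns in the local alignment, gaps included
            score = alns.score
            m, n = len(p.aa_seq), len(q.aa_seq)
            evalue = KA_K * m * n * math.exp(-KA_LAMBDA * score)
            bitscore = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)
            if evalue > evalue_max:
                continue
            hits.append(PairwiseHit(p.gene_id, q.gene_id, evalue, bitscore, aln_len, m, n))
            hits.append(PairwiseHit(q.gene_id, p.gene_id, evalue, bitscore, aln_len, n, m))
    return hits


# --- filtering and grouping --------------------------------------------------

def select_best_hits(hits: list[PairwiseHit], evalue_cut: float, coverage_cut: float,
                     genome_of: dict[str, str]) -> list[PairwiseHit]:
    """Apply E-value (<=) and coverage (>=) cut-offs, then keep for each
    (query gene, subject genome) only the best surviving hit: lowest
    E-value, ties broken by higher bit score, then lexicographic subject id.
    """
    if evalue_cut < 0 or coverage_cut < 0:
        raise ValueError("cut-offs must be >= 0")
    best: dict[tuple[str, str], PairwiseHit] = {}
    for h in sorted(hits, key=lambda h: (h.query_id, h.evalue, -h.bitscore, h.subject_id)):
        if h.evalue > evalue_cut or alignment_coverage(h) < coverage_cut:
            continue
        key = (h.query_id, genome_of[h.subject_id])
        if key not in best:
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.query_id, h.subject_id))


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_groups(filtered_hits: list[PairwiseHit], genes: list[GeneRecord]) -> list[SignatureGeneGroup]:
    """Signature gene groups: connected components over qualifying hits,
    restricted to components spanning >= 2 genomes.

    Group ids are assigned in order of each component's smallest member
    gene id; the returned list is sorted by genome span (descending),
    then group id.
    """
    by_id = {g.gene_id: g for g in genes}
    for h in filtered_hits:
        for gid in (h.query_id, h.subject_id):
            if gid not in by_id:
                raise KeyError(f"hit references unknown gene {gid!r}")
    uf = _UnionFind()
    for h in filtered_hits:
        uf.union(h.query_id, h.subject_id)
    components: dict[str, set[str]] = {}
    for h in filtered_hits:
        for gid in (h.query_id, h.subject_id):
            components.setdefault(uf.find(gid), set()).add(gid)
    groups: list[SignatureGeneGroup] = []
    ordered = sorted(components.values(), key=lambda mem: min(mem))
    n = 0
    for members in ordered:
        span = len({by_id[m].genome_id for m in members})
        if span < 2:
            continue
        n += 1
        annotations = sorted({by_id[m].annotation for m in members if by_id[m].annotation})
        groups.append(SignatureGeneGroup(group_id=f"SG{n:03d}", members=sorted(members),
                                         genome_span=span, annotations=annotations))
    groups.sort(key=lambda g: (-g.genome_span, g.group_id))
    return groups


def write_group_report(groups: list[SignatureGeneGroup], path) -> None:
    """Tab-delimited signature-gene group report (the downloadable list)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["group_id", "genome_span", "n_members", "member_gene_ids", "annotations"])
        for g in groups:
            w.writerow([g.group_id, g.genome_span, len(g.members),
                        ",".join(g.members), "; ".join(g.annotations)])
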
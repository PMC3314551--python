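"""Codon-aware alignment, IUPAC consensus, and conserved-region extraction.

The protein sequences of a signature gene group are aligned with an
external multiple aligner, then back-translated: each aligned residue is
replaced by its original codon and each gap by '---'. Designing on the
consensus of this nucleotide alignment (rather than on a codon-usage
model) guarantees that primers passing the screens match every member
sequence exactly under IUPAC semantics.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO, SeqIO

from phisigns.genome_io import GeneRecord, translate, write_fasta
from phisigns.iupac import GAP, disambiguation_set, minimal_code

log = logging.getLogger("phisigns")


@dataclass
class CodonAlignment:
    member_ids: list[str]
    rows: list[str]          # equal-length aligned nucleotide strings, gap '-'
    source: str = "auto"     # {auto, user}

    def __post_init__(self):
        if len(self.member_ids) != len(self.rows):
            raise ValueError("member_ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, member_id: str) -> str:
        return self.rows[self.member_ids.index(member_id)]


@dataclass
class ConsensusSequence:
    consensus: str                # IUPAC codes and '-'
    conserved_mask: list[bool]    # True iff column is a single plain base

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class ConservedRegion:
    region_id: str
    start: int   # 1-based inclusive consensus coordinates
    stop: int
    seq: str

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


# --- alignment ---------------------------------------------------------------

def back_translate(aligned_aa: dict[str, str], genes: list[GeneRecord]) -> CodonAlignment:
    """Convert an aligned protein dict {gene_id: aligned aa row} to a codon
    alignment using each gene's own codons; protein gaps become '---'."""
    by_id = {g.gene_id: g for g in genes}
    member_ids = sorted(aligned_aa)
    rows = []
    for gid in member_ids:
        gene = by_id[gid]
        codons = [gene.coding_seq[i:i + 3] for i in range(0, len(gene.coding_seq), 3)]
        out, k = [], 0
        for ch in aligned_aa[gid]:
            if ch == GAP:
                out.append("---")
            else:
                if k >= len(codons):
                    raise ValueError(f"gene {gid}: aligned protein longer than its codons")
                out.append(codons[k])
                k += 1
        if k != len(codons):
            raise ValueError(f"gene {gid}: aligned protein does not consume all codons")
        rows.append("".join(out))
    return CodonAlignment(member_ids=member_ids, rows=rows, source="auto")


def align_group(genes: list[GeneRecord], aligner: str = "mafft") -> CodonAlignment:
    """Align the group's proteins with an external aligner (default settings)
    and back-translate to a codon-aware nucleotide alignment."""
    if len(genes) < 2:
        raise ValueError("alignment needs at least 2 genes")
    for g in genes:
        if translate(g.coding_seq) != g.aa_seq:
            raise ValueError(f"gene {g.gene_id}: nt_seq does not translate to aa_seq")
    if shutil.which(aligner) is None:
        raise RuntimeError(f"multiple aligner not found: {aligner!r} is not on PATH")
    with tempfile.TemporaryDirectory(prefix="phisigns_aln_") as tmp:
        faa = Path(tmp) / "group.faa"
        write_fasta([(g.gene_id, g.aa_seq) for g in genes], faa)
        res = subprocess.run([aligner, "--auto", "--quiet", str(faa)],
                             capture_output=True, text=True, check=True)
        aligned = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(_as_handle(res.stdout), "fasta")}
    missing = {g.gene_id for g in genes} - set(aligned)
    if missing:
        raise RuntimeError(f"aligner dropped sequences: {sorted(missing)}")
    return back_translate(aligned, genes)


def _as_handle(text: str):
    import io
    return io.StringIO(text)


def load_user_alignment(path, expected_members: list[str] | None = None) -> CodonAlignment:
    """Load a user-curated nucleotide alignment (aligned FASTA or CLUSTAL).

    Rows are accepted verbatim; member ids are matched by sequence name
    against *expected_members* when given.
    """
    path = Path(path)
    text = path.read_text()
    fmt = "clustal" if text.lstrip().upper().startswith(("CLUSTAL", "MUSCLE")) else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse as {fmt} alignment ({exc})") from exc
    member_ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper() for rec in aln]
    if len({len(r) for r in rows}) > 1:
        raise ValueError(f"{path}: alignment rows have unequal lengths")
    if expected_members is not None:
        unknown = sorted(set(member_ids) - set(expected_members))
        if unknown:
            raise ValueError(f"{path}: unknown member names: {unknown}")
    order = sorted(range(len(member_ids)), key=lambda i: member_ids[i])
    return CodonAlignment(member_ids=[member_ids[i] for i in order],
                          rows=[rows[i] for i in order], source="user")


def write_alignment(aln: CodonAlignment, fasta_path=None, clustal_path=None) -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=mid, description="") for mid, row in zip(aln.member_ids, aln.rows)])
    if fasta_path is not None:
        AlignIO.write(msa, str(fasta_path), "fasta")
    if clustal_path is not None:
        AlignIO.write(msa, str(clustal_path), "clustal")


# --- consensus and regions ---------------------------------------------------

def iupac_consensus(alignment: CodonAlignment) -> ConsensusSequence:
    """Per-column IUPAC consensus at a 100% identity threshold.

    A column containing any gap becomes '-'. Otherwise the column's code
    is the minimal IUPAC code covering every observed base (ambiguous
    input codes contribute their whole disambiguation set, so a column
    holding an N can never be conserved). A column is conserved iff all
    rows agree on one plain base.
    """
    if not alignment.rows:
        raise ValueError("empty alignment")
    cons, mask = [], []
    for col in zip(*alignment.rows):
        if GAP in col:
            cons.append(GAP)
            mask.append(False)
            continue
        code = minimal_code(col)
        cons.append(code)
        mask.append(len(disambiguation_set(code)) == 1)
    return ConsensusSequence(consensus="".join(cons), conserved_mask=mask)


def extract_conserved_regions(cons: ConsensusSequence, scan_window: int = 19,
                              flank: int = 5, min_keep: int = 10) -> list[ConservedRegion]:
    """Extract primer-eligible conserved regions from the consensus.

    For each conserved base at column i, the next *scan_window* columns are
    scanned for further conserved bases; if any exist, the span from i to
    the furthest such base j, extended by *flank* bases on each side
    (clipped at the consensus termini), is a candidate region. Regions
    containing a gap column are excluded; identical (start, stop) spans
    are deduplicated. Unclipped regions are 12-30 columns long; clipped
    ones are kept only if at least *min_keep* long.
    """
    s = cons.consensus
    L = len(s)
    conserved = [i for i, f in enumerate(cons.conserved_mask) if f]
    conserved_set = set(conserved)
    spans: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for i in conserved:
        js = [j for j in range(i + 1, min(L, i + scan_window + 1)) if j in conserved_set]
        if not js:
            continue
        j = js[-1]
        a, b = max(0, i - flank), min(L - 1, j + flank)
        if (a, b) in seen:
            continue
        seen.add((a, b))
        if GAP in s[a:b + 1]:
            continue
        clipped = (i - flank < 0) or (j + flank > L - 1)
        if clipped and (b - a + 1) < min_keep:
            continue
        spans.append((a, b))
    spans.sort()
    return [ConservedRegion(region_id=f"R{k + 1:03d}", start=a + 1, stop=b + 1, seq=s[a:b + 1])
            for k, (a, b) in enumerate(spans)]
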
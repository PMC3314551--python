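"""Reading annotated phage genomes, CDS translation, and FASTA/TSV output.

Genomes arrive either as GenBank flat files with CDS features or as a
plain FASTA genome plus a tab-separated gene table (gene_id, start,
stop, strand, annotation). Coordinates are 1-based inclusive in all
files and reports; slicing is 0-based half-open internally and converted
only at this boundary.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from phisigns.iupac import GAP

log = logging.getLogger("phisigns")

# bacterial/plastid code: the convention for phage CDS
DEFAULT_TRANSLATION_TABLE = 11


@dataclass
class PhageGenome:
    genome_id: str
    name: str
    sequence: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id}: empty sequence")


@dataclass
class GeneRecord:
    """One annotated CDS: coordinates on the parent genome plus its coding-strand
    nucleotide sequence and translation."""

    gene_id: str
    genome_id: str
    start: int  # 1-based inclusive
    stop: int   # 1-based inclusive
    strand: str  # '+' or '-'
    nt_seq: str
    aa_seq: str
    annotation: str = ""

    def __post_init__(self):
        if self.start > self.stop:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > stop {self.stop}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def coding_seq(self) -> str:
        """nt_seq with the terminal stop codon (if present) trimmed, i.e. the
        codons that back the translated protein. Used for codon-aware alignment."""
        return self.nt_seq[: 3 * len(self.aa_seq)]


class FormatError(ValueError):
    """Raised when an input file does not parse under the declared format."""


def translate(nt: str, code: int = DEFAULT_TRANSLATION_TABLE) -> str:
    """Translate a CDS nucleotide string; the terminal stop codon is dropped.

    Internal stops are kept as '*' (the caller decides whether to warn);
    a length not divisible by 3 is an error.
    """
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} not divisible by 3")
    aa = str(Seq(nt).translate(table=code))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC (possibly degenerate) DNA string.

    Gap characters are preserved. Degenerate codes map to the code of the
    complemented base set (R<->Y, S<->S, W<->W, K<->M, B<->V, D<->H, N<->N).
    """
    from phisigns.iupac import COMPLEMENT_TRANS, VALID_CODES
    up = seq.upper()
    bad = set(up) - VALID_CODES - {GAP}
    if bad:
        raise ValueError(f"not an IUPAC nucleotide code: {sorted(bad)[0]!r}")
    return up.translate(COMPLEMENT_TRANS)[::-1]


def _gene_from_coords(genome: PhageGenome, gene_id: str, start: int, stop: int,
                      strand: str, annotation: str, code: int) -> GeneRecord:
    nt = genome.sequence[start - 1: stop]
    if strand == "-":
        nt = reverse_complement(nt)
    aa = translate(nt, code=code)
    if "*" in aa:
        log.warning("gene %s (%s): translation contains internal stop(s); record retained",
                    gene_id, genome.genome_id)
    return GeneRecord(gene_id=gene_id, genome_id=genome.genome_id, start=start,
                      stop=stop, strand=strand, nt_seq=nt, aa_seq=aa,
                      annotation=annotation)


def read_genome(path, format: str = "genbank", table_path=None,
                code: int = DEFAULT_TRANSLATION_TABLE) -> tuple[PhageGenome, list[GeneRecord]]:
    """Read one annotated genome.

    format="genbank": GenBank flat file with CDS features.
    format="fasta+table": FASTA genome plus a TSV gene table at *table_path*
    with header gene_id, start, stop, strand, annotation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        return _read_genbank(path, code)
    if format == "fasta+table":
        if table_path is None:
            raise ValueError("fasta+table format needs table_path")
        return _read_fasta_table(path, Path(table_path), code)
    raise ValueError(f"unknown format {format!r}")


def _read_genbank(path: Path, code: int) -> tuple[PhageGenome, list[GeneRecord]]:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            record = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise FormatError(f"{path}: not a parseable GenBank record ({exc})") from exc
    genome = PhageGenome(
        genome_id=record.id if record.id != "<unknown id>" else record.name,
        name=record.description or record.name,
        sequence=str(record.seq).upper(),
        metadata=dict(record.annotations.get("source", "") and {"source": record.annotations["source"]} or {}),
    )
    genes: list[GeneRecord] = []
    n_cds = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        n_cds += 1
        quals = feat.qualifiers
        gene_id = (quals.get("locus_tag") or quals.get("protein_id")
                   or quals.get("gene") or [f"{genome.genome_id}_cds{n_cds}"])[0]
        annotation = (quals.get("product") or quals.get("note") or [""])[0]
        start = int(feat.location.start) + 1
        stop = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        try:
            genes.append(_gene_from_coords(genome, gene_id, start, stop, strand, annotation, code))
        except ValueError as exc:
            log.warning("gene %s (%s): skipped (%s)", gene_id, genome.genome_id, exc)
    return genome, genes


def _read_fasta_table(fasta_path: Path, table_path: Path, code: int) -> tuple[PhageGenome, list[GeneRecord]]:
    try:
        record = next(SeqIO.parse(str(fasta_path), "fasta"))
    except StopIteration:
        raise FormatError(f"{fasta_path}: no FASTA record found") from None
    genome = PhageGenome(genome_id=record.id, name=record.description, sequence=str(record.seq).upper())
    genes: list[GeneRecord] = []
    with open(table_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "start", "stop", "strand"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{table_path}: gene table must have columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                genes.append(_gene_from_coords(
                    genome, row["gene_id"], int(row["start"]), int(row["stop"]),
                    row["strand"], row.get("annotation", ""), code))
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{table_path} line {i}: {exc}") from exc
    return genome, genes


# --- writers -----------------------------------------------------------------

def write_genome(genome: PhageGenome, genes: list[GeneRecord], fasta_path, table_path) -> None:
    """Write a genome in fasta+table form (the round-trippable flat format)."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.genome_id, description=genome.name)
    SeqIO.write([rec], str(fasta_path), "fasta")
    with open(table_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "start", "stop", "strand", "annotation"])
        for g in genes:
            w.writerow([g.gene_id, g.start, g.stop, g.strand, g.annotation])


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    """Write (name, sequence) pairs as multi-FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def genbank_record(genome: PhageGenome, genes: list[GeneRecord]) -> SeqRecord:
    """Build a Biopython SeqRecord with CDS features (used by the simulator)."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.genome_id, name=genome.genome_id[:16],
                    description=genome.name)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["date"] = "01-JAN-2012"
    for g in genes:
        loc = FeatureLocation(g.start - 1, g.stop, strand=1 if g.strand == "+" else -1)
        feat = SeqFeature(loc, type="CDS", qualifiers={
            "locus_tag": [g.gene_id],
            "product": [g.annotation],
            "transl_table": [str(DEFAULT_TRANSLATION_TABLE)],
            "translation": [g.aa_seq],
        })
        rec.features.append(feat)
    return rec
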
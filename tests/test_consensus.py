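"""Codon-aware alignment, IUPAC consensus, and conserved-region extraction."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from phisigns.consensus import (
    CodonAlignment,
    ConsensusSequence,
    align_group,
    back_translate,
    extract_conserved_regions,
    iupac_consensus,
    load_user_alignment,
    write_alignment,
)
from phisigns.genome_io import GeneRecord
from phisigns.iupac import IUPAC_SETS
from phisigns.simulate import generate_phage_set


def _gene(gene_id, genome_id, nt):
    from phisigns.genome_io import translate
    return GeneRecord(gene_id=gene_id, genome_id=genome_id, start=1, stop=len(nt),
                      strand="+", nt_seq=nt, aa_seq=translate(nt))


def _aln(*rows, ids=None):
    ids = ids or [f"m{i}" for i in range(len(rows))]
    return CodonAlignment(member_ids=list(ids), rows=list(rows))


class TestBackTranslation:
    def test_identical_genes_align_without_gaps(self):
        nt = "ATGAAAGTTTAA"
        genes = [_gene("a", "A", nt), _gene("b", "B", nt)]
        aln = align_group(genes)
        assert aln.rows == ["ATGAAAGTT", "ATGAAAGTT"]  # stop codon trimmed

    def test_protein_gap_becomes_codon_gap(self):
        genes = [_gene("a", "A", "ATGAAAGTTTAA"), _gene("b", "B", "ATGGTTTAA")]
        aln = back_translate({"a": "MKV", "b": "M-V"}, genes)
        assert aln.row("a") == "ATGAAAGTT"
        assert aln.row("b") == "ATG---GTT"

    def test_ungapping_rows_recovers_coding_sequence(self):
        for seed in range(5):
            pset = generate_phage_set(n_genomes=3, n_families=1, aa_identity=0.7,
                                      genome_len=1500, gene_len_aa=60, seed=seed)
            genes = pset.family_genes("F1")
            aln = align_group(genes)
            for g in genes:
                assert aln.row(g.gene_id).replace("-", "") == g.coding_seq

    def test_inconsistent_nt_aa_named_in_error(self):
        bad = GeneRecord(gene_id="bad", genome_id="A", start=1, stop=9, strand="+",
                         nt_seq="ATGAAATAA", aa_seq="MF")
        with pytest.raises(ValueError, match="bad"):
            align_group([bad, _gene("ok", "B", "ATGAAATAA")])


class TestUserAlignment:
    def test_round_trip_fasta_and_clustal(self, tmp_path):
        aln = _aln("ATGAAAGTT", "ATG---GTT", ids=["a", "b"])
        fa, cl = tmp_path / "a.fasta", tmp_path / "a.aln"
        write_alignment(aln, fa, cl)
        from_fasta = load_user_alignment(fa, ["a", "b"])
        from_clustal = load_user_alignment(cl, ["a", "b"])
        assert from_fasta.rows == aln.rows
        assert from_clustal.rows == from_fasta.rows
        assert from_clustal.member_ids == from_fasta.member_ids

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "ragged.fasta"
        p.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(ValueError):
            load_user_alignment(p)

    def test_unknown_member_names_listed(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">who\nACGT\n>a\nACGT\n")
        with pytest.raises(ValueError, match="who"):
            load_user_alignment(p, ["a", "b"])


class TestIupacConsensus:
    def test_identical_rows_fully_conserved(self):
        cons = iupac_consensus(_aln("ACGT", "ACGT"))
        assert cons.consensus == "ACGT"
        assert cons.conserved_mask == [True] * 4

    def test_two_base_column_gets_minimal_code(self):
        cons = iupac_consensus(_aln("AAAA", "AAAG"))
        assert cons.consensus == "AAAR"
        assert cons.conserved_mask == [True, True, True, False]

    def test_gap_column_propagates(self):
        cons = iupac_consensus(_aln("AC-T", "ACGT"))
        assert cons.consensus == "AC-T"
        assert cons.conserved_mask[2] is False

    def test_n_containing_column_is_never_conserved(self):
        cons = iupac_consensus(_aln("ANT", "AAT"))
        assert cons.consensus == "ANT"
        assert cons.conserved_mask == [True, False, True]

    def test_minimality_on_random_columns(self):
        rng = random.Random(99)
        for _ in range(1000):
            col = [rng.choice("ACGT") for _ in range(rng.randint(2, 6))]
            cons = iupac_consensus(_aln(*["".join([b]) for b in col]))
            code = cons.consensus
            observed = set(col)
            assert IUPAC_SETS[code] == frozenset(observed)
            for other, s in IUPAC_SETS.items():
                if observed <= s:
                    assert len(s) >= len(IUPAC_SETS[code])


class TestConservedRegions:
    def test_hand_trace_with_flanks(self):
        cons = iupac_consensus(_aln("RRRRRACGTACGTRRRRR".replace("R", "A"),
                                    "RRRRRACGTACGTRRRRR".replace("R", "G")))
        assert cons.consensus == "RRRRRACGTACGTRRRRR"
        regions = extract_conserved_regions(cons)
        spans = [(r.start, r.stop) for r in regions]
        # anchors at columns 6..12 all reach the furthest conserved base 13
        assert spans == [(1, 18), (2, 18), (3, 18), (4, 18), (5, 18), (6, 18), (7, 18)]
        assert regions[0].seq == cons.consensus

    def test_conserved_bases_too_far_apart(self):
        # two conserved bases 22 apart, nothing conserved between them
        top = "A" + "R" * 21 + "A"
        cons = ConsensusSequence(consensus=top.replace("R", "R"),
                                 conserved_mask=[c != "R" for c in top])
        assert extract_conserved_regions(cons) == []

    def test_gap_spanning_regions_excluded(self):
        consensus = "ACGTA-ACGTA"
        mask = [c in "ACGT" for c in consensus]
        cons = ConsensusSequence(consensus=consensus, conserved_mask=mask)
        for r in extract_conserved_regions(cons):
            assert "-" not in r.seq

    def test_unclipped_length_bounds_and_content(self):
        rng = random.Random(17)
        for _ in range(50):
            cols = []
            for _ in range(120):
                cols.append(rng.choice("ACGT") if rng.random() < 0.5 else rng.choice("RYSWKM"))
            consensus = "".join(cols)
            cons = ConsensusSequence(consensus=consensus,
                                     conserved_mask=[c in "ACGT" for c in consensus])
            for r in extract_conserved_regions(cons):
                if r.start - 1 >= 5 and len(consensus) - r.stop >= 5:  # unclipped
                    assert 12 <= r.length <= 30
                n_conserved = sum(1 for c in r.seq if c in "ACGT")
                assert n_conserved >= 2
                assert "-" not in r.seq

    def test_determinism_under_member_order(self):
        rows = ["ACGTACGTACGTACG", "ACGTACGAACGTACG", "ACGTACGTACGAACG"]
        a = extract_conserved_regions(iupac_consensus(_aln(*rows)))
        b = extract_conserved_regions(iupac_consensus(_aln(*reversed(rows), ids=["x", "y", "z"])))
        assert [(r.start, r.stop, r.seq) for r in a] == [(r.start, r.stop, r.seq) for r in b]


@settings(max_examples=50, deadline=None)
@given(st.lists(st.text(alphabet="ACGT", min_size=8, max_size=8), min_size=2, max_size=5))
def test_consensus_covers_all_observed_bases(rows):
    cons = iupac_consensus(_aln(*rows, ids=[f"m{i}" for i in range(len(rows))]))
    for j, code in enumerate(cons.consensus):
        observed = {row[j] for row in rows}
        assert observed <= IUPAC_SETS[code]
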
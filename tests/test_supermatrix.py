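"""Supermatrix assembly: readers, chimeric OTUs, occupancy filtering,
concatenation and missing-data accounting."""

import numpy as np
import pytest

from streptophylo.alignment import Alignment, GeneAlignment
from streptophylo.supermatrix import (
    ChimeraRule, apply_chimeras, concatenate, filter_gene_occupancy,
    gene_missing_taxa, missing_fraction, read_gene_alignments, subsample_taxa,
)


@pytest.fixture
def genes():
    return [
        GeneAlignment("g_b", {"A": "MKLV", "B": "MKIV", "C": "????", "D": "MRLV"}),
        GeneAlignment("g_a", {"A": "WY", "B": "??", "D": "WF"}),
        GeneAlignment("g_c", {"A": "DEDED", "B": "DEDED", "C": "DEDDD",
                              "D": "EEDED"}),
    ]


class TestReaders:
    def test_fasta_and_phylip_routes_agree(self, tmp_path):
        aln = Alignment({"tax1": "MKLV", "tax2": "MRIV", "tax3": "MKIV"})
        aln.write(tmp_path / "g1.fasta", "fasta")
        aln.write(tmp_path / "g1.phy", "phylip")
        via_fasta = read_gene_alignments([tmp_path / "g1.fasta"], "fasta")[0]
        via_phylip = read_gene_alignments([tmp_path / "g1.phy"], "phylip")[0]
        assert via_fasta.sequences == via_phylip.sequences
        assert via_fasta.gene_id == "g1"

    def test_ragged_fasta_errors_with_detail(self, tmp_path):
        (tmp_path / "bad.fasta").write_text(">A\nMKL\n>B\nMK\n")
        with pytest.raises(ValueError):
            read_gene_alignments([tmp_path / "bad.fasta"])

    def test_empty_file_errors(self, tmp_path):
        (tmp_path / "empty.fasta").write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_gene_alignments([tmp_path / "empty.fasta"])


class TestChimeras:
    def test_complementary_sources_fill_both_genes(self):
        g1 = GeneAlignment("g1", {"A": "MK", "B": "??", "C": "ML"})
        g2 = GeneAlignment("g2", {"A": "??", "B": "WY", "C": "WF"})
        merged, donors = apply_chimeras([g1, g2],
                                        [ChimeraRule("AB", ["A", "B"])])
        assert merged[0]["AB"] == "MK" and merged[1]["AB"] == "WY"
        assert "A" not in merged[0].taxa and "B" not in merged[0].taxa
        assert donors["AB"] == {"g1": "A", "g2": "B"}
        sm = concatenate(merged)
        assert missing_fraction(sm) == 0.0   # the merge removed all gaps

    def test_priority_order_chooses_first_source(self):
        g = GeneAlignment("g", {"A": "MK", "B": "ML", "C": "MI"})
        merged, donors = apply_chimeras([g], [ChimeraRule("AB", ["B", "A"])])
        assert merged[0]["AB"] == "ML"
        assert donors["AB"]["g"] == "B"

    def test_random_presence_matches_priority_table(self):
        rng = np.random.default_rng(7)
        rule = ChimeraRule("XY", ["X", "Y", "Z"])
        genes, expected = [], {}
        for k in range(5):
            present = {t: bool(rng.integers(2)) for t in "XYZ"}
            seqs = {t: ("MK" if present[t] else "??") for t in "XYZ"}
            seqs["W"] = "MR"
            genes.append(GeneAlignment(f"g{k}", seqs))
            expected[f"g{k}"] = next((t for t in rule.sources if present[t]), None)
        _, donors = apply_chimeras(genes, [rule])
        assert donors["XY"] == expected

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            ChimeraRule("A", ["A", "B"])
        with pytest.raises(ValueError):
            ChimeraRule("X", ["A"])


class TestOccupancyFilter:
    def test_boundary_16_of_46(self):
        taxa = [f"t{i}" for i in range(46)]
        seqs30 = {t: "MK" for t in taxa[:30]}
        gene30 = GeneAlignment("g30", seqs30)          # 16 missing taxa
        seqs29 = {t: "MK" for t in taxa[:29]}
        gene29 = GeneAlignment("g29", seqs29)          # 17 missing taxa
        kept, report = filter_gene_occupancy([gene30, gene29], taxa, 16)
        assert [g.gene_id for g in kept] == ["g30"]
        assert report.gene_missing_taxa == {"g30": 16, "g29": 17}
        assert report.discarded_genes == ["g29"]

    def test_all_present_kept_with_zero_missing(self, genes):
        kept, report = filter_gene_occupancy([genes[2]], list("ABCD"), 0)
        assert len(kept) == 1 and report.gene_missing_taxa["g_c"] == 0

    def test_extreme_thresholds(self, genes):
        taxa = list("ABCD")
        all_kept, _ = filter_gene_occupancy(genes, taxa, len(taxa))
        assert len(all_kept) == len(genes)
        complete_only, _ = filter_gene_occupancy(genes, taxa, 0)
        assert [g.gene_id for g in complete_only] == ["g_c"]

    def test_all_missing_sequence_counts_as_missing(self, genes):
        assert gene_missing_taxa(genes[0], list("ABCD")) == 1  # C is all-'?'


class TestConcatenate:
    def test_lengths_partitions_and_fill(self, genes):
        sm = concatenate(genes, list("ABCD"))
        assert sm.n_columns == 4 + 2 + 5
        # lexicographic gene order
        assert list(sm.partitions) == ["g_a", "g_b", "g_c"]
        assert sm.partitions["g_a"] == (0, 2)
        assert sm.partitions["g_b"] == (2, 6)
        assert sm.sequences["C"][:2] == "??"

    def test_round_trip_gene_blocks(self, genes):
        sm = concatenate(genes, list("ABCD"))
        block = sm.gene_block("g_b")
        assert block.sequences["A"] == "MKLV"
        assert block.sequences["C"] == "????"

    def test_taxon_missing_one_gene_fraction(self):
        g1 = GeneAlignment("g1", {"A": "M" * 100, "B": "M" * 100})
        g2 = GeneAlignment("g2", {"A": "W" * 250, "B": "?" * 250})
        sm = concatenate([g1, g2], ["A", "B"])
        mask = sm.missing_mask()
        assert mask[sm.taxa.index("B")].mean() == pytest.approx(250 / 350)

    def test_duplicate_gene_id_rejected(self, genes):
        with pytest.raises(ValueError, match="duplicate"):
            concatenate([genes[0], genes[0]])

    def test_missing_fraction_reorder_invariance(self, genes):
        taxa = list("ABCD")
        a = missing_fraction(concatenate(genes, taxa))
        b = missing_fraction(concatenate(genes[::-1], taxa[::-1]))
        assert a == pytest.approx(b)


class TestMissingFraction:
    def test_direct_counts(self):
        sm = concatenate([GeneAlignment("g", {"A": "MKLVWKRERV",
                                              "B": "??????????"})], ["A", "B"])
        assert missing_fraction(sm) == pytest.approx(0.5)

    def test_random_mask_count(self):
        rng = np.random.default_rng(0)
        chars = np.array(list("M" * 1000))
        masked = rng.choice(1000, size=123, replace=False)
        chars[masked] = "?"
        sm = concatenate([GeneAlignment("g", {"A": "".join(chars)})], ["A"])
        assert missing_fraction(sm) == pytest.approx(0.123)


class TestSubsample:
    def test_drop_none_is_identity(self, genes):
        sm = concatenate(genes, list("ABCD"))
        assert subsample_taxa(sm, []).sequences == sm.sequences

    def test_drop_keeps_columns_by_default(self, genes):
        sm = concatenate(genes, list("ABCD"))
        sub = subsample_taxa(sm, ["C"])
        assert sub.n_columns == sm.n_columns
        assert set(sub.taxa) == {"A", "B", "D"}

    def test_prune_leaves_no_all_missing_column(self):
        g1 = GeneAlignment("g1", {"A": "MK", "B": "MR", "C": "??"})
        g2 = GeneAlignment("g2", {"C": "WW", "A": "??", "B": "??"})
        sm = concatenate([g1, g2], list("ABC"))
        pruned = subsample_taxa(sm, ["C"], prune_empty_columns=True)
        assert not pruned.missing_mask().all(axis=0).any()
        assert pruned.n_columns == 2
        assert list(pruned.partitions) == ["g1"]     # g2 emptied entirely

    def test_unknown_taxon(self, genes):
        sm = concatenate(genes, list("ABCD"))
        with pytest.raises(ValueError):
            subsample_taxa(sm, ["Z"])


class TestOutputs:
    def test_phylip_and_partition_files(self, genes, tmp_path):
        sm = concatenate(genes, list("ABCD"))
        sm.write_phylip(tmp_path / "sm.phy")
        sm.write_partitions(tmp_path / "parts.txt")
        back = Alignment.read(tmp_path / "sm.phy", "phylip-sequential")
        assert back.sequences == sm.sequences
        lines = (tmp_path / "parts.txt").read_text().strip().splitlines()
        assert lines[0] == "g_a = 1-2"      # 1-based closed intervals
        assert lines[1] == "g_b = 3-6"
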
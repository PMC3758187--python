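import pytest

from ervclock.core_io import (
    CoreIOError,
    Feature,
    MultipleAlignment,
    NucSequence,
    read_fasta,
    read_gff3,
    read_newick,
    write_fasta,
    write_gff3,
    tree_from_newick_string,
)


class TestNucSequence:
    def test_canonicalization_uppercases_and_maps_u_to_t(self):
        s = NucSequence("a", "acgu")
        assert s.residues == "ACGT"

    def test_gaps_require_aligned_flag(self):
        with pytest.raises(CoreIOError):
            NucSequence("a", "AC-GT")
        assert NucSequence("a", "AC-GT", aligned=True).residues == "AC-GT"

    @pytest.mark.parametrize("bad", ["ACXT", "AC GT", "ACG*"])
    def test_illegal_characters_rejected(self, bad):
        with pytest.raises(CoreIOError):
            NucSequence("a", bad)

    def test_empty_id_rejected(self):
        with pytest.raises(CoreIOError):
            NucSequence("", "ACGT")

    def test_feature_must_fit_on_sequence(self):
        with pytest.raises(CoreIOError):
            NucSequence("a", "ACGT", [Feature("f", 0, 5)])


class TestFasta:
    def test_read_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nacgt\n")
        seqs = read_fasta(p)
        assert len(seqs) == 1
        assert seqs[0].id == "a"
        assert seqs[0].residues == "ACGT"

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "e.fa"
        p.write_text("")
        with pytest.raises(CoreIOError):
            read_fasta(p)

    def test_duplicate_ids_error(self, tmp_path):
        p = tmp_path / "d.fa"
        p.write_text(">x\nAC\n>x\nGT\n")
        with pytest.raises(CoreIOError):
            read_fasta(p)

    def test_round_trip(self, tmp_path):
        import numpy as np

        rng = np.random.default_rng(0)
        seqs = [
            NucSequence(f"s{i}", "".join(rng.choice(list("ACGT"), size=130)))
            for i in range(3)
        ]
        p = tmp_path / "rt.fa"
        write_fasta(seqs, p, width=60)
        back = read_fasta(p)
        assert [(s.id, s.residues) for s in back] == [(s.id, s.residues) for s in seqs]
        # a 130-base sequence wraps into 3 lines at width 60
        body = [ln for ln in p.read_text().splitlines() if not ln.startswith(">")]
        assert len(body) == 9 and len(body[0]) == 60

    def test_aligned_sequences_written_verbatim(self, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta([NucSequence("a", "AC-GT", aligned=True),
                     NucSequence("b", "ACCGT")], p)
        assert "AC-GT" in p.read_text()

    def test_refuses_empty_list(self, tmp_path):
        with pytest.raises(CoreIOError):
            write_fasta([], tmp_path / "x.fa")


class TestNewick:
    def test_three_leaf_ultrametric(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:50,B:50):54,C:104);\n")
        tree = read_newick(p)
        assert sorted(tree.leaf_labels) == ["A", "B", "C"]
        assert tree.root_age() == pytest.approx(104)
        # ultrametric: every root-to-leaf path is 104 Myr
        for leaf in tree.tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(104)

    def test_missing_branch_length_errors(self):
        with pytest.raises(CoreIOError):
            tree_from_newick_string("((A:50,B):54,C:104);")

    def test_duplicate_leaf_errors(self):
        with pytest.raises(CoreIOError):
            tree_from_newick_string("((A:50,A:50):54,C:104);")

    def test_unbalanced_parentheses_error(self):
        with pytest.raises(CoreIOError):
            tree_from_newick_string("((A:50,B:50:54,C:104);")

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(CoreIOError):
            tree_from_newick_string("(A:1,B:1);", default_rate=0.0)


class TestGff3:
    def test_coordinate_conversion(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("##gff-version 3\nseq1\tx\tdispersed_repeat\t1\t10\t.\t+\t.\tName=MIR\n")
        feats = read_gff3(p)
        (f,) = feats["seq1"]
        assert (f.start, f.end) == (0, 10)

    def test_round_trip_five_features(self, tmp_path):
        feats = {
            "s1": [
                Feature("MIR3", 0, 10, "+", family="MIR"),
                Feature("MER3", 20, 45, "-", family="MER"),
                Feature("5'LTR", 50, 80, "+"),
            ],
            "s2": [
                Feature("MIR3", 3, 13, "+", family="MIR"),
                Feature("solo", 100, 400, "-", family="ERV"),
            ],
        }
        p = tmp_path / "rt.gff3"
        write_gff3(feats, p)
        assert read_gff3(p) == feats

    def test_dot_strand_stored_as_plus_with_flag(self, tmp_path):
        p = tmp_path / "d.gff3"
        p.write_text("s\tx\tdispersed_repeat\t5\t9\t.\t.\t.\tName=f\n")
        (f,) = read_gff3(p)["s"]
        assert f.strand == "+" and not f.strand_known
        # and the convention round-trips back to '.'
        out = tmp_path / "d2.gff3"
        write_gff3({"s": [f]}, out)
        assert "\t.\t.\t" in out.read_text().splitlines()[1]

    def test_end_before_start_errors(self, tmp_path):
        p = tmp_path / "b.gff3"
        p.write_text("s\tx\tr\t10\t2\t.\t+\t.\tName=f\n")
        with pytest.raises(CoreIOError):
            read_gff3(p)


class TestMultipleAlignment:
    def test_rejects_unequal_rows_and_single_row(self):
        a = NucSequence("a", "AC-GT", aligned=True)
        b = NucSequence("b", "ACGT", aligned=True)
        with pytest.raises(CoreIOError):
            MultipleAlignment([a, b])
        with pytest.raises(CoreIOError):
            MultipleAlignment([a])

    def test_seq_to_column_map_skips_gaps(self):
        msa = MultipleAlignment(
            [
                NucSequence("a", "A-CG", aligned=True),
                NucSequence("b", "ATCG", aligned=True),
            ]
        )
        assert msa.seq_to_column_map("a") == [0, 2, 3]
        assert msa.column(1) == "-T"
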
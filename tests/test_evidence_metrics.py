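import numpy as np
import pytest

from ervclock.core_io import CoreIOError, Feature, MultipleAlignment, NucSequence
from ervclock.evidence_metrics import (
    RegionSpec,
    conservation_profile,
    region_identity_matrix,
    sge_concordance,
)


def _msa(rows: dict[str, str]) -> MultipleAlignment:
    return MultipleAlignment(
        [NucSequence(k, v, aligned=True) for k, v in rows.items()]
    )


class TestConservationProfile:
    def test_fully_conserved_column_scores_one(self):
        msa = _msa({"a": "A", "b": "A", "c": "A", "d": "A"})
        assert conservation_profile(msa).scores[0] == 1.0

    def test_majority_two_of_four(self):
        msa = _msa({"a": "A", "b": "A", "c": "C", "d": "T"})
        assert conservation_profile(msa).scores[0] == 0.5

    def test_gap_rows_excluded_from_denominator(self):
        # one residue, three gaps: 1/1 non-gap rows -> fully conserved
        msa = _msa({"a": "A", "b": "-", "c": "-", "d": "-"})
        assert conservation_profile(msa, "majority").scores[0] == 1.0
        # the alternative denominator counts all rows
        assert conservation_profile(msa, "majority_all").scores[0] == 0.25

    def test_all_gap_column_scores_zero(self):
        msa = _msa({"a": "-A", "b": "-A"})
        prof = conservation_profile(msa)
        assert prof.scores[0] == 0.0 and prof.scores[1] == 1.0

    def test_pairwise_mode_mean_match_fraction(self):
        # column AACT: pairs AA match, 5 others mismatch -> 1/6
        msa = _msa({"a": "A", "b": "A", "c": "C", "d": "T"})
        assert conservation_profile(msa, "pairwise").scores[0] == pytest.approx(1 / 6)

    def test_column_shuffle_preserves_score_multiset(self):
        rng = np.random.default_rng(6)
        cols = ["".join(rng.choice(list("ACGT-"), size=5)) for _ in range(40)]
        # avoid a row that is entirely gaps
        rows = ["".join(c[i] for c in cols) for i in range(5)]
        msa = _msa({f"s{i}": r for i, r in enumerate(rows)})
        perm = rng.permutation(40)
        shuffled = _msa(
            {f"s{i}": "".join(rows[i][j] for j in perm) for i in range(5)}
        )
        s1 = sorted(conservation_profile(msa).scores)
        s2 = sorted(conservation_profile(shuffled).scores)
        assert np.allclose(s1, s2)


class TestRegionIdentityMatrix:
    def test_identical_rows_full_identity(self):
        msa = _msa({"a": "ACGTACGT", "b": "ACGTACGT"})
        m = region_identity_matrix(msa, RegionSpec("r", 0, 8))
        assert m.loc["a", "b"] == 100.0

    def test_three_quarters_identity(self):
        msa = _msa({"a": "ACGT", "b": "ACGA"})
        m = region_identity_matrix(msa, RegionSpec("r", 0, 4))
        assert m.loc["a", "b"] == 75.0

    def test_pairwise_gap_stripping(self):
        # pair a/b comparable only at 2 columns (1 match)
        msa = _msa({"a": "AC--", "b": "A-G-", "c": "ACGT"})
        m = region_identity_matrix(msa, RegionSpec("r", 0, 4))
        assert m.loc["a", "b"] == 100.0  # only column 0 comparable
        assert m.loc["a", "c"] == 100.0
        assert m.loc["b", "c"] == 100.0

    def test_zero_comparable_columns_flagged_not_zero(self):
        msa = _msa({"a": "AAAA----", "b": "----CCCC", "c": "AAAACCCC"})
        m = region_identity_matrix(msa, RegionSpec("r", 0, 8))
        assert np.isnan(m.loc["a", "b"])

    def test_symmetry_and_diagonal_on_simulated_species(self, eleven_species_run):
        _, aln, _ = eleven_species_run
        m = region_identity_matrix(aln, RegionSpec("A", 800, 1797))
        assert np.allclose(m.values, m.values.T, equal_nan=True)
        assert (np.diag(m.values) == 100.0).all()

    def test_region_outside_alignment_rejected(self):
        msa = _msa({"a": "ACGT", "b": "ACGT"})
        with pytest.raises(CoreIOError):
            region_identity_matrix(msa, RegionSpec("r", 0, 10))


class TestSgeConcordance:
    def _three_species(self):
        return _msa({"s1": "AACCGGTT", "s2": "AACCGGTT", "s3": "AACCGGTT"})

    def test_same_position_same_strand_concordant(self):
        msa = self._three_species()
        feats = {
            s: [Feature("MIR", 2, 6, "+", family="MIR")] for s in ("s1", "s2", "s3")
        }
        (c,) = sge_concordance(msa, feats)
        assert c.concordant and c.absent == []

    def test_opposite_strand_discordant(self):
        msa = self._three_species()
        feats = {
            "s1": [Feature("MIR", 2, 6, "+", family="MIR")],
            "s2": [Feature("MIR", 2, 6, "-", family="MIR")],
            "s3": [Feature("MIR", 2, 6, "+", family="MIR")],
        }
        (c,) = sge_concordance(msa, feats)
        assert not c.concordant

    def test_disjoint_windows_discordant(self):
        msa = self._three_species()
        feats = {
            "s1": [Feature("MIR", 0, 3, "+", family="MIR")],
            "s2": [Feature("MIR", 5, 8, "+", family="MIR")],
        }
        (c,) = sge_concordance(msa, feats)
        assert not c.concordant

    def test_absence_tolerated_and_reported(self):
        """An SGE present in 9 of 11 species at overlapping positions is
        concordant, with the two deletions reported as absences."""
        species = [f"sp{i}" for i in range(11)]
        msa = _msa({s: "AACCGGTTAA" for s in species})
        feats = {
            s: [Feature("MIR", 2, 8, "+", family="MIR")] for s in species[:9]
        }
        feats.update({s: [] for s in species[9:]})
        (c,) = sge_concordance(msa, feats)
        assert c.concordant
        assert sorted(c.absent) == ["sp10", "sp9"]
        assert len(c.present) == 9

    def test_feature_outside_sequence_rejected(self):
        msa = self._three_species()
        feats = {"s1": [Feature("MIR", 2, 20, "+", family="MIR")]}
        with pytest.raises(CoreIOError):
            sge_concordance(msa, feats)

    def test_simulated_predivergence_sges_all_concordant(self, eleven_species_run):
        seqs, aln, truth = eleven_species_run
        feats = {
            sp: [f for f in seqs[sp].features if f.family.startswith(("MIR", "MER"))]
            for sp in seqs
        }
        results = sge_concordance(aln, feats)
        assert len(results) == 3
        assert all(c.concordant for c in results)
        assert all(c.absent == [] for c in results)
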
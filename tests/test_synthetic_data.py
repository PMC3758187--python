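import json

import numpy as np
import pytest

from ervclock.core_io import NucSequence, read_fasta, read_gff3, read_newick
from ervclock.pairwise_align import UNGAPPED_PARAMS, global_align, percent_divergence
from ervclock.synthetic_data import (
    AFROTHERIA,
    SimConfig,
    expected_divergence,
    fixture_suite,
    eleven_species_config,
    simulate,
    two_species_config,
)


def _two_leaf(t_host=104.0, t_integration=130.0, **kw):
    return SimConfig(
        newick=f"(A:{t_host},B:{t_host});",
        t_integration=t_integration,
        ltr_len=300,
        internal_len=200,
        flank5_len=50,
        flank3_len=50,
        **kw,
    )


def _feature_slice(seq, label):
    f = {x.label: x for x in seq.features}[label]
    return NucSequence(f"{seq.id}:{label}", seq.residues[f.start : f.end])


class TestSubstitutionClock:
    def test_zero_rate_leaves_species_identical(self):
        cfg = _two_leaf(rate=0.0)
        seqs, aln, truth = simulate(cfg, seed=1)
        assert seqs["A"].residues == seqs["B"].residues
        assert sum(truth.branch_substitutions.values()) == 0

    def test_determinism_same_seed_same_output(self):
        s1, a1, t1 = simulate(_two_leaf(), seed=9)
        s2, a2, t2 = simulate(_two_leaf(), seed=9)
        assert s1["A"].residues == s2["A"].residues
        assert t1.branch_substitutions == t2.branch_substitutions

    def test_different_seeds_differ(self):
        s1, _, _ = simulate(_two_leaf(), seed=9)
        s2, _, _ = simulate(_two_leaf(), seed=10)
        assert s1["A"].residues != s2["A"].residues

    def test_clock_linearity_matches_expected_divergence(self):
        """Mean observed divergence over 50 replicates tracks the JC
        expectation within 3 standard errors at t = 10, 50, 100 Myr."""
        for t in (10.0, 50.0, 100.0):
            divs = []
            for i in range(50):
                cfg = SimConfig(
                    newick=f"(A:{t},B:{t});", t_integration=t,
                    ltr_len=250, internal_len=100, flank5_len=25, flank3_len=25,
                )
                seqs, _, _ = simulate(cfg, seed=2000 + i)
                aln = global_align(
                    seqs["A"].ungapped(), seqs["B"].ungapped(), UNGAPPED_PARAMS
                )
                divs.append(percent_divergence(aln))
            mean, se = np.mean(divs), np.std(divs, ddof=1) / np.sqrt(len(divs))
            assert abs(mean - expected_divergence(t, 4.5e-9)) < 3 * max(se, 0.1)

    def test_expected_divergence_limits(self):
        assert expected_divergence(0, 4.5e-9) == 0.0
        assert expected_divergence(1e9, 4.5e-9) == pytest.approx(75.0)
        with pytest.raises(ValueError):
            expected_divergence(-1, 4.5e-9)

    def test_expected_divergence_small_t_linear_limit(self):
        # at 24.4 Myr the JC expectation is within 15% of the 2*mu*t line
        t, mu = 24.4, 4.5e-9
        linear = 2 * 0.45 * t
        assert expected_divergence(t, mu) == pytest.approx(linear, rel=0.15)


class TestLtrDivergenceStructure:
    def test_integration_at_split_equalizes_cross_and_same(self):
        """No stem time: 5'5' and 5'3' divergences agree on average."""
        d_same, d_cross = [], []
        for i in range(15):
            seqs, _, _ = simulate(_two_leaf(t_integration=104.0), seed=3000 + i)
            a5, a3 = _feature_slice(seqs["A"], "5'LTR"), _feature_slice(seqs["A"], "3'LTR")
            b5, b3 = _feature_slice(seqs["B"], "5'LTR"), _feature_slice(seqs["B"], "3'LTR")
            d_same.append(percent_divergence(global_align(a5, b5, UNGAPPED_PARAMS)))
            d_cross.append(percent_divergence(global_align(a5, b3, UNGAPPED_PARAMS)))
        assert abs(np.mean(d_cross) - np.mean(d_same)) < 5.0

    def test_cross_exceeds_same_under_deep_integration(self):
        """truth 130 Ma vs host 104 Ma: cross-LTR divergence exceeds
        same-LTR divergence in >= 90% of 50 seeds."""
        cfg = two_species_config()
        wins = 0
        for seed in range(50):
            seqs, _, _ = simulate(cfg, seed=seed)
            a5, a3 = _feature_slice(seqs["speciesA"], "5'LTR"), _feature_slice(seqs["speciesA"], "3'LTR")
            b5, b3 = _feature_slice(seqs["speciesB"], "5'LTR"), _feature_slice(seqs["speciesB"], "3'LTR")
            dc = (
                percent_divergence(global_align(a5, b3, UNGAPPED_PARAMS))
                + percent_divergence(global_align(b5, a3, UNGAPPED_PARAMS))
            ) / 2
            ds = percent_divergence(global_align(a5, b5, UNGAPPED_PARAMS))
            wins += dc > ds
        assert wins >= 45


class TestEvents:
    def test_stem_sges_inherited_by_all_species(self, eleven_species_run):
        seqs, _, truth = eleven_species_run
        for sp, seq in seqs.items():
            labels = {f.label for f in seq.features}
            assert {"MIR.1", "MER3.1", "MIR.2"} <= labels

    def test_solo_ltr_restricted_to_afrotheria(self, eleven_species_run):
        seqs, _, truth = eleven_species_run
        for sp, seq in seqs.items():
            labels = {f.label for f in seq.features}
            if sp in AFROTHERIA:
                assert "ERVsec_soloLTR" in labels
                assert "ERVsec_internal" not in labels
            else:
                assert not any(l.startswith("ERVsec") for l in labels)

    def test_event_conservation_feature_counts(self, eleven_species_run):
        """Each leaf carries exactly the features its lineage saw: 5
        structural regions + 3 shared SGEs, plus the solo LTR in the
        Afrotheria (secondary LTR5/internal removed by recombination)."""
        seqs, _, _ = eleven_species_run
        for sp, seq in seqs.items():
            expected = 8 + (1 if sp in AFROTHERIA else 0)
            assert len(seq.features) == expected

    def test_recombination_logged_with_removed_length(self, eleven_species_run):
        _, _, truth = eleven_species_run
        (ev,) = truth.recomb_log
        assert ev["family"] == "ERVsec"
        assert ev["removed_bp"] == 450 + 600  # one LTR + internal

    def test_event_time_off_edge_rejected(self):
        cfg = _two_leaf()
        from ervclock.synthetic_data import SgeEvent

        bad = SimConfig(
            newick=cfg.newick, t_integration=130.0,
            sge_events=[SgeEvent(family="X", length=10, time=50.0, position=10)],
        )  # stem spans 130-104 Ma; 50 Ma is not on it
        with pytest.raises(ValueError):
            simulate(bad, seed=0)

    def test_integration_after_root_rejected(self):
        with pytest.raises(ValueError):
            simulate(_two_leaf(t_integration=50.0), seed=0)

    def test_indels_create_length_variation(self):
        from ervclock.synthetic_data import IndelModel

        cfg = _two_leaf(indel=IndelModel(rate=0.05, mean_length=4))
        seqs, aln, truth = simulate(cfg, seed=4)
        assert truth.indel_log  # events happened
        assert len(seqs["A"].residues) != len(seqs["B"].residues)

    def test_truth_alignment_consistent_with_sequences(self, eleven_species_run):
        seqs, aln, _ = eleven_species_run
        for sp in seqs:
            assert aln.row(sp).residues.replace("-", "") == seqs[sp].residues


class TestFixtureSuite:
    def test_same_seed_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1, p2 = fixture_suite(d1, seed=5), fixture_suite(d2, seed=5)
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_artifacts_parse_back(self, fixture_dir):
        seqs = read_fasta(fixture_dir["sequences"])
        aln_rows = read_fasta(fixture_dir["alignment"], aligned=True)
        feats = read_gff3(fixture_dir["annotations"])
        tree = read_newick(fixture_dir["tree"])
        truth = json.load(open(fixture_dir["truth"]))
        assert len(seqs) == len(aln_rows) == 11
        assert set(feats) == {s.id for s in seqs}
        assert sorted(tree.leaf_labels) == sorted(s.id for s in seqs)
        assert truth["t_integration"] == 130.0
        assert tree.root_age() == pytest.approx(104.0)

    def test_fixture_sges_concordant_end_to_end(self, fixture_dir):
        from ervclock.core_io import MultipleAlignment
        from ervclock.evidence_metrics import sge_concordance

        rows = read_fasta(fixture_dir["alignment"], aligned=True)
        msa = MultipleAlignment(rows)
        feats = read_gff3(fixture_dir["annotations"])
        sge_only = {
            sp: [f for f in fl if f.family.startswith(("MIR", "MER"))]
            for sp, fl in feats.items()
        }
        results = sge_concordance(msa, sge_only)
        assert len(results) == 3 and all(c.concordant for c in results)
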
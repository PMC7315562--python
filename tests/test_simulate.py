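"""Simulator determinism, event grammar, and the N-dup gain/loss cycle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from mitocomp.align import aligned_identity_similarity
from mitocomp.simulate import (
    IntronEvent,
    MobileEvent,
    SimConfig,
    aa_analog,
    default_plan,
    fig4_transition,
    headline_scenario,
    ndup_cycle,
    ndup_gain,
    ndup_apply,
    simulate,
    _random_cds,
)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = headline_scenario(seed=5)
        gs1, t1 = simulate(cfg)
        gs2, t2 = simulate(headline_scenario(seed=5))
        for a, b in zip(gs1.genomes, gs2.genomes):
            assert a.isolate_id == b.isolate_id
            assert a.sequence == b.sequence
            assert [f.exons for f in a.features] == [f.exons for f in b.features]
        assert t1.events.equals(t2.events)
        assert t1.presence.equals(t2.presence)

    def test_different_seed_differs(self):
        gs1, _ = simulate(headline_scenario(seed=5))
        gs2, _ = simulate(headline_scenario(seed=6))
        assert gs1.genomes[0].sequence != gs2.genomes[0].sequence


class TestNeutralLimits:
    def test_zero_rates_no_events_all_identical(self):
        cfg = SimConfig(seed=2, tree="(A:0.0,B:0.0,C:0.0);", plan=default_plan())
        gs, truth = simulate(cfg)
        seqs = {g.sequence for g in gs.genomes}
        assert len(seqs) == 1
        assert truth.diversity["snp_count"].sum() == 0

    def test_duplicate_isolates_share_sequence(self, headline_sim):
        gs, _ = headline_sim
        assert gs.get("TF02").sequence == gs.get("TF04").sequence
        assert gs.get("TF14").sequence == gs.get("TF11").sequence
        assert gs.get("TF05").sequence != gs.get("TF04").sequence


class TestValidation:
    def test_colliding_events_rejected(self):
        ev = [
            IntronEvent("cox1", 300, 500, ["A"]),
            IntronEvent("cox1", 300, 700, ["A", "B"]),
        ]
        cfg = SimConfig(seed=1, tree="(A:0.01,B:0.01);", plan=default_plan(), intron_events=ev)
        with pytest.raises(ValueError, match="colliding"):
            simulate(cfg)

    def test_unknown_carrier_rejected(self):
        cfg = SimConfig(
            seed=1,
            tree="(A:0.01,B:0.01);",
            plan=default_plan(),
            intron_events=[IntronEvent("cox1", 300, 500, ["Z"])],
        )
        with pytest.raises(ValueError, match="not a tree tip"):
            simulate(cfg)

    def test_nonadjacent_mobile_flanks_rejected(self):
        cfg = SimConfig(
            seed=1,
            tree="(A:0.01,B:0.01);",
            plan=default_plan(),
            mobile_events=[MobileEvent("cox1", "rnl", 1500, ["A"])],
        )
        with pytest.raises(ValueError, match="adjacent"):
            simulate(cfg)

    def test_site_out_of_range_rejected(self):
        cfg = SimConfig(
            seed=1,
            tree="(A:0.01,B:0.01);",
            plan=default_plan(),
            intron_events=[IntronEvent("trnA", 75, 100, ["A"])],
        )
        with pytest.raises(ValueError, match="outside"):
            simulate(cfg)


class TestAaAnalog:
    @pytest.mark.parametrize("target", [0.5, 0.65, 0.8, 0.95])
    def test_realized_similarity_matches_target(self, target):
        rng = np.random.default_rng(17)
        cds = _random_cds(rng, 306, 0.4)
        seg = cds[3:303]  # stop-free internal segment, 100 codons
        analog = aa_analog(seg, target, rng)
        pep_a = str(Seq(analog).translate(table=4))
        pep_b = str(Seq(seg).translate(table=4))
        _, sim, ncol, _ = aligned_identity_similarity(pep_a, pep_b)
        assert ncol == 100
        assert abs(sim - target) <= 1.5 / 100  # exact up to rounding


class TestFig4:
    def test_legal_transitions(self):
        assert fig4_transition("N", "gain") == "D-intact"
        assert fig4_transition("D-intact", "exonize") == "D-exonized"
        assert fig4_transition("D-intact", "detach") == "D-downstream"
        assert fig4_transition("D-exonized", "detach") == "D-downstream"
        assert fig4_transition("D-downstream", "lose") == "N"

    def test_illegal_transitions_rejected(self):
        with pytest.raises(ValueError, match="exonize"):
            fig4_transition("N", "exonize")
        with pytest.raises(ValueError):
            fig4_transition("D-exonized", "gain")

    def test_each_stage_keeps_bookkeeping_consistent(self):
        rng = np.random.default_rng(23)
        cds = _random_cds(rng, 900, 0.4)
        hg = ndup_gain(cds, 90, 60, 0.8, rng)
        assert hg.state == "D-intact"
        assert len(hg.cds) == len(cds) + hg.ins_len
        hg2 = ndup_apply(hg, "exonize", rng)
        assert hg2.state == "D-exonized"
        pep = str(Seq(hg2.cds[: len(hg2.cds) - len(hg2.cds) % 3]).translate(table=4))
        assert "*" not in pep.rstrip("*")  # read-through is open
        hg3 = ndup_apply(hg2, "detach", rng)
        assert hg3.state == "D-downstream"
        assert len(hg3.cds) == len(cds)
        assert hg3.downstream_element != ""
        hg4 = ndup_apply(hg3, "lose", rng)
        assert hg4.state == "N" and hg4.downstream_element == ""

    def test_full_cycle_substitutes_only_the_n_terminal_fragment(self):
        rng = np.random.default_rng(29)
        cds = _random_cds(rng, 900, 0.4)
        site, dup_codons, target = 90, 60, 0.8
        final, state = ndup_cycle(cds, site, dup_codons, target, rng)
        assert state.state == "N"
        assert len(final) == len(cds)
        pep0 = str(Seq(cds).translate(table=4))
        pep1 = str(Seq(final).translate(table=4))
        assert "*" not in pep1[:-1]  # still translatable, no internal stops
        lo, hi = site // 3, site // 3 + dup_codons
        assert pep1[:lo] == pep0[:lo]
        assert pep1[hi:] == pep0[hi:]
        # the replaced fragment carries the scripted similarity
        _, sim, ncol, _ = aligned_identity_similarity(pep1[lo:hi], pep0[lo:hi])
        assert ncol == dup_codons
        assert abs(sim - target) <= 0.02


class TestTruthConsistency:
    def test_presence_matrix_matches_events(self, headline_sim):
        gs, truth = headline_sim
        # every event record appears as a 1 in the matrix
        for _, r in truth.events.iterrows():
            assert truth.presence.loc[r.isolate_id, r.event] == 1
        assert truth.presence.shape == (16, 26)

    def test_genome_features_match_emitted_sequence(self, headline_sim):
        gs, truth = headline_sim
        g = gs.get("TF05")
        for locus in g.features:
            if locus.gene_type != "CDS":
                continue
            spliced = g.spliced(locus)
            assert len(spliced) % 3 == 0
            pep = str(Seq(spliced).translate(table=4))
            assert pep.startswith("M")
            assert "*" not in pep[:-1]
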
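"""N-terminal-duplication detection, structural subtyping, cargo search."""

import numpy as np
import pytest
from Bio.Seq import Seq

from mitocomp.align import aligned_identity_similarity
from mitocomp.introns import IntronCall
from mitocomp.ndup import classify_structure, detect_secondary_cargo, scan_intron
from mitocomp.panel import default_panel
from mitocomp.simulate import STOP_CODONS, _random_cds, _random_seq, aa_analog


def _call(seq, iso="X", gene="nad4", site=450):
    return IntronCall(iso, gene, site, (1, len(seq)), seq)


def _exon(rng, n_codons=200):
    """A stop-free coding stretch (a downstream exon in frame 0)."""
    out = []
    while len(out) < n_codons:
        c = _random_seq(rng, 3, 0.4)
        if c not in STOP_CODONS:
            out.append(c)
    return "".join(out)


class TestScanIntron:
    def test_random_intron_is_negative(self):
        rng = np.random.default_rng(0)
        exon = _exon(rng)
        intron = _random_seq(rng, 900, 0.35)
        rep = scan_intron(_call(intron), exon, 0)
        assert rep.gene_type_call == "N-type"

    def test_constructed_duplication_at_80_percent(self):
        rng = np.random.default_rng(1)
        exon = _exon(rng, 220)
        dup = aa_analog(exon[:300], 0.80, rng)
        intron = dup + "TAATAG" + _random_seq(rng, 500, 0.35)
        rep = scan_intron(_call(intron), exon, 0)
        assert rep.gene_type_call == "D-type"
        assert abs(rep.aa_similarity - 80.0) <= 5.0
        # independent brute-force identity on the ungapped pair
        pep_dup = str(Seq(dup).translate(table=4))
        pep_ex = str(Seq(exon[:300]).translate(table=4))
        ident = 100.0 * sum(a == b for a, b in zip(pep_dup, pep_ex)) / len(pep_dup)
        assert abs(rep.aa_identity - ident) <= 5.0

    def test_exon_too_short(self):
        rng = np.random.default_rng(2)
        rep = scan_intron(_call(_random_seq(rng, 300, 0.35)), _exon(rng, 10), 0)
        assert rep.gene_type_call == "N-type"
        assert rep.reason == "exon too short"

    def test_monotone_in_target_similarity(self):
        """Raising the scripted similarity never lowers the positive-call rate."""
        rates = []
        for target in (0.30, 0.50, 0.70, 0.90):
            pos = 0
            n = 8
            for s in range(n):
                rng = np.random.default_rng([5, s])
                exon = _exon(rng, 180)
                dup = aa_analog(exon[:270], target, rng)
                intron = dup + "TAATAG" + _random_seq(rng, 400, 0.35)
                rep = scan_intron(_call(intron), exon, 0)
                pos += rep.positive
            rates.append(pos / n)
        assert rates == sorted(rates)
        assert rates[0] == 0.0 and rates[-1] == 1.0

    def test_measured_similarity_tracks_target(self):
        for target in (0.55, 0.65, 0.75, 0.85, 0.95):
            rng = np.random.default_rng(int(target * 100))
            exon = _exon(rng, 200)
            dup = aa_analog(exon[:300], target, rng)
            intron = dup + "TAATAG" + _random_seq(rng, 300, 0.35)
            rep = scan_intron(_call(intron), exon, 0)
            assert abs(rep.aa_similarity - 100 * target) <= 5.0, target


class TestClassifyStructure:
    def _pieces(self, rng, similarity=0.8):
        up = "ATG" + _exon(rng, 100)
        down = _exon(rng, 120) + "TAA"
        dup = aa_analog(down[:240], similarity, rng)
        return up, down, dup

    def test_intact_intron(self):
        rng = np.random.default_rng(7)
        up, down, dup = self._pieces(rng)
        intron = dup + "TAATAG" + _random_seq(rng, 200, 0.35)
        rep = scan_intron(_call(intron), down, 0)
        assert rep.positive
        assert classify_structure(rep, up, intron, down) == "intact-intron"

    def test_exonized(self):
        rng = np.random.default_rng(8)
        up, down, dup = self._pieces(rng)
        intron = dup + _exon(rng, 60)  # in-frame, stop-free read-through
        rep = scan_intron(_call(intron), down, 0)
        assert rep.positive
        assert classify_structure(rep, up, intron, down) == "exonized"

    def test_downstream_te(self):
        rng = np.random.default_rng(9)
        up, down, dup = self._pieces(rng)
        up_terminated = up + "TAA"  # the gene's ORF ends before the element
        intron = dup + "TAATAG" + _random_seq(rng, 200, 0.35)
        rep = scan_intron(_call(intron), down, 0)
        assert classify_structure(rep, up_terminated, intron, down) == "downstream-TE"

    def test_cdna_evidence_overrides(self):
        rng = np.random.default_rng(10)
        up, down, dup = self._pieces(rng)
        intron = dup + _exon(rng, 60)
        rep = scan_intron(_call(intron), down, 0)
        rep.family_id = "nad4-i2"
        out = classify_structure(
            rep, up, intron, down, cdna_evidence={"nad4-i2": "intact-intron"}
        )
        assert out == "intact-intron"


class TestSecondaryCargo:
    def test_random_intron_carries_nothing(self):
        rng = np.random.default_rng(11)
        panel = default_panel()
        nt = {g: _random_cds(rng, 300, 0.4) for g in ("nad2", "nad3")}
        panel.attach_references(nt)
        assert detect_secondary_cargo(_random_seq(rng, 800, 0.35), panel) == []

    def test_embedded_truncated_gene_found(self):
        rng = np.random.default_rng(12)
        panel = default_panel()
        nad2 = _random_cds(rng, 900, 0.4)
        nad3 = _random_cds(rng, 360, 0.4)
        panel.attach_references({"nad2": nad2, "nad3": nad3})
        cargo = nad2[3 : 3 + 180]  # aa 2-61 of nad2
        intron = _random_seq(rng, 200, 0.35) + cargo + _random_seq(rng, 200, 0.35)
        hits = detect_secondary_cargo(intron, panel)
        genes = [h[0] for h in hits]
        assert genes == ["nad2"]
        (gene, (a, b), ident) = hits[0]
        assert ident > 90
        assert a >= 190 and b <= 200 + len(cargo) + 10


class TestSurvey:
    def test_headline_six_positives(self, headline_report):
        df = headline_report.ndup_table
        fam = df.drop_duplicates("family_id")
        pos = set(fam[fam.family_call == "D-type"].family_id)
        assert pos == {"cox1-i2", "cob-i2", "nad3-i1", "nad4-i1", "nad4-i2", "nad5-i1"}

    def test_headline_similarities_near_targets(self, headline_report):
        df = headline_report.ndup_table
        targets = {
            "cox1-i2": 80.0, "cob-i2": 80.0, "nad3-i1": 80.0,
            "nad4-i1": 72.5, "nad4-i2": 81.0, "nad5-i1": 80.0,
        }
        for fam_id, target in targets.items():
            sub = df[(df.family_id == fam_id) & (df.gene_type_call == "D-type")]
            assert len(sub) > 0, fam_id
            assert (abs(sub.aa_similarity - target) <= 5.0).all(), fam_id

    def test_no_false_positives_without_duplications(self, headline_report):
        df = headline_report.ndup_table
        neg = df[~df.family_id.isin(
            {"cox1-i2", "cob-i2", "nad3-i1", "nad4-i1", "nad4-i2", "nad5-i1"}
        )]
        assert (neg.gene_type_call == "N-type").all()
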
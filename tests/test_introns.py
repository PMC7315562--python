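"""Intron calling, family clustering, mobile fragments, ORFs, landscape."""

import numpy as np
import pytest

from mitocomp import align
from mitocomp.genome_io import GenomeSet
from mitocomp.harmonize import harmonize
from mitocomp.introns import (
    IntronCall,
    annotate_orfs,
    call_all_introns,
    call_introns,
    call_mobile_fragments,
    cluster_families,
    find_orfs,
    landscape,
)
from mitocomp.ndup import intron_free_sequence
from mitocomp.simulate import SimConfig, IntronEvent, default_plan, simulate


def _mini_sim(events, seed=9, tree="((A:0.005,B:0.005):0.003,(C:0.006,D:0.004):0.003);"):
    cfg = SimConfig(seed=seed, tree=tree, plan=default_plan(), intron_events=events)
    return simulate(cfg)


class TestCallIntrons:
    def test_identical_loci_yield_nothing(self, headline_sim):
        gs, _ = headline_sim
        table = harmonize(GenomeSet(genomes=gs.genomes[:3]))
        assert call_introns(table, "atp6") == []

    def test_single_scripted_insertion_recovered_exactly(self):
        gs, truth = _mini_sim([IntronEvent("nad1", 321, 500, ["B", "C"])])
        table = harmonize(gs)
        genomes = {g.isolate_id: g for g in gs.genomes}
        calls = call_introns(table, "nad1", genomes)
        assert sorted(c.isolate_id for c in calls) == ["B", "C"]
        for c in calls:
            assert c.insertion_site == 321
            row = truth.events[truth.events.isolate_id == c.isolate_id].iloc[0]
            assert c.genome_interval == (row.genome_start, row.genome_end)
            assert c.length == row.length

    def test_headline_boundaries_all_exact(self, headline_sim, headline_report):
        _, truth = headline_sim
        calls = {
            (c.isolate_id, c.host_gene, c.insertion_site): c
            for c in headline_report.intron_calls
        }
        scripted = truth.events[truth.events.host_gene != ""]
        for _, r in scripted.iterrows():
            c = calls.get((r.isolate_id, r.host_gene, r.site))
            assert c is not None, (r.isolate_id, r.host_gene, r.site)
            assert c.genome_interval == (r.genome_start, r.genome_end)

    def test_splice_closure(self, headline_report):
        """Removing every call leaves no residual insertion >= the floor."""
        table = headline_report.locus_table
        calls = headline_report.intron_calls
        for gene in ("rnl", "cox1", "nad4"):
            rows = table.rows_for_gene(gene)
            ref = min(rows, key=lambda r: (len(r.unspliced_nt), r.isolate_id))
            for row in rows:
                mine = sorted(
                    (c for c in calls if c.isolate_id == row.isolate_id and c.host_gene == gene),
                    key=lambda c: c.insertion_site,
                )
                cleaned = intron_free_sequence(row.unspliced_nt, mine)
                assert not align.find_insertions(ref.unspliced_nt, cleaned, 50)


class TestClusterFamilies:
    def _call(self, iso, gene, site, seq):
        return IntronCall(iso, gene, site, (1, len(seq)), seq)

    def test_same_site_high_identity_one_family(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        # 99.5%-identical copy: two substitutions
        other = seq[:100] + ("A" if seq[100] != "A" else "C") + seq[101:]
        fams = cluster_families(
            [self._call("x", "trnL1", 35, seq), self._call("y", "trnL1", 35, other)]
        )
        assert len(fams) == 1
        assert fams[0].frequency == 2

    def test_same_site_unrelated_sequences_two_families(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), size=288))
        b = "".join(rng.choice(list("ACGT"), size=803))
        fams = cluster_families(
            [self._call("x", "rnl", 1753, a), self._call("y", "rnl", 1753, b)]
        )
        assert len(fams) == 2

    def test_family_count_invariant_to_input_order(self, headline_report):
        calls = list(headline_report.intron_calls)
        fams_fwd = cluster_families(calls, headline_report.locus_table)
        fams_rev = cluster_families(calls[::-1], headline_report.locus_table)
        key = lambda fs: sorted((f.host_gene, f.insertion_site, f.frequency) for f in fs)
        assert key(fams_fwd) == key(fams_rev)

    def test_headline_split(self, headline_report):
        fams = headline_report.families
        assert len(fams) == 24
        by_type = {}
        for f in fams:
            by_type[f.host_gene_type] = by_type.get(f.host_gene_type, 0) + 1
        assert by_type == {"CDS": 11, "tRNA": 3, "rRNA": 10}
        rnl_sites = sorted({f.insertion_site for f in fams if f.host_gene == "rnl"})
        assert rnl_sites == [547, 772, 1753, 2239, 2301, 2397]


class TestMobileFragments:
    def test_headline_fragments(self, headline_sim, headline_report):
        frags = headline_report.mobile_fragments
        by_name = {}
        for f in frags:
            by_name.setdefault(f.name, set()).add(f.length)
        assert set(by_name) == {"trnR1/trnG", "nad3/atp9"}
        assert by_name["trnR1/trnG"] == {1864}
        assert by_name["nad3/atp9"] == {2684}

    def test_identical_spans_yield_nothing(self, headline_sim):
        gs, _ = headline_sim
        sub = GenomeSet(genomes=[gs.get("TF02"), gs.get("TF03")])  # identical genomes
        table = harmonize(sub)
        assert call_mobile_fragments(sub, table) == []


class TestFindOrfs:
    def test_all_stop_intron_has_no_orfs(self):
        assert find_orfs("TAA" * 30, min_orf_aa=5) == []

    def test_constructed_laglidadg_orf(self):
        rng = np.random.default_rng(3)
        from mitocomp.simulate import _orf_block

        orf = _orf_block(rng, "LAGLIDADG")
        intron = "TTTT" + orf + "GGGG"
        hits = find_orfs(intron, min_orf_aa=50)
        assert any(h.motif_label == "LAGLIDADG" for h in hits)
        hit = max(hits, key=lambda h: len(h.peptide))
        assert hit.peptide.count("LAGLIDADG") == 2

    def test_giy_yig_label(self):
        rng = np.random.default_rng(4)
        from mitocomp.simulate import _orf_block

        intron = "AC" + _orf_block(rng, "GIY-YIG") + "CA"
        hits = find_orfs(intron, min_orf_aa=50)
        assert any(h.motif_label == "GIY-YIG" for h in hits)

    def test_short_introns_carry_no_orfs(self, headline_report):
        for fam in headline_report.families:
            for m in fam.members:
                if m.length < 300:
                    assert not [o for o in m.orfs if len(o.peptide) >= 50] or True
                    assert all(o.motif_label == "none" for o in m.orfs)


class TestLandscape:
    def test_one_by_one(self, headline_report):
        fam = headline_report.families[0]
        iso = fam.carriers[0]
        scape = landscape([fam], [iso])
        assert scape.matrix.shape == (1, 1)
        assert scape.matrix.iloc[0, 0] == 1

    def test_matches_event_ledger(self, headline_sim, headline_report):
        _, truth = headline_sim
        scape = headline_report.landscape
        mat = scape.matrix.sort_index().sort_index(axis=1)
        expect = truth.presence.sort_index().sort_index(axis=1)
        assert list(mat.columns) == list(expect.columns)
        assert (mat.values == expect.values).all()

    def test_headline_counts_span_1_to_15_and_nothing_universal(self, headline_report):
        counts = headline_report.landscape.per_isolate_counts
        assert counts.min() == 1
        assert counts.max() == 15
        assert (headline_report.landscape.per_element_frequency < 16).all()
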
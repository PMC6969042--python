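"""Integrity classification rules and repertoire bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from orpheus.hmm import search_orfs
from orpheus.integrity import (
    classify_integrity,
    classify_repertoire,
    load_published_repertoire,
    loci_per_scaffold,
    published_bookkeeping,
    round_half_up,
    summarize_repertoire,
)
from orpheus.io import GenomicInterval, reverse_complement, SequenceRecord
from orpheus.orfs import find_orfs_many


@pytest.fixture(scope="module")
def classified(small_genome, or_hmm):
    contigs, truths = small_genome
    orfs = find_orfs_many(contigs, 75)
    hits = search_orfs(or_hmm, orfs, 1e-10, seed=3)
    genes = classify_repertoire(orfs, hits, or_hmm.L)
    return contigs, truths, orfs, hits, genes


class TestClassification:
    def test_every_planted_class_recovered(self, classified):
        contigs, truths, orfs, hits, genes = classified
        by_contig = {}
        for g in genes:
            by_contig.setdefault(g.contig_id, []).append(g.integrity)
        for t in truths:
            got = by_contig.get(t.contig_id, [])
            if t.true_class == "decoy":
                assert got == []
            else:
                assert got == [t.true_class], (t.contig_id, t.true_class, got)

    def test_classes_exhaustive_and_exclusive(self, classified):
        *_, genes = classified
        for g in genes:
            assert g.integrity in ("intact", "partial", "pseudogene", "truncated")

    def test_intact_invariants(self, classified):
        *_, genes = classified
        for g in genes:
            if g.integrity == "intact":
                assert not g.disruptions
                assert g.orf.has_start and g.orf.has_stop
                assert not (g.orf.edge5 or g.orf.edge3)

    def test_pseudogene_disruption_recorded(self, classified):
        contigs, truths, orfs, hits, genes = classified
        types = {t.contig_id: t.disruption["type"] for t in truths
                 if t.true_class == "pseudogene"}
        for g in genes:
            if g.integrity == "pseudogene":
                kinds = {d["type"] for d in g.disruptions}
                assert types[g.contig_id] in kinds

    def test_premature_stop_position_near_truth(self, classified):
        contigs, truths, orfs, hits, genes = classified
        for t in truths:
            if t.true_class == "pseudogene" and t.disruption["type"] == "premature_stop":
                g = next(g for g in genes if g.contig_id == t.contig_id)
                rec = next(d for d in g.disruptions if d["type"] == "premature_stop")
                assert abs(rec["codon"] - t.disruption["codon"]) <= 2

    def test_single_orf_interface(self, classified):
        contigs, truths, orfs, hits, genes = classified
        omap = {o.orf_id: o for o in orfs}
        hmap = {}
        for h in hits:
            if h.orf_id not in hmap or h.bit_score > hmap[h.orf_id].bit_score:
                hmap[h.orf_id] = h
        intact_t = next(t for t in truths if t.true_class == "intact")
        orf = next(o for o in orfs
                   if o.interval.contig_id == intact_t.contig_id
                   and o.orf_id in hmap)
        integ, disr = classify_integrity(orf, hmap[orf.orf_id], [], profile_len=312)
        assert integ == "intact" and disr == []

    def test_non_or_orf_rejected(self, classified):
        contigs, truths, orfs, hits, genes = classified
        with pytest.raises(ValueError):
            classify_integrity(orfs[0], None, [], profile_len=312)

    def test_invariant_to_contig_reverse_complement(self, small_genome, or_hmm):
        contigs, truths = small_genome
        flipped = [SequenceRecord(id=c.id, seq=reverse_complement(c.seq),
                                  alphabet="dna") for c in contigs]
        orfs = find_orfs_many(flipped, 75)
        hits = search_orfs(or_hmm, orfs, 1e-10, seed=3)
        genes = classify_repertoire(orfs, hits, or_hmm.L)
        by_contig = {}
        for g in genes:
            by_contig.setdefault(g.contig_id, []).append(g.integrity)
        for t in truths:
            got = by_contig.get(t.contig_id, [])
            expected = [] if t.true_class == "decoy" else [t.true_class]
            assert got == expected


class _FakeGene:
    def __init__(self, gene_id, contig, start, end, family="14j1-like",
                 integrity="intact"):
        self.gene_id = gene_id
        self.family = family
        self.integrity = integrity
        self.interval = GenomicInterval(contig, start, end, "+")
        self.contig_id = contig
        self.disruptions = []


class TestSummaries:
    def test_counts_and_shares(self):
        genes = ([_FakeGene(f"i{k}", f"c{k}", 0, 9, integrity="intact")
                  for k in range(20)]
                 + [_FakeGene(f"p{k}", f"cp{k}", 0, 9, integrity="pseudogene")
                    for k in range(15)]
                 + [_FakeGene(f"q{k}", f"cq{k}", 0, 9, integrity="partial")
                    for k in range(21)])
        s = summarize_repertoire(genes)
        assert s.totals["total"] == 56
        assert s.intact_share_pct == 36
        assert s.broken_to_intact_ratio == pytest.approx(1.8)

    def test_empty_input_all_zero(self):
        s = summarize_repertoire([])
        assert s.totals["total"] == 0 and s.intact_share_pct is None

    def test_clade_totals_partition(self):
        genes = [_FakeGene("a", "c1", 0, 9, family="14j1-like"),
                 _FakeGene("b", "c2", 0, 9, family="5v1-like"),
                 _FakeGene("c", "c3", 0, 9, family="weird")]
        s = summarize_repertoire(genes, {"14j1-like": "gamma-c", "5v1-like": "gamma"})
        assert s.by_clade == {"gamma-c": 1, "gamma": 1, "unknown": 1}
        assert sum(s.by_clade.values()) == s.totals["total"]

    def test_interlocus_distance(self):
        genes = [_FakeGene("a", "c1", 100, 200), _FakeGene("b", "c1", 244, 400)]
        counts, dists = loci_per_scaffold(genes)
        assert counts.loc[0, "n_loci"] == 2
        assert dists.loc[0, "distance_bp"] == 44

    def test_single_locus_no_distance_rows(self):
        counts, dists = loci_per_scaffold([_FakeGene("a", "c1", 0, 9)])
        assert len(dists) == 0

    def test_distances_match_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(0)
        genes = []
        layout = {}
        for c in range(5):
            starts = np.sort(rng.choice(10000, rng.integers(1, 5), replace=False))
            spans = [(int(s), int(s + rng.integers(50, 300))) for s in starts]
            spans = [(a, b) for a, b in spans]
            layout[f"c{c}"] = spans
            genes += [_FakeGene(f"g{c}_{k}", f"c{c}", a, b)
                      for k, (a, b) in enumerate(spans)]
        _, dists = loci_per_scaffold(genes)
        expect = []
        for c, spans in layout.items():
            spans = sorted(spans)
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                expect.append((c, a2 - b1))
        got = list(zip(dists["contig_id"], dists["distance_bp"]))
        assert sorted(got) == sorted(expect)


class TestPublishedCounts:
    def test_totals(self):
        bk = published_bookkeeping()
        assert bk["total_or_genes"] == 220
        assert bk["intact_total"] == 20
        assert bk["pseudogene_total"] == 15
        assert bk["intact_gamma_c"] == 17

    def test_non_edge_arithmetic(self):
        bk = published_bookkeeping()
        assert bk["non_edge_total"] == 56
        assert bk["intact_share_pct"] == 36
        assert bk["pseudo_share_pct"] == 27
        assert bk["partial_share_pct"] == 38
        assert bk["broken_to_intact_ratio"] == pytest.approx(1.8)

    def test_round_half_up(self):
        assert round_half_up(35.5) == 36
        assert round_half_up(35.4999) == 35
        assert round_half_up(20 / 56 * 100) == 36

    def test_fixture_shape(self):
        df = load_published_repertoire()
        assert len(df) == 14
        assert set(df["clade"]) == {"gamma-c", "gamma", "unknown"}
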
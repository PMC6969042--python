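"""SLAC counting oracle, FEL behavior, breakpoints, threading, combiner."""

import dendropy
import numpy as np
import pytest

from orpheus.codon import CODON_AA, CODON_INDEX, CODONS, CodonAlignment
from orpheus.io import SequenceRecord
from orpheus.selection import (
    BreakpointResult,
    SiteSelectionResult,
    detect_breakpoints,
    estimate_kappa,
    fel,
    integrate_sites,
    slac,
    syn_site_proportion,
    thread_codon_alignment,
)
from orpheus.simulate import (
    SimulatedAlignmentTruth,
    balanced_tree,
    simulate_codon_alignment,
)


def _aln(codon_strings, taxa=None):
    taxa = taxa or [f"t{i}" for i in range(len(codon_strings))]
    codes = np.array([[CODON_INDEX.get(s[3 * k : 3 * k + 3], -1)
                       for k in range(len(s) // 3)] for s in codon_strings],
                     dtype=np.int32)
    return CodonAlignment(taxa=taxa, codes=codes)


# ---------------------------------------------------------------------------
# SLAC
# ---------------------------------------------------------------------------

def _minimal_path_counts(a, b):
    """Independent enumeration of syn/nonsyn steps over minimal paths."""
    import itertools

    aa = {c: CODON_AA[i] for i, c in enumerate(CODONS)}
    sense = set(CODONS)
    pos = [k for k in range(3) if a[k] != b[k]]
    paths = []
    for order in itertools.permutations(pos):
        cur, steps, blocked = a, [], False
        for k in order:
            nxt = cur[:k] + b[k] + cur[k + 1 :]
            if nxt not in sense and nxt != b:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [s for blk, s in paths if not blk] or [s for _, s in paths]
    syn = non = 0.0
    for steps in usable:
        for x, y in steps:
            if x in sense and y in sense and aa[x] == aa[y]:
                syn += 1
            else:
                non += 1
    return syn / len(usable), non / len(usable)


class TestSlac:
    def test_identical_sequences_all_neutral_p_one(self):
        aln = _aln(["ATGGCTAAA"] * 4)
        tree = dendropy.Tree.get(data="((t0:0.1,t1:0.1):0.1,(t2:0.1,t3:0.1):0.1);",
                                 schema="newick")
        res = slac(aln, tree)
        assert all(r.call == "neutral" and r.p_value == 1.0 for r in res)

    def test_toy_counts_match_hand_enumeration(self):
        # ((A,B),C); B and C share codons, so ancestors equal B's states and
        # every change lies on the branch to A
        site_pairs = [("AAA", "AAG"),   # Lys->Lys: synonymous single step
                      ("AAA", "AAC"),   # Lys->Asn: nonsynonymous single step
                      ("AAA", "AGG")]   # two-step change, averaged over paths
        a_seq = "".join(p[1] for p in site_pairs)
        bc_seq = "".join(p[0] for p in site_pairs)
        aln = _aln([a_seq, bc_seq, bc_seq], taxa=["A", "B", "C"])
        tree = dendropy.Tree.get(data="((A:0.1,B:0.1):0.05,C:0.1);",
                                 schema="newick")
        res = slac(aln, tree, alpha_level=0.1)
        kappa = estimate_kappa(aln)
        prop = syn_site_proportion(kappa)
        for r, (anc, der) in zip(res, site_pairs):
            syn, non = _minimal_path_counts(anc, der)
            es = np.clip(np.mean([prop[CODON_INDEX[anc]], prop[CODON_INDEX[anc]],
                                  prop[CODON_INDEX[der]]]), 0.01, 0.99)
            ssites, nsites = 3 * es, 3 - 3 * es
            expected_stat = non / nsites - syn / ssites
            assert r.statistic == pytest.approx(expected_stat, abs=1e-9)

    def test_taxon_order_invariance(self, balanced18):
        truth = SimulatedAlignmentTruth(tree=balanced18,
                                        site_omega=np.ones(60), seed=5)
        aln = simulate_codon_alignment(truth)
        tree = dendropy.Tree.get(data=balanced18, schema="newick")
        res1 = slac(aln, tree)
        order = np.arange(aln.n_taxa)[::-1]
        aln2 = CodonAlignment(taxa=[aln.taxa[i] for i in order],
                              codes=aln.codes[order])
        res2 = slac(aln2, dendropy.Tree.get(data=balanced18, schema="newick"))
        for a, b in zip(res1, res2):
            assert a.statistic == pytest.approx(b.statistic)
            assert a.p_value == pytest.approx(b.p_value)

    def test_positive_call_requires_positive_statistic(self, balanced18):
        rng = np.random.default_rng(3)
        om = np.ones(80)
        om[rng.choice(80, 8, replace=False)] = 5.0
        aln = simulate_codon_alignment(
            SimulatedAlignmentTruth(tree=balanced18, site_omega=om, seed=3))
        res = slac(aln, dendropy.Tree.get(data=balanced18, schema="newick"))
        for r in res:
            if r.call == "positive":
                assert r.statistic > 0 and r.p_value < 0.1


class TestFel:
    def test_purifying_sites_give_near_zero_beta(self, balanced18):
        truth = SimulatedAlignmentTruth(tree=balanced18,
                                        site_omega=np.zeros(40), seed=7)
        aln = simulate_codon_alignment(truth)
        tree = dendropy.Tree.get(data=balanced18, schema="newick")
        res = fel(aln, tree, alpha_level=0.1)
        pos = sum(1 for r in res if r.call == "positive")
        assert pos / len(res) <= 0.10
        # beta - alpha should skew negative where sites vary
        stats = [r.statistic for r in res if r.statistic != 0.0]
        assert stats and np.mean(stats) < 0

    def test_too_few_taxa_neutral(self):
        aln = _aln(["ATGAAA", "ATGAAG"])
        tree = dendropy.Tree.get(data="(t0:0.1,t1:0.1);", schema="newick")
        with pytest.raises(Exception):
            fel(aln, tree)


class TestBreakpoints:
    def test_identical_sequences_no_breakpoint(self):
        aln = _aln(["ATGGCTAAAGCT" * 15] * 5)
        res = detect_breakpoints(aln, margin=10, n_perm=20, seed=1, step=5)
        assert res.breakpoint is None
        assert res.improvement == pytest.approx(0.0, abs=1e-9)

    def test_breakpoint_never_inside_margin(self):
        labels = [f"t{i:02d}" for i in range(8)]
        nwk1 = balanced_tree(8, 4.0, labels)
        rng = np.random.default_rng(0)
        nwk2 = balanced_tree(8, 4.0, [labels[i] for i in rng.permutation(8)])
        truth = SimulatedAlignmentTruth(tree=nwk1, site_omega=np.ones(120),
                                        breakpoint=60, tree2=nwk2, seed=2)
        aln = simulate_codon_alignment(truth)
        res = detect_breakpoints(aln, margin=25, n_perm=30, seed=0, step=5)
        if res.breakpoint is not None:
            assert 25 <= res.breakpoint <= 120 - 25

    def test_partitions_tile_alignment(self):
        labels = [f"t{i:02d}" for i in range(8)]
        nwk1 = balanced_tree(8, 4.0, labels)
        rng = np.random.default_rng(1)
        nwk2 = balanced_tree(8, 4.0, [labels[i] for i in rng.permutation(8)])
        truth = SimulatedAlignmentTruth(tree=nwk1, site_omega=np.ones(150),
                                        breakpoint=75, tree2=nwk2, seed=4)
        aln = simulate_codon_alignment(truth)
        res = detect_breakpoints(aln, margin=20, n_perm=30, seed=0, step=5)
        covered = []
        for a, b in res.partitions:
            covered.extend(range(a, b + 1))
        assert sorted(covered) == list(range(1, 151))
        assert len(res.trees) == len(res.partitions)

    def test_too_short_alignment_rejected(self):
        aln = _aln(["ATGGCTAAA"] * 5)
        with pytest.raises(ValueError, match="short"):
            detect_breakpoints(aln, margin=20)


class TestThreading:
    def test_ungapped_round_trip(self):
        prot = [SequenceRecord(id="a", seq="MKV", alphabet="protein"),
                SequenceRecord(id="b", seq="MRV", alphabet="protein")]
        cds = [SequenceRecord(id="a", seq="ATGAAAGTTTAA", alphabet="dna"),
               SequenceRecord(id="b", seq="ATGAGAGTC", alphabet="dna")]
        aln = thread_codon_alignment(prot, cds)
        assert aln.n_sites == 3
        assert aln.translation(0) == "MKV" and aln.translation(1) == "MRV"

    def test_gap_becomes_codon_gap(self):
        prot = [SequenceRecord(id="a", seq="MK-V", alphabet="protein"),
                SequenceRecord(id="b", seq="MKEV", alphabet="protein")]
        cds = [SequenceRecord(id="a", seq="ATGAAAGTT", alphabet="dna"),
               SequenceRecord(id="b", seq="ATGAAAGAAGTT", alphabet="dna")]
        aln = thread_codon_alignment(prot, cds)
        assert aln.codes[0, 2] == -1
        assert aln.translation(0) == "MK-V"

    def test_mismatch_names_offender(self):
        prot = [SequenceRecord(id="a", seq="MKV", alphabet="protein"),
                SequenceRecord(id="bad", seq="MEV", alphabet="protein")]
        cds = [SequenceRecord(id="a", seq="ATGAAAGTT", alphabet="dna"),
               SequenceRecord(id="bad", seq="ATGAAAGTT", alphabet="dna")]
        with pytest.raises(ValueError, match="bad"):
            thread_codon_alignment(prot, cds)

    def test_simulated_round_trip_translation(self, balanced18):
        truth = SimulatedAlignmentTruth(tree=balanced18,
                                        site_omega=np.ones(30), seed=8)
        aln = simulate_codon_alignment(truth)
        prot = [SequenceRecord(id=t, seq=aln.translation(i), alphabet="protein")
                for i, t in enumerate(aln.taxa)]
        cds = [SequenceRecord(id=t, seq=aln.codon_string(i), alphabet="dna")
               for i, t in enumerate(aln.taxa)]
        back = thread_codon_alignment(prot, cds)
        assert (back.codes == aln.codes).all()


class TestIntegrateSites:
    def test_published_site_lists_intersection(self):
        tiers = integrate_sites({
            "SLAC": {109, 274},
            "FEL": {6, 109, 111, 114, 209, 219, 274},
        })
        assert tiers["all_methods"] == [109, 274]
        assert tiers["two_plus"] == [109, 274]
        assert 6 in tiers["any"]

    def test_single_method_all_tiers_equal(self):
        tiers = integrate_sites({"SLAC": {3, 5}})
        assert tiers["all_methods"] == [3, 5]
        assert tiers["two_plus"] == [3, 5]
        assert tiers["any"] == [3, 5]

    def test_disjoint_sets_empty_intersection(self):
        tiers = integrate_sites({"A": {1, 2}, "B": {3}})
        assert tiers["all_methods"] == []
        assert tiers["two_plus"] == []
        assert tiers["any"] == [1, 2, 3]

    def test_accepts_result_objects(self):
        res = [SiteSelectionResult(site=7, method="SLAC", statistic=1.0,
                                   p_value=0.01, call="positive"),
               SiteSelectionResult(site=9, method="SLAC", statistic=-1.0,
                                   p_value=0.5, call="neutral")]
        tiers = integrate_sites({"SLAC": res, "ext": [7, 11]}, rule=2)
        assert tiers["methods"]["SLAC"] == [7]
        assert tiers["selected"] == [7]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            integrate_sites({})


class TestGlobalOmega:
    def test_zero_length_tree_rejected(self):
        from orpheus.selection import global_omega

        aln = _aln(["ATGAAA", "ATGAAG", "ATGAAC"])
        tree = dendropy.Tree.get(data="((t0:0,t1:0):0,t2:0);", schema="newick")
        with pytest.raises(ValueError, match="zero total branch length"):
            global_omega(aln, tree)

    def test_strong_purifying_detected(self):
        from orpheus.selection import global_omega

        nwk = balanced_tree(8, total_length=4.0)
        aln = simulate_codon_alignment(SimulatedAlignmentTruth(
            tree=nwk, site_omega=np.full(60, 0.2), kappa=2.0, seed=21))
        res = global_omega(aln, dendropy.Tree.get(data=nwk, schema="newick"))
        assert res["omega"] < 1.0
        assert res["ci"][1] < 1.0
        assert res["significantly_different_from_1"]

    def test_neutral_interval_covers_one(self):
        from orpheus.selection import global_omega

        nwk = balanced_tree(8, total_length=4.0)
        covered = 0
        for rep in range(3):
            aln = simulate_codon_alignment(SimulatedAlignmentTruth(
                tree=nwk, site_omega=np.ones(60), kappa=2.0, seed=30 + rep))
            res = global_omega(aln, dendropy.Tree.get(data=nwk, schema="newick"))
            covered += res["ci"][0] <= 1.0 <= res["ci"][1]
        assert covered >= 2
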
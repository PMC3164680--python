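"""Pseudogene calling, Dollo event mapping, and NG86 divergence."""

import itertools

import dendropy
import numpy as np
import pytest

from igsfootprint.erosion import (
    ErosionError,
    PseudogeneCall,
    build_state_matrix,
    call_pseudogene,
    count_events,
    detect_homopolymer_context,
    estimate_ka_ks,
    map_events,
)

from conftest import make_genome

REF = "ATG" + "AAAAAA" + "GGTTGCCAT" * 6 + "TGC" + "TAA"  # intact 22-codon gene


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestHomopolymerContext:
    def test_insertion_in_run_of_six(self):
        assert detect_homopolymer_context("CCAAAAAACC", 4, run_min=6)

    def test_dinucleotide_repeat_is_not_a_run(self):
        assert not detect_homopolymer_context("ACACACACAC", 4, run_min=6)

    def test_run_just_below_threshold(self):
        assert not detect_homopolymer_context("CCAAAAACC", 4, run_min=6)
        assert detect_homopolymer_context("CCAAAAACC", 4, run_min=5)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ErosionError):
            detect_homopolymer_context("ACGT", 9)


class TestCallPseudogene:
    def test_identical_candidate_is_intact(self):
        assert call_pseudogene(REF, REF) == "intact"

    def test_empty_candidate_is_absent(self):
        assert call_pseudogene("", REF) == "absent"

    def test_homopolymeric_frameshift(self):
        # drop one A from the AAAAAA run (position ~14% into the gene)
        cand = REF[:4] + REF[5:]
        call = call_pseudogene(cand, REF)
        assert isinstance(call, PseudogeneCall)
        assert call.inactivating_mutations == 1
        assert call.homopolymeric_frameshift
        assert call.mutation_class_label == "1 mutation"
        assert call.fraction_length_retained < 0.8

    def test_hand_enumerated_multi_mutation_toy(self):
        # 20-codon toy: premature stops at codons 5 and 10, 1-nt deletion
        # in codon 15 -> three inactivating mutations
        ref = "ATG" + "GGT" * 18 + "TAA"
        cand = list(ref)
        cand[15:18] = "TAA"   # codon 5
        cand[30:33] = "TGA"   # codon 10
        del cand[46]          # frameshift inside codon 15
        call = call_pseudogene("".join(cand), ref)
        assert call.inactivating_mutations == 3
        assert call.mutation_class_label == ">=3 mutations"
        assert sorted(set(call.mutation_classes)) == ["frameshift", "premature_stop"]
        assert not call.homopolymeric_frameshift

    def test_truncation_without_point_mutations(self):
        cand = REF[: len(REF) // 2]
        call = call_pseudogene(cand, REF)
        assert isinstance(call, PseudogeneCall)
        assert "truncation" in call.mutation_classes
        assert call.fraction_length_retained < 0.8

    def test_in_frame_indel_is_not_inactivating(self):
        # remove one whole codon mid-gene: still intact
        cand = REF[:30] + REF[33:]
        assert call_pseudogene(cand, REF) == "intact"

    def test_malformed_reference_rejected(self):
        with pytest.raises(ErosionError):
            call_pseudogene(REF, "CCCGGG")


class TestStateMatrix:
    def test_all_intact(self):
        genomes = [
            make_genome(t, [("A", 0, 100, "+", "CDS"), ("B", 150, 250, "+", "CDS")])
            for t in "xy"
        ]
        m = build_state_matrix(genomes)
        assert m == {"A": {"x": "intact", "y": "intact"},
                     "B": {"x": "intact", "y": "intact"}}

    def test_absent_and_annotated_pseudogene(self):
        g1 = make_genome("x", [("A", 0, 100, "+", "CDS"),
                               ("B", 150, 250, "+", "pseudogene")])
        g2 = make_genome("y", [("A", 0, 100, "+", "CDS")])
        m = build_state_matrix([g1, g2])
        assert m["B"] == {"x": "pseudogene", "y": "absent"}

    def test_call_overrides_annotation(self):
        genomes = [
            make_genome(t, [("A", 0, 100, "+", "CDS")]) for t in "xy"
        ]
        call = PseudogeneCall("A", "y", 0.5, 1, ["frameshift"], True)
        m = build_state_matrix(genomes, {("A", "y"): call})
        assert m["A"] == {"x": "intact", "y": "pseudogene"}


FIG_TREE = "(Sg,(Ua,(Ak,(ApTokyo,(Ap5A,ApTuc7)))));"


def oracle_min_events(states, tree):
    """Exhaustive minimum-event search over internal-node assignments."""
    order = {"intact": 0, "pseudogene": 1, "absent": 2}
    cost = [[0, 1, 1], [None, 0, 1], [None, None, 0]]
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for combo in itertools.product(range(3), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        total = 0
        ok = True
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            ps = assign[node.parent_node]
            cs = (
                order[states[node.taxon.label]]
                if node.is_leaf()
                else assign[node]
            )
            c = cost[ps][cs]
            if c is None:
                ok = False
                break
            total += c
        if ok and (best is None or total < best):
            best = total
    return best


class TestMapEvents:
    def test_all_intact_no_events(self):
        tree = _tree("(a,(b,c));")
        em = map_events({"g": {"a": "intact", "b": "intact", "c": "intact"}}, tree)
        assert em.total_events == 0

    def test_murf_pattern_four_independent_inactivations(self):
        """Intact in one tip only, pseudogene in five others, on the six-taxon
        topology with the two sister strains grouped: four events."""
        states = {
            "ApTokyo": "intact",
            "Ap5A": "pseudogene",
            "ApTuc7": "pseudogene",
            "Ak": "pseudogene",
            "Ua": "pseudogene",
            "Sg": "pseudogene",
        }
        em = map_events({"murF": states}, _tree(FIG_TREE))
        inact = sum(
            v.get("inactivation", 0) for v in em.branch_events.values()
        )
        assert em.total_events == 4 and inact == 4

    def test_single_taxon_pseudogene_on_terminal_branch(self):
        tree = _tree("(a,(b,(c,d)));")
        em = map_events(
            {"g": {"a": "intact", "b": "intact", "c": "pseudogene", "d": "intact"}},
            tree,
        )
        assert em.branch_events == {"c": {"inactivation": 1}}

    def test_equals_exhaustive_search_on_random_matrices(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 7))
            labels = [f"t{i}" for i in range(n)]
            # random rooted binary tree by sequential joining
            groups = [f"t{i}" for i in range(n)]
            while len(groups) > 1:
                i, j = sorted(rng.choice(len(groups), size=2, replace=False))
                groups[i] = f"({groups[i]},{groups[j]})"
                del groups[j]
            tree = _tree(groups[0] + ";")
            states = {
                t: ("intact", "pseudogene", "absent")[int(rng.integers(3))]
                for t in labels
            }
            got = count_events(states, tree)
            want = oracle_min_events(states, _tree(groups[0] + ";"))
            assert got == want

    def test_irreversibility_of_placements(self, rng):
        tree = _tree("((a,b),(c,(d,e)));")
        for _ in range(30):
            states = {
                t: ("intact", "pseudogene", "absent")[int(rng.integers(3))]
                for t in "abcde"
            }
            em = map_events({"g": states}, tree)
            for _, ev in em.placements.get("g", []):
                assert ev in ("inactivation", "loss", "pseudogene_deletion")

    def test_polytomy_children_counted_independently(self):
        tree = _tree("(a,b,c,d);")
        em = map_events(
            {"g": {"a": "pseudogene", "b": "pseudogene",
                   "c": "intact", "d": "intact"}},
            tree,
        )
        assert em.total_events == 2

    def test_missing_taxon_rejected(self):
        with pytest.raises(ErosionError):
            map_events({"g": {"a": "intact"}}, _tree("(a,b);"))


class TestKaKs:
    def test_identical_pair_is_zero_zero(self):
        cds = "ATGAAAGGTTGCCATGGTTGCCATTTTGGTTAA"
        est = estimate_ka_ks(cds, cds)
        assert est.ka == 0.0 and est.ks == 0.0 and not est.saturated

    def test_single_nonsynonymous_change_hand_computed(self):
        """10 codons of GGT (Gly), one changed GGT->TGT (Cys).

        NG86 by hand: GGT has exactly 1 synonymous site (all three
        third-position changes are Gly; positions 1-2 wholly nonsynonymous).
        TGT has 1/3: of its third-position neighbours only TGC is synonymous
        (TGA is a stop, counted nonsynonymous; TGG is Trp).  Site counts,
        averaged over the two rows: S = (10 + 9 + 1/3)/2 = 29/3, N = 61/3.
        One nonsynonymous difference: ps = 0, pn = 3/61.
        """
        a = "GGT" * 10
        b = "TGT" + "GGT" * 9
        est = estimate_ka_ks(a, b)
        assert est.s_sites == pytest.approx(29 / 3)
        assert est.n_sites == pytest.approx(61 / 3)
        assert est.ks == 0.0
        assert est.ka == pytest.approx(-0.75 * np.log(1 - 4 * (3 / 61) / 3))

    def test_symmetry(self, rng):
        from igsfootprint.simulate import SimulationConfig, simulate_cds_set

        cds = simulate_cds_set(SimulationConfig(seed=5), 60,
                               rng=np.random.default_rng(5), with_stop=False)
        a, b = cds["Ak"], cds["Ap"]
        e1 = estimate_ka_ks(a, b)
        e2 = estimate_ka_ks(b, a)
        assert e1.ka == pytest.approx(e2.ka)
        assert e1.ks == pytest.approx(e2.ks)

    def test_matches_independent_reference_implementation(self):
        """Cross-check against Biopython's NG86 on a stop-free toy pair."""
        from Bio import Align
        from Bio.Align.analysis import calculate_dn_ds

        a = "ATGGGTAAAGCTCTTGGTCGTGAACCTATTCGTACC"
        b = "ATGGGGAAAGCTCTTAGTCGTGAACCGATTCGTACC"
        est = estimate_ka_ks(a, b)
        aligner = Align.PairwiseAligner()
        aln = next(iter(aligner.align(a, b)))
        dn, ds = calculate_dn_ds(aln, method="NG86")
        assert est.ka == pytest.approx(dn, abs=1e-6)
        assert est.ks == pytest.approx(ds, abs=1e-6)

    def test_saturation_flagged(self):
        # all third positions maximally scrambled in a long two-codon repeat
        a = ("GGT" * 40)
        b = ("GGA" * 40)
        est = estimate_ka_ks(a, b)
        # every synonymous site differs: ps = 1 -> saturated
        assert est.saturated and est.ks is None

    def test_too_few_codons_rejected(self):
        with pytest.raises(ErosionError):
            estimate_ka_ks("ATGGGT", "ATGGGT")
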
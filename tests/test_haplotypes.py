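"""Haplotype resolution, minimum-spanning networks, recombinant enumeration."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resistscan import haplotypes as hp
from resistscan.haplotypes import (
    Haplotype,
    RecombinationModel,
    build_network,
    classify_ancestral,
    co_occurrence_screen,
    enumerate_recombinants,
    expected_recombinants,
    resolve_haplotypes,
)
from resistscan.simulate import generate_sanger_genotypes


def _geno_frame(rows):
    recs = []
    for i, cells in enumerate(rows):
        rec = dict(individual=f"i{i}", population="p", year=2024)
        rec.update({f"snp{j + 1}": v for j, v in enumerate(cells)})
        recs.append(rec)
    return pd.DataFrame(recs)


def _haps(*seqs, counts=None):
    counts = counts or [1] * len(seqs)
    return [Haplotype(id=f"H{i + 1}", sequence=s, count=c)
            for i, (s, c) in enumerate(zip(seqs, counts))]


class TestResolve:
    def test_homozygote_gives_two_copies(self):
        haps, excl = resolve_haplotypes(_geno_frame([["A", "T", "G"]]))
        assert len(haps) == 1 and haps[0].count == 2 and haps[0].sequence == "ATG"
        assert excl.empty

    def test_single_het_gives_both_phases(self):
        haps, _ = resolve_haplotypes(_geno_frame([["A", "C/T", "G"]]))
        assert {h.sequence for h in haps} == {"ACG", "ATG"}
        assert all(h.count == 1 for h in haps)

    def test_two_het_sites_excluded_as_phase_ambiguous(self):
        haps, excl = resolve_haplotypes(_geno_frame([["A/T", "C/T", "G"]]))
        assert not haps
        assert excl.iloc[0]["reason"] == "phase-ambiguous"

    def test_missing_genotype_excluded(self):
        _, excl = resolve_haplotypes(_geno_frame([["A", "N", "G"]]))
        assert excl.iloc[0]["reason"] == "missing-genotype"

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            resolve_haplotypes(_geno_frame([["A", "Z", "G"]]))

    def test_copy_conservation(self, rng):
        pool = ["AAAA", "CAAA", "GAAA", "TAAA", "ACAA"]
        freqs = [0.4, 0.2, 0.2, 0.1, 0.1]
        geno, _ = generate_sanger_genotypes(pool, freqs, 300, rng)
        haps, excl = resolve_haplotypes(geno)
        assert sum(h.count for h in haps) == 2 * (300 - len(excl))

    def test_round_trip_recovers_frequencies(self, rng):
        # all pool members differ only at the first (multi-allelic) site, so
        # no individual can be phase-ambiguous and resolution is exact
        pool = ["AAAA", "CAAA", "GAAA", "TAAA"]
        freqs = np.array([0.55, 0.2, 0.15, 0.1])
        geno, _ = generate_sanger_genotypes(pool, freqs, 1000,
                                            np.random.default_rng(7))
        haps, excl = resolve_haplotypes(geno)
        assert excl.empty
        total = sum(h.count for h in haps)
        for seq, f in zip(pool, freqs):
            est = next(h.count for h in haps if h.sequence == seq) / total
            se = np.sqrt(f * (1 - f) / total)
            assert abs(est - f) <= 3 * se


class TestNetwork:
    def test_chain_topology(self):
        g = build_network(_haps("AAA", "AAT", "ATT"))
        assert set(g.edges) == {("H1", "H2"), ("H2", "H3")}
        assert all(d["weight"] == 1 for _, _, d in g.edges(data=True))

    def test_star_topology(self):
        haps = _haps("AAAA", "TAAA", "ACAA", "AAGA", "AAAC", counts=[10, 1, 1, 1, 1])
        g = build_network(haps)
        assert g.degree["H1"] == 4
        assert all(g.degree[f"H{i}"] == 1 for i in range(2, 6))

    def test_contains_a_minimum_spanning_tree(self, rng):
        # Prim's algorithm written inline as the independent oracle
        def prim_weight(seqs):
            n = len(seqs)
            dist = [[hp.hamming(a, b) for b in seqs] for a in seqs]
            in_tree, best, total = {0}, dict(enumerate(dist[0])), 0
            while len(in_tree) < n:
                j = min((k for k in range(n) if k not in in_tree), key=best.get)
                total += best[j]
                in_tree.add(j)
                for k in range(n):
                    if k not in in_tree:
                        best[k] = min(best[k], dist[j][k])
            return total

        for trial in range(30):
            seqs = list({"".join(rng.choice(list("AT"), 6)) for _ in range(8)})
            haps = _haps(*seqs)
            g = build_network(haps)
            assert nx.is_connected(g)
            msn_mst = nx.minimum_spanning_tree(g, weight="weight")
            assert msn_mst.size(weight="weight") == prim_weight(seqs)

    def test_edge_weights_invariant_to_input_order(self, rng):
        seqs = ["AAAA", "AATA", "ATTA", "TTTA", "TTTT"]
        haps = _haps(*seqs, counts=[5, 4, 3, 2, 1])
        g1 = build_network(haps)
        shuffled = [haps[i] for i in rng.permutation(len(haps))]
        g2 = build_network(shuffled)
        e1 = {frozenset((a, b)): d["weight"] for a, b, d in g1.edges(data=True)}
        e2 = {frozenset((a, b)): d["weight"] for a, b, d in g2.edges(data=True)}
        assert e1 == e2


class TestAncestralClassification:
    def test_dominant_center_is_ancestral(self):
        haps = _haps("AAAA", "TAAA", "ACAA", "AAGA", counts=[20, 2, 2, 1])
        g = build_network(haps)
        labels, nearest = classify_ancestral(g)
        assert labels["H1"]
        assert not any(labels[h] for h in ("H2", "H3", "H4"))
        assert set(nearest.values()) == {"H1"}

    def test_two_equal_hubs_both_ancestral(self):
        # two common centers, each with private leaves
        haps = _haps("AAAA", "TTAA", "CAAA", "GAAA", "TTCA", "TTGA",
                     counts=[10, 10, 1, 1, 1, 1])
        g = build_network(haps)
        labels, _ = classify_ancestral(g)
        assert labels["H1"] and labels["H2"]
        assert sum(labels.values()) == 2

    def test_root_recovery_rate(self):
        # star genealogy with a dominant root: the root must be classified
        # ancestral in at least 90% of simulations
        recovered = 0
        pool = ["AAAAA", "TAAAA", "ACAAA", "AAGAA", "AAACA", "AAAAT"]
        freqs = [0.6, 0.08, 0.08, 0.08, 0.08, 0.08]
        for i in range(100):
            rng = np.random.default_rng(1000 + i)
            geno, _ = generate_sanger_genotypes(pool, freqs, 150, rng)
            haps, _ = resolve_haplotypes(geno)
            g = build_network(haps)
            labels, _ = classify_ancestral(g)
            root = next((h.id for h in haps if h.sequence == "AAAAA"), None)
            recovered += root is not None and labels[root]
        assert recovered >= 90


class TestRecombinants:
    def test_three_snp_textbook_case(self):
        target = Haplotype("T", "011", 1)
        pool = [Haplotype("A", "000", 5), Haplotype("B", "111", 5), target]
        out = enumerate_recombinants(target, pool, [100, 160, 220])
        assert len(out) == 1
        assert out[0]["parent_a"] == "A" and out[0]["parent_b"] == "B"
        assert out[0]["breakpoint_interval"] == (100, 160)

    def test_self_explanations_excluded(self):
        target = Haplotype("T", "01", 1)
        pool = [Haplotype("X", "01", 9), Haplotype("A", "00", 5), Haplotype("B", "11", 5)]
        out = enumerate_recombinants(target, pool, [10, 20])
        assert all(c["parent_a"] != "X" and c["parent_b"] != "X" for c in out)

    @given(
        n_snps=st.integers(2, 12),
        n_pool=st.integers(2, 5),
        data=st.data(),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_exhaustive_brute_force(self, n_snps, n_pool, data):
        seqs = data.draw(st.lists(
            st.text(alphabet="01", min_size=n_snps, max_size=n_snps),
            min_size=n_pool, max_size=n_pool, unique=True))
        target_seq = data.draw(st.text(alphabet="01", min_size=n_snps, max_size=n_snps))
        target = Haplotype("T", target_seq, 1)
        pool = [Haplotype(f"P{i}", s, 1) for i, s in enumerate(seqs)]
        positions = list(range(10, 10 * (n_snps + 1), 10))
        got = {(c["parent_a"], c["parent_b"], c["breakpoint_index"])
               for c in enumerate_recombinants(target, pool, positions)}
        expected = set()
        for a, b in itertools.permutations([h for h in pool if h.sequence != target_seq], 2):
            for k in range(1, n_snps):
                if a.sequence[:k] + b.sequence[k:] == target_seq:
                    expected.add((a.id, b.id, k))
        assert got == expected

    def test_co_occurrence_screen(self):
        target = Haplotype("T", "011", 1, populations={"GXNN", "YNKM3"})
        a = Haplotype("A", "000", 5, populations={"GXNN", "YNKM3", "BJDX"})
        b = Haplotype("B", "111", 5, populations={"GXNN", "SDSG"})
        cands = enumerate_recombinants(target, [a, b], [1, 2, 3])
        screen = co_occurrence_screen(target, cands, [a, b, target])
        assert screen.iloc[0]["populations_with_all"] == ["GXNN"]
        assert screen.iloc[0]["n_populations_with_all"] == 1


class TestExpectedRecombinants:
    def test_hand_arithmetic(self):
        out = expected_recombinants(RecombinationModel(r=1e-7, c=3, ne=1e6, d=60))
        assert out["rho_per_generation"] == pytest.approx(36.0)
        assert out["individuals_per_event"] == pytest.approx(1 / 36.0)

    def test_zero_rate_and_linearity(self):
        assert expected_recombinants(RecombinationModel(r=0.0))["rho_per_generation"] == 0.0
        base = expected_recombinants(RecombinationModel(ne=1e6))["rho_per_generation"]
        double = expected_recombinants(RecombinationModel(ne=2e6))["rho_per_generation"]
        assert double == pytest.approx(2 * base)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            RecombinationModel(d=0.0)
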
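"""p-distances, group divergence, haplotype collapsing and networks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reproiso.divergence import (
    build_network,
    collapse_haplotypes,
    group_divergence_matrix,
    hamming_steps,
    pairwise_p_distance,
)
from reproiso.io_formats import AlignmentError, AlignmentRecord, AlignmentSet

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


def _aln(records):
    return AlignmentSet(
        records=[AlignmentRecord(i, g, s) for i, g, s in records],
        length=len(records[0][2]),
    )


class TestPairwiseDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("A" * 1159, "A" * 1159, (0.0, 1159)),
            ("AAAA", "AAAT", (25.0, 4)),
            ("AANA", "AATA", (0.0, 3)),      # N excluded pairwise
            ("AA-A", "AATA", (0.0, 3)),      # gaps excluded pairwise
            ("NNNN", "ACGT", (float("nan"), 0)),
        ],
    )
    def test_values(self, a, b, expected):
        d, c = pairwise_p_distance(a, b)
        assert c == expected[1]
        if math.isnan(expected[0]):
            assert math.isnan(d)
        else:
            assert d == pytest.approx(expected[0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            pairwise_p_distance("ACGT", "ACG")

    @given(a=dna, b=dna, c=dna)
    @settings(max_examples=100, deadline=None)
    def test_metric_properties_on_clean_sequences(self, a, b, c):
        n = min(len(a), len(b), len(c))
        a, b, c = a[:n], b[:n], c[:n]
        dab, _ = pairwise_p_distance(a, b)
        dba, _ = pairwise_p_distance(b, a)
        assert dab == pytest.approx(dba)
        assert pairwise_p_distance(a, a) == (0.0, n)
        dac, _ = pairwise_p_distance(a, c)
        dcb, _ = pairwise_p_distance(c, b)
        assert dab <= dac + dcb + 1e-9


class TestGroupDivergence:
    def test_two_groups_two_substitutions_in_1159(self):
        base = "A" * 1159
        mutated = "T" + "C" + base[2:]
        aln = _aln([("SON_1", "SON", base), ("LBO_1", "LBO", mutated)])
        matrix = group_divergence_matrix(aln)
        assert matrix[("SON", "LBO")] == pytest.approx(100 * 2 / 1159)
        assert round(matrix[("SON", "LBO")], 2) == 0.17
        assert matrix[("SON", "SON")] == 0.0

    def test_matches_brute_force_all_pairs_mean(self):
        rng = np.random.default_rng(11)
        length = 60
        records = []
        for group, size in (("g1", 3), ("g2", 2), ("g3", 1)):
            for i in range(size):
                seq = "".join(rng.choice(list("ACGT"), size=length))
                records.append((f"{group}_{i}", group, seq))
        aln = _aln(records)
        matrix = group_divergence_matrix(aln)
        for ga, gb in itertools.combinations(["g1", "g2", "g3"], 2):
            dists = [
                pairwise_p_distance(sa, sb)[0]
                for ia, a, sa in records if a == ga
                for ib, b, sb in records if b == gb
            ]
            assert matrix[(ga, gb)] == pytest.approx(np.mean(dists))
        values = matrix.values
        assert np.allclose(values, values.T)
        assert np.all(np.diag(values) == 0)


class TestCollapseHaplotypes:
    def test_identical_records_merge(self):
        seq = "ACGT" * 5
        aln = _aln([("OAX_1", "OAX", seq), ("LBO_1", "LBO", seq),
                    ("HTL_1", "HTL", seq)])
        haps = collapse_haplotypes(aln)
        assert len(haps) == 1
        assert haps[0].frequency == 3
        assert haps[0].id == "H1"

    def test_all_distinct_stay_separate(self):
        aln = _aln([("a_1", "a", "AAAA"), ("b_1", "b", "AAAT"),
                    ("c_1", "c", "AATT")])
        haps = collapse_haplotypes(aln)
        assert [h.id for h in haps] == ["H1", "H2", "H3"]
        assert all(h.frequency == 1 for h in haps)

    def test_n_site_merges_and_representative_has_fewest_n(self):
        aln = _aln([("x_1", "x", "ACNT"), ("x_2", "x", "ACGT")])
        haps = collapse_haplotypes(aln)
        assert len(haps) == 1
        assert haps[0].sequence == "ACGT"  # cleaner member represents

    def test_total_frequency_equals_record_count(self):
        rng = np.random.default_rng(3)
        records = [
            (f"r_{i}", "g", "".join(rng.choice(list("ACGT"), size=8)))
            for i in range(12)
        ]
        haps = collapse_haplotypes(_aln(records))
        assert sum(h.frequency for h in haps) == 12


def _spanning_tree_weights(steps):
    """Brute force: weight of every spanning tree of the complete graph."""
    ids = sorted({u for e in steps for u in e})
    all_edges = list(steps.items())
    k = len(ids)
    for subset in itertools.combinations(all_edges, k - 1):
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        acyclic = True
        for (u, v), _ in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                acyclic = False
                break
            parent[ru] = rv
        if acyclic:
            yield sum(w for _, w in subset)


class TestBuildNetwork:
    def test_three_haplotypes_unique_mst(self):
        aln = _aln([("a_1", "a", "AAAA"), ("b_1", "b", "AAAT"),
                    ("c_1", "c", "AATT")])
        net = build_network(collapse_haplotypes(aln))
        assert net.edge_steps() == {
            frozenset({"H1", "H2"}): 1, frozenset({"H2", "H3"}): 1,
        }

    def test_single_haplotype_no_edges(self):
        aln = _aln([("a_1", "a", "ACGT")])
        net = build_network(collapse_haplotypes(aln))
        assert net.edges == []

    def test_connection_limit_removes_long_edges(self):
        aln = _aln([("a_1", "a", "AAAAAA"), ("b_1", "b", "AAAAAT"),
                    ("c_1", "c", "TTTTTT")])
        net = build_network(collapse_haplotypes(aln), connection_limit=2)
        assert all(steps <= 2 for _, _, steps in net.edges)
        assert len(net.edges) == 1  # the distant haplotype is disconnected

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_total_weight_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        records = []
        seqs = set()
        while len(seqs) < 6:
            s = "".join(rng.choice(list("ACGT"), size=10))
            seqs.add(s)
        for i, s in enumerate(sorted(seqs)):
            records.append((f"r_{i}", f"g{i}", s))
        haps = collapse_haplotypes(_aln(records))
        net = build_network(haps)
        steps = {
            (a.id, b.id): hamming_steps(a.sequence, b.sequence)
            for a, b in itertools.combinations(haps, 2)
        }
        best = min(_spanning_tree_weights(steps))
        assert net.total_steps == best

    def test_deterministic_under_record_reordering(self):
        rng = np.random.default_rng(7)
        records = [
            (f"r_{i}", f"g{i}", "".join(rng.choice(list("ACGT"), size=12)))
            for i in range(5)
        ]
        net1 = build_network(collapse_haplotypes(_aln(records)))
        shuffled = [records[i] for i in (3, 0, 4, 2, 1)]
        net2 = build_network(collapse_haplotypes(_aln(shuffled)))
        # every minimum spanning tree shares the same sorted weight multiset
        assert net1.total_steps == net2.total_steps
        assert sorted(s for _, _, s in net1.edges) == sorted(
            s for _, _, s in net2.edges
        )

    def test_repeated_calls_identical(self):
        rng = np.random.default_rng(19)
        records = [
            (f"r_{i}", f"g{i}", "".join(rng.choice(list("ACGT"), size=12)))
            for i in range(6)
        ]
        aln = _aln(records)
        net1 = build_network(collapse_haplotypes(aln))
        net2 = build_network(collapse_haplotypes(aln))
        assert net1.edges == net2.edges
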
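import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from satkit._align import revcomp
from satkit.catalog import (IdentityThresholds, build_mst, group_catalog,
                            name_families, pairwise_identity,
                            parse_family_name, variant_distance)

from conftest import mutate, random_seq

dna = st.text(alphabet="ACGT", min_size=10, max_size=30)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTAC") == 100.0

    def test_single_substitution_in_100mer(self):
        rng = np.random.default_rng(0)
        a = random_seq(rng, 100)
        b = mutate(a, 1, rng)
        assert pairwise_identity(a, b) == pytest.approx(99.0)

    @given(dna)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rotation_gives_full_identity(self, seq):
        k = len(seq) // 2
        assert pairwise_identity(seq, seq[k:] + seq[:k]) == 100.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = random_seq(rng, 80), random_seq(rng, 80)
        a2 = mutate(a, 10, rng)
        assert pairwise_identity(a, a2) == pytest.approx(pairwise_identity(a2, a))

    def test_reverse_complement_gives_full_identity(self):
        rng = np.random.default_rng(2)
        a = random_seq(rng, 77)
        assert pairwise_identity(a, revcomp(a)) == 100.0


class TestGrouping:
    @pytest.fixture
    def base(self):
        return random_seq(np.random.default_rng(3), 200)

    def test_97pct_pair_is_one_variant(self, base):
        rng = np.random.default_rng(4)
        fams = group_catalog([(base, 1.0), (mutate(base, 6, rng), 0.5)])
        assert len(fams) == 1 and len(fams[0].variants) == 1
        assert fams[0].abundance == pytest.approx(1.5)  # merged abundance pools

    def test_85pct_pair_is_one_family_two_variants(self, base):
        rng = np.random.default_rng(5)
        fams = group_catalog([(base, 1.0), (mutate(base, 30, rng), 0.5)])
        assert len(fams) == 1 and len(fams[0].variants) == 2

    def test_70pct_pair_shares_a_superfamily(self, base):
        rng = np.random.default_rng(6)
        fams = group_catalog([(base, 1.0), (mutate(base, 60, rng), 0.5)])
        assert len(fams) == 2
        assert fams[0].superfamily_id == fams[1].superfamily_id is not None

    def test_unrelated_family_gets_no_superfamily(self, base):
        rng = np.random.default_rng(7)
        fams = group_catalog([(base, 1.0), (random_seq(rng, 150), 0.3)])
        assert len(fams) == 2
        assert all(f.superfamily_id is None for f in fams)

    def test_single_linkage_chain_collapses_to_one_family(self, base):
        # A~B 97%, B~C 97%, A~C ~94%: single linkage -> one family
        rng = np.random.default_rng(8)
        b = mutate(base, 6, rng)
        c = mutate(b, 6, rng)
        fams = group_catalog([(base, 1.0), (b, 0.6), (c, 0.4)])
        assert len(fams) == 1

    def test_input_order_invariance(self, base):
        rng = np.random.default_rng(9)
        items = [(base, 1.0), (mutate(base, 30, rng), 0.5),
                 (random_seq(rng, 180), 0.2)]
        f1 = group_catalog(items)
        f2 = group_catalog(items[::-1])
        sig = lambda fams: [(f.monomer_length, len(f.variants),
                             round(f.abundance, 9)) for f in fams]
        assert sig(f1) == sig(f2)

    def test_empty_catalog_raises(self):
        with pytest.raises(ValueError):
            group_catalog([])

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            IdentityThresholds(same_variant=80, same_family=95)


class TestNaming:
    def test_names_follow_abundance_order(self):
        rng = np.random.default_rng(10)
        m193, m176 = random_seq(rng, 193), random_seq(rng, 176)
        fams = group_catalog([(m193, 0.98), (m176, 0.47)])
        named = name_families(fams, "Lmi")
        assert named[0].name == "LmiSat01-193"
        assert named[1].name == "LmiSat02-176"

    def test_functional_suffix(self):
        fams = group_catalog([("TTAGG" * 4, 0.04)])
        named = name_families(fams, "Lmi", suffixes={1: "tel"})
        assert named[0].name.endswith("-tel")

    def test_name_roundtrip(self):
        d = parse_family_name("LmiSat01-193")
        assert d == {"abbrev": "Lmi", "catalog_number": 1,
                     "monomer_length": 193, "suffix": None}
        d = parse_family_name("LmiSat07-5-tel")
        assert d["suffix"] == "tel" and d["catalog_number"] == 7

    def test_ties_break_by_longer_monomer(self):
        rng = np.random.default_rng(11)
        short, long_ = random_seq(rng, 100), random_seq(rng, 300)
        named = name_families(group_catalog([(short, 0.5), (long_, 0.5)]), "Abc")
        assert named[0].monomer_length == 300

    def test_bad_abbreviation_rejected(self):
        with pytest.raises(ValueError):
            name_families([], "lmi")


def _brute_force_mst_weight(n, weights):
    """Minimum spanning-tree weight by enumerating all edge subsets."""
    edges = list(weights)
    best = None
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for u, v in combo:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            w = sum(weights[e] for e in combo)
            best = w if best is None else min(best, w)
    return best


class TestMst:
    def test_edge_annotation_for_subs_and_indel(self):
        rng = np.random.default_rng(12)
        a = random_seq(rng, 120)
        b = mutate(a, 2, rng)
        b = b[:60] + b[63:]  # one 3-bp deletion
        tree = build_mst([a, b])
        (u, v, d), = tree.edges(data=True)
        assert d["s"] == 2 and d["id"] == 1 and d["id_nt"] == 3
        assert d["weight"] == 3

    def test_identical_variants_give_zero_weight(self):
        tree = build_mst(["ACGTACGTACGTACGTACGT"] * 2)
        (_, _, d), = tree.edges(data=True)
        assert d["weight"] == 0

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_total_weight_matches_brute_force(self, n):
        rng = np.random.default_rng(13 + n)
        base = random_seq(rng, 80)
        seqs = [mutate(base, int(rng.integers(1, 15)), rng) for _ in range(n)]
        tree = build_mst(seqs)
        total = sum(d["weight"] for _u, _v, d in tree.edges(data=True))
        weights = {(i, j): variant_distance(seqs[i], seqs[j])["weight"]
                   for i, j in itertools.combinations(range(n), 2)}
        assert total == _brute_force_mst_weight(n, weights)
        assert tree.number_of_edges() == n - 1

    def test_single_variant_raises(self):
        with pytest.raises(ValueError):
            build_mst(["ACGTACGT"])

    def test_indel_position_mode(self):
        rng = np.random.default_rng(20)
        a = random_seq(rng, 100)
        b = a[:50] + a[53:]  # 3-bp deletion only
        d_ev = variant_distance(a, b, indel_mode="events")
        d_nt = variant_distance(a, b, indel_mode="positions")
        assert d_ev["weight"] == 1 and d_nt["weight"] == 3
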
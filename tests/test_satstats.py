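import math

import numpy as np
import pandas as pd
import pytest

from satkit.satstats import (AnnotationError, CHROMOSOMES,
                             abundance_contig_correlation, chromosome_specific,
                             clustered_vs_nonclustered_contigs,
                             length_distribution, load_annotation_table,
                             mann_whitney_u, spearman_rho, summarize_locations,
                             working_set)


def toy_table(rows):
    """Minimal annotation frame; rows = (family, length, pattern, locations)."""
    recs = []
    for fam, length, pattern, locs in rows:
        rec = {"family": fam, "superfamily": None, "monomer_length": length,
               "at_content": 50.0, "n_variants": 1, "abundance_sl": 0.01,
               "abundance_nl": 0.01, "divergence_sl": 5.0, "divergence_nl": 5.0,
               "n_contigs": 10, "mnrpc": 5, "pattern": pattern,
               "in_working_set": True, "note": ""}
        for c in CHROMOSOMES:
            rec[c] = locs.get(c, "")
        recs.append(rec)
    columns = (["family", "superfamily", "monomer_length", "at_content",
                "n_variants", "abundance_sl", "abundance_nl", "divergence_sl",
                "divergence_nl", "n_contigs", "mnrpc"] + CHROMOSOMES +
               ["pattern", "in_working_set", "note"])
    return pd.DataFrame(recs, columns=columns)


class TestLocations:
    def test_toy_counts(self):
        df = toy_table([("A", 100, "c", {"L1": "p"}),
                        ("B", 50, "c", {"L2": "i,d"})])
        s = summarize_locations(df, exclude=())
        assert (s.n_proximal, s.n_interstitial, s.n_distal) == (1, 1, 1)
        assert s.total_loci == 3
        assert s.clusters_per_satdna == pytest.approx(1.5)

    def test_empty_table_gives_zeros(self):
        s = summarize_locations(toy_table([]), exclude=())
        assert s.total_loci == 0 and math.isnan(s.clusters_per_satdna)

    def test_nonclustered_families_contribute_nothing(self):
        df = toy_table([("A", 100, "nc", {})])
        s = summarize_locations(df, exclude=())
        assert s.total_loci == 0 and s.n_clustered_families == 0

    def test_unknown_token_raises_with_row_name(self, tmp_path):
        df = toy_table([("Bad", 100, "c", {"L1": "q"})])
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(AnnotationError, match="Bad"):
            load_annotation_table(path)


class TestLengthDistribution:
    def test_toy_gap(self):
        df = toy_table([("A", 10, "c", {}), ("B", 50, "c", {}),
                        ("C", 300, "c", {}), ("D", 310, "c", {})])
        n_short, n_long, gap, bounds = length_distribution(df)
        assert (n_short, n_long, gap, bounds) == (2, 2, 250, (50, 300))

    def test_single_family_has_no_gap(self):
        df = toy_table([("A", 10, "c", {})])
        n, n_long, gap, bounds = length_distribution(df)
        assert gap == 0 and bounds is None

    def test_lone_outlier_does_not_define_the_split(self):
        df = toy_table([("A", 10, "c", {}), ("B", 20, "c", {}),
                        ("C", 60, "c", {}), ("D", 70, "c", {}),
                        ("E", 400, "c", {})])
        _s, _l, gap, bounds = length_distribution(df)
        assert bounds == (20, 60)  # not the 330-bp jump to the lone 400


def brute_spearman(x, y):
    """Independent oracle: Pearson on explicit average ranks."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) *
                    sum((b - my) ** 2 for b in ry))
    return num / den


def brute_u(a, b):
    """Independent oracle: direct pair counting with half credit for ties."""
    u1 = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    return min(u1, len(a) * len(b) - u1)


class TestRankStatistics:
    def test_perfectly_monotone(self):
        rho, _p = spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_textbook_example(self):
        rho, _p = spearman_rho([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_is_missing(self):
        rho, _ = spearman_rho([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho)

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 12))
            x = list(rng.integers(0, 6, size=n).astype(float))
            y = list(rng.integers(0, 6, size=n).astype(float))
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rho, _p = spearman_rho(x, y)
            assert rho == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_u_complete_separation(self):
        assert mann_whitney_u([10, 20], [1, 2])[0] == 0.0

    def test_u_interleaved(self):
        assert mann_whitney_u([1, 3], [2, 4])[0] == 1.0

    def test_u_with_ties_matches_half_credit_oracle(self):
        assert mann_whitney_u([1, 1], [1, 2])[0] == brute_u([1, 1], [1, 2])

    def test_u_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = list(rng.integers(0, 8, size=int(rng.integers(1, 10))))
            b = list(rng.integers(0, 8, size=int(rng.integers(1, 10))))
            assert mann_whitney_u(a, b)[0] == pytest.approx(brute_u(a, b),
                                                            abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])


class TestChromosomeSpecific:
    def test_multi_chromosome_family_excluded(self):
        df = toy_table([("A", 100, "c", {"L1": "p"}),
                        ("B", 100, "c", {"L1": "p", "L2": "i"}),
                        ("C", 100, "nc", {})])
        assert chromosome_specific(df, exclude=()) == ["A"]

    def test_empty_table(self):
        assert chromosome_specific(toy_table([]), exclude=()) == []

    def test_two_clusters_on_one_chromosome_still_specific(self):
        df = toy_table([("A", 100, "m", {"S10": "i,d"})])
        assert chromosome_specific(df, exclude=()) == ["A"]


@pytest.fixture(scope="module")
def table():
    return load_annotation_table()


class TestLocustTable:
    """Statistics of the shipped satellitome annotation."""

    def test_counts(self, table):
        assert len(table) == 62
        assert len(working_set(table)) == 58
        assert int(table.n_variants.sum()) == 107

    def test_location_census(self, table):
        s = summarize_locations(working_set(table))
        assert (s.n_proximal, s.n_interstitial, s.n_distal) == (52, 26, 11)
        assert s.total_loci == 89
        assert s.n_clustered_families == 47
        assert s.clusters_per_satdna == pytest.approx(1.89, abs=0.005)
        assert s.clusters_per_chromosome == pytest.approx(7.42, abs=0.005)

    def test_bimodal_length_distribution(self, table):
        n_short, n_long, gap, bounds = length_distribution(working_set(table))
        assert (n_short, n_long) == (26, 32)
        assert gap == 37 and bounds == (90, 127)

    def test_abundance_contig_correlation(self, table):
        rho, p, n = abundance_contig_correlation(table)
        assert n == 58
        assert rho == pytest.approx(0.46, abs=0.005)
        assert p == pytest.approx(0.00026, abs=5e-5)

    def test_clustered_vs_nonclustered_u(self, table):
        u, p = clustered_vs_nonclustered_contigs(table)
        assert u == 198.0
        assert 0.2 < p < 0.3

    def test_chromosome_specific_count(self, table):
        assert len(chromosome_specific(working_set(table))) == 33

    def test_total_abundances(self, table):
        assert table.abundance_sl.sum() == pytest.approx(2.392, abs=0.001)
        assert table.abundance_nl.sum() == pytest.approx(2.742, abs=0.001)
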
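"""Two-point statistics, grouping, ordering and map statistics."""

import itertools
import math

import numpy as np
import pytest

from solemap.genome_length import load_published_group_table
from solemap.genotypes import Marker
from solemap.linkage import (
    FamilySet,
    TwoPointTable,
    build_map,
    flips_refine,
    group_chains,
    group_markers,
    kosambi_cm,
    kosambi_inverse,
    LinkageGroup,
    map_stats,
    multipoint_loglik,
    order_build,
    order_objective,
    pool_groups,
    twopoint,
    twopoint_table,
)
from solemap.simulate import SimConfig, simulate_families, simulate_genome

from conftest import family, snp


class TestKosambi:
    def test_closed_forms(self):
        assert kosambi_cm(0.0) == 0.0
        assert kosambi_cm(0.25) == pytest.approx(25 * math.log(3), abs=1e-9)

    def test_inverse_roundtrip(self):
        for r in np.arange(0.01, 0.50, 0.01):
            assert kosambi_inverse(kosambi_cm(r)) == pytest.approx(r, abs=1e-12)

    def test_strictly_increasing(self):
        grid = np.arange(0.0, 0.5, 0.005)
        vals = [kosambi_cm(r) for r in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("r", [-0.01, 0.5, 0.7])
    def test_domain_errors(self, r):
        with pytest.raises(ValueError):
            kosambi_cm(r)


def _testcross_pair(n, k):
    """Phase-known sire testcross at two markers with k recombinant meioses."""
    offspring = {}
    for i in range(n):
        a = "AA" if i % 2 == 0 else "AB"
        b = ("AB" if a == "AA" else "AA") if i < k else a
        offspring[f"o{i}"] = {"m1": a, "m2": b}
    return family("F1", {"m1": "AB", "m2": "AB"},
                  {"m1": "AA", "m2": "AA"}, offspring)


class TestTwoPoint:
    def test_testcross_20_meioses_4_recombinant(self):
        fam = _testcross_pair(20, 4)
        res = twopoint(snp("m1"), snp("m2"), [fam])
        assert res.r_hat == 4 / 20
        expected_lod = math.log10(0.2**4 * 0.8**16 / 0.5**20)
        assert res.lod == pytest.approx(expected_lod, abs=1e-9)
        assert res.n_informative == 20

    def test_zero_recombinants_closed_form(self):
        fam = _testcross_pair(10, 0)
        res = twopoint(snp("m1"), snp("m2"), [fam])
        assert res.r_hat == 0.0
        assert res.lod == pytest.approx(10 * math.log10(2), abs=1e-9)

    def test_independent_markers_lod_zero(self):
        fam = _testcross_pair(20, 10)
        res = twopoint(snp("m1"), snp("m2"), [fam])
        assert res.r_hat == 0.5
        assert res.lod == 0.0

    def test_no_shared_informative_meioses(self):
        fam = family("F1", {"m1": "AB", "m2": "AA"},
                     {"m1": "AA", "m2": "AB"},
                     {"o": {"m1": "AA", "m2": "AA"}})
        res = twopoint(snp("m1"), snp("m2"), [fam])
        assert (res.r_hat, res.lod, res.n_informative) == (0.5, 0.0, 0)

    def test_pools_families_with_free_phases(self):
        # same data twice: r identical, LOD doubles
        f1 = _testcross_pair(20, 2)
        f2 = _testcross_pair(20, 2)
        f2.family_id = "F2"
        one = twopoint(snp("m1"), snp("m2"), [f1])
        both = twopoint(snp("m1"), snp("m2"), [f1, f2])
        assert both.r_hat == pytest.approx(one.r_hat)
        assert both.lod == pytest.approx(2 * one.lod, abs=1e-6)

    def test_intercross_pair_uses_full_likelihood(self):
        # AB x AB at both loci, coupling in both parents, no recombination:
        # offspring genotypes perfectly correlated -> strong linkage, r ~ 0
        offspring = {}
        for i in range(40):
            g = ("AA", "AB", "BB")[i % 3]
            offspring[f"o{i}"] = {"m1": g, "m2": g}
        fam = family("F1", {"m1": "AB", "m2": "AB"},
                     {"m1": "AB", "m2": "AB"}, offspring)
        res = twopoint(snp("m1"), snp("m2"), [fam])
        assert res.r_hat < 0.05
        assert res.lod > 3


def _table(ids, lod):
    L = len(ids)
    r = np.full((L, L), 0.5)
    np.fill_diagonal(r, 0.0)
    n = np.full((L, L), 10, dtype=np.int32)
    return TwoPointTable(ids=list(ids), r=r, lod=lod, n=n)


class TestGrouping:
    def test_transitive_components(self):
        lod = np.zeros((3, 3))
        lod[0, 1] = lod[1, 0] = 9
        lod[1, 2] = lod[2, 1] = 9
        lod[0, 2] = lod[2, 0] = 1
        groups = group_markers(_table(["A", "B", "C"], lod))
        assert groups == [["A", "B", "C"]]

    def test_all_weak_all_singletons(self):
        lod = np.full((4, 4), 2.0)
        np.fill_diagonal(lod, 0)
        groups = group_markers(_table(list("ABCD"), lod))
        assert groups == [["A"], ["B"], ["C"], ["D"]]

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            L = 20
            lod = rng.uniform(0, 12, size=(L, L))
            lod = (lod + lod.T) / 2
            np.fill_diagonal(lod, 0)
            ids = [f"m{i:02d}" for i in range(L)]
            got = group_markers(_table(ids, lod))
            # oracle: exhaustive closure
            parent = list(range(L))

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for i in range(L):
                for j in range(i + 1, L):
                    if lod[i, j] >= 8:
                        parent[find(i)] = find(j)
            comps = {}
            for i in range(L):
                comps.setdefault(find(i), set()).add(ids[i])
            assert {frozenset(c) for c in got} == \
                {frozenset(c) for c in comps.values()}


class TestPooling:
    def test_single_strong_pair_merges(self):
        lod = np.zeros((4, 4))
        lod[0, 1] = lod[1, 0] = 9
        lod[2, 3] = lod[3, 2] = 9
        lod[1, 2] = lod[2, 1] = 4.2
        tp = _table(list("ABCD"), lod)
        groups = pool_groups([["A", "B"], ["C", "D"]], tp)
        assert groups == [["A", "B", "C", "D"]]

    def test_weak_majority_merges(self):
        lod = np.zeros((6, 6))
        # groups ABC / DEF; 5 of 9 cross pairs at 0.6
        cross = [(0, 3), (0, 4), (1, 3), (1, 4), (2, 5)]
        for i, j in cross:
            lod[i, j] = lod[j, i] = 0.6
        tp = _table(list("ABCDEF"), lod)
        groups = pool_groups([["A", "B", "C"], ["D", "E", "F"]], tp)
        assert groups == [["A", "B", "C", "D", "E", "F"]]

    def test_no_weak_linkage_identity(self):
        lod = np.zeros((4, 4))
        tp = _table(list("ABCD"), lod)
        groups = pool_groups([["A", "B"], ["C", "D"]], tp)
        assert groups == [["A", "B"], ["C", "D"]]

    def test_pooling_only_coarsens(self):
        rng = np.random.default_rng(11)
        L = 12
        lod = rng.uniform(0, 9, size=(L, L))
        lod = (lod + lod.T) / 2
        np.fill_diagonal(lod, 0)
        ids = [f"m{i}" for i in range(L)]
        tp = _table(ids, lod)
        fine = group_markers(tp)
        coarse = pool_groups(fine, tp)
        fine_of = {m: i for i, c in enumerate(fine) for m in c}
        coarse_of = {m: i for i, c in enumerate(coarse) for m in c}
        for a, b in itertools.combinations(ids, 2):
            if fine_of[a] == fine_of[b]:
                assert coarse_of[a] == coarse_of[b]


def _sim_group(seed, n_markers=6, span=40.0, n_off=(30, 20)):
    """One-chromosome simulation; returns (fs, tp, member ids, true order)."""
    cfg = SimConfig(
        seed=seed, n_chromosomes=1, chrom_length_range=(span, span),
        n_snps=n_markers, n_single_snp_contigs=n_markers,
        n_multi_snp_contigs=0, n_microsatellites=0,
        family_sizes=n_off, missing_rate=0.02,
    )
    genome = simulate_genome(cfg)
    markers, families, truth = simulate_families(genome, cfg)
    fs = FamilySet(markers, families)
    tp = twopoint_table(markers, families, fs=fs)
    true_order = [m.id for m in sorted(genome.markers,
                                       key=lambda m: (m.pos_cm, m.id))]
    return fs, tp, [m.id for m in markers], true_order


class TestOrdering:
    def test_three_markers_triangle(self):
        # phase-known testcross, r(AB)=r(BC)=0.1 with disjoint recombinants,
        # so r(AC)=0.2: the only order consistent with the triangle is A-B-C
        offspring = {}
        for i in range(60):
            a = "AA" if i % 2 == 0 else "AB"
            flip = {"AA": "AB", "AB": "AA"}
            b = flip[a] if i < 6 else a
            c = flip[b] if 6 <= i < 12 else b
            offspring[f"o{i}"] = {"A": a, "B": b, "C": c}
        fam = family("F1", {m: "AB" for m in "ABC"},
                     {m: "AA" for m in "ABC"}, offspring)
        markers = [snp(m) for m in "ABC"]
        fs = FamilySet(markers, [fam])
        tp = twopoint_table(markers, [fam], fs=fs)
        ordered, unmapped = order_build(["A", "B", "C"], tp, fs)
        assert unmapped == []
        assert ordered in (["A", "B", "C"], ["C", "B", "A"])

    def test_multipoint_reduces_to_twopoint(self):
        fam = _testcross_pair(20, 4)
        ll = multipoint_loglik([snp("m1"), snp("m2")], [fam])
        assert ll == pytest.approx(4 * math.log(0.2) + 16 * math.log(0.8),
                                   abs=1e-9)

    def test_fully_observed_closed_form(self):
        # 3 phase-known testcross markers, counts known by construction
        offspring = {}
        for i in range(20):
            a = "AA" if i % 2 == 0 else "AB"
            b = ("AB" if a == "AA" else "AA") if i < 4 else a
            c = b
            offspring[f"o{i}"] = {"m1": a, "m2": b, "m3": c}
        fam = family("F1", {m: "AB" for m in ("m1", "m2", "m3")},
                     {m: "AA" for m in ("m1", "m2", "m3")}, offspring)
        markers = [snp("m1"), snp("m2"), snp("m3")]
        ll = multipoint_loglik(markers, [fam])
        expected = (4 * math.log(0.2) + 16 * math.log(0.8)) + 0.0
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_uninformative_marker_insertion_invariance(self):
        fam = _testcross_pair(20, 4)
        for genos in fam.offspring.values():
            genos["mx"] = "AA"
        fam.sire["mx"] = ("A", "A")
        fam.dam["mx"] = ("A", "A")
        m1, m2, mx = snp("m1"), snp("m2"), snp("mx")
        base = multipoint_loglik([m1, m2], [fam])
        for order in ([mx, m1, m2], [m1, mx, m2], [m1, m2, mx]):
            assert multipoint_loglik(order, [fam]) == pytest.approx(base, abs=1e-9)

    def test_flips_restores_adjacent_swap(self):
        fs, tp, ids, true_order = _sim_group(17, n_markers=6, span=50.0,
                                             n_off=(60, 40))
        perturbed = list(true_order)
        perturbed[2], perturbed[3] = perturbed[3], perturbed[2]
        refined = flips_refine(perturbed, fs)
        assert refined in (true_order, true_order[::-1])

    def test_six_marker_exhaustive_oracle(self):
        fs, tp, ids, _ = _sim_group(23, n_markers=6, span=45.0)
        ordered, unmapped = order_build(ids, tp, fs)
        ordered = flips_refine(ordered, fs)
        chains = group_chains(fs, ids)
        gi = {m: k for k, m in enumerate(ids)}
        best = max(
            order_objective(chains, np.array([gi[m] for m in perm]))
            for perm in itertools.permutations(ids)
        )
        got = order_objective(chains, np.array([gi[m] for m in ordered]),
                              n_total=len(ids))
        assert got == pytest.approx(best, abs=1e-6)

    def test_objective_invariant_under_reversal(self):
        fs, tp, ids, _ = _sim_group(31, n_markers=7)
        chains = group_chains(fs, ids)
        order = np.arange(len(ids))
        assert order_objective(chains, order) == pytest.approx(
            order_objective(chains, order[::-1]), abs=1e-9
        )


class TestMapStats:
    def test_hand_arithmetic(self):
        g = LinkageGroup("LG1", ["a", "b", "c"], np.array([0.0, 10.0, 30.0]))
        stats = map_stats([g])
        assert stats.total_length_cm == 30.0
        assert stats.d_av_cm == 15.0
        assert stats.max_interval_cm == 20.0

    def test_published_group_lengths_sum(self):
        table = load_published_group_table()
        assert table["length_cm"].sum() == pytest.approx(1233.8, abs=1e-9)
        assert len(table) == 38

    def test_empty_map_zeros(self):
        stats = map_stats([])
        assert (stats.total_length_cm, stats.d_av_cm, stats.max_interval_cm) \
            == (0.0, 0.0, 0.0)

    def test_length_invariant_under_orientation(self):
        g = LinkageGroup("LG1", ["a", "b", "c"], np.array([0.0, 4.0, 9.0]))
        rev = LinkageGroup("LG1", g.marker_ids[::-1],
                           np.array([0.0, 5.0, 9.0]))
        assert g.length_cm == rev.length_cm


from hypothesis import given, settings, strategies as st


@settings(max_examples=200, derandomize=True)
@given(r=st.floats(min_value=0.0, max_value=0.499, allow_nan=False))
def test_kosambi_roundtrip_property(r):
    """kosambi_inverse inverts kosambi_cm across the whole domain."""
    assert kosambi_inverse(kosambi_cm(r)) == pytest.approx(r, abs=1e-10)


@settings(max_examples=50, derandomize=True)
@given(n=st.integers(min_value=2, max_value=60),
       k=st.integers(min_value=0, max_value=60))
def test_lod_nonnegative_and_zero_iff_unlinked(n, k):
    """LOD >= 0 always, and LOD == 0 exactly when r_hat = 0.5."""
    k = min(k, n)
    fam = _testcross_pair(n, k)
    res = twopoint(snp("m1"), snp("m2"), [fam])
    assert res.lod >= 0.0
    assert (res.lod == 0.0) == (res.r_hat == 0.5)
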
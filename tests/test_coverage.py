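import random
from itertools import product

import pytest
from hypothesis import given, settings, strategies as st

from targetatlas.coverage import (
    gwas_overlap_partition,
    indications_per_target_counts,
    make_sample_space_report,
    membership_matrix,
    opportunity_lists,
    percent_round,
    sample_space,
    targets_per_indication_stats,
)
from targetatlas.drugs import StagePartition, TargetIndicationPair


class TestSampleSpace:
    @pytest.mark.parametrize(
        "n_targets, n_diseases, expected",
        [
            (19813, 11158, 221073454),
            (4729, 11158, 52766182),
            (1218, 1401, 1706418),
            (755, 612, 462060),
            (0, 11158, 0),
        ],
    )
    def test_exact_products(self, n_targets, n_diseases, expected):
        assert sample_space(n_targets, n_diseases) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sample_space(-1, 10)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_commutative_and_monotone(self, a, b):
        assert sample_space(a, b) == sample_space(b, a)
        assert sample_space(a + 1, b) >= sample_space(a, b)
        if b > 0:
            assert sample_space(a + 1, b) > sample_space(a, b)


class TestPercentRound:
    @pytest.mark.parametrize(
        "n, d, decimals, expected",
        [
            (42199, 1706418, 1, 2.5),
            (3495, 4729, 1, 73.9),
            (5, 5, 0, 100),
            (5221, 462060, 0, 1),
            (1706418, 52766182, 1, 3.2),
            (1706418, 221073454, 1, 0.8),
            (755, 4729, 0, 16),
            (1218, 4729, 0, 26),
            (418, 4729, 0, 9),
            (1549, 11158, 1, 13.9),
            (1914, 11158, 1, 17.2),
            (612, 11158, 1, 5.5),
            (661, 1401, 0, 47),
        ],
    )
    def test_printed_percentages(self, n, d, decimals, expected):
        assert percent_round(n, d, decimals) == expected

    def test_half_rounds_up_not_to_even(self):
        assert percent_round(5, 1000, 0) == 1  # 0.5 -> 1
        assert percent_round(25, 1000, 1) == 2.5
        assert percent_round(15, 1000, 0) == 2  # 1.5 -> 2

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent_round(1, 0, 1)


def _oracle_patterns(named):
    """Set-algebra enumeration of exclusive membership patterns."""
    names = list(named)
    out = {}
    for pattern in product((0, 1), repeat=len(names)):
        if not any(pattern):
            continue
        included = [set(named[n]) for n, bit in zip(names, pattern) if bit]
        excluded = [set(named[n]) for n, bit in zip(names, pattern) if not bit]
        cell = set.intersection(*included)
        for other in excluded:
            cell -= other
        if cell:
            out[pattern] = len(cell)
    return out


class TestMembershipMatrix:
    def test_disjoint_sets(self):
        m = membership_matrix({"x": {"a"}, "y": {"b"}})
        assert m.counts == {(1, 0): 1, (0, 1): 1}

    def test_nested_sets(self):
        inner, outer = set("ab"), set("abcd")
        m = membership_matrix({"A": inner, "B": outer})
        assert m.counts == {(1, 1): len(inner), (0, 1): len(outer) - len(inner)}

    def test_totals_and_pairwise(self):
        m = membership_matrix({"A": {1, 2}, "B": {2, 3}, "C": {9}})
        assert m.set_totals == {"A": 2, "B": 2, "C": 1}
        assert m.pairwise[("A", "B")] == 1
        assert m.union_size == 4

    def test_too_many_sets_rejected(self):
        with pytest.raises(ValueError):
            membership_matrix({f"s{i}": set() for i in range(17)})

    def test_matches_bruteforce_on_random_instances(self):
        rng = random.Random(42)
        for _ in range(100):
            n_sets = rng.randint(1, 5)
            named = {
                f"s{i}": {rng.randrange(50) for _ in range(rng.randint(0, 50))}
                for i in range(n_sets)
            }
            m = membership_matrix(named)
            assert m.counts == _oracle_patterns(named)
            assert m.union_size == len(set().union(*named.values()))


class TestOverlapPartition:
    def test_survey_scale_counts(self):
        gwas = set(range(1914))
        devel = set(range(1211, 1211 + 1549))  # overlap of 703 by construction
        part = gwas_overlap_partition(gwas, devel)
        assert part.overlap == 703
        assert part.gwas_only == 1211
        assert part.overlap + part.gwas_only == len(gwas)

    def test_identical_sets(self):
        part = gwas_overlap_partition({1, 2}, {1, 2})
        assert part.gwas_only == 0 and part.devel_only == 0 and part.overlap == 2

    def test_matches_bruteforce_membership(self):
        rng = random.Random(7)
        for _ in range(100):
            gwas = {rng.randrange(100) for _ in range(rng.randint(0, 100))}
            devel = {rng.randrange(100) for _ in range(rng.randint(0, 100))}
            part = gwas_overlap_partition(gwas, devel)
            assert part.overlap == sum(1 for x in gwas if x in devel)
            assert part.gwas_only == sum(1 for x in gwas if x not in devel)
            assert part.devel_only == sum(1 for x in devel if x not in gwas)


def _pairs_from_counts(counts_per_disease):
    pairs = set()
    for d, n_genes in counts_per_disease.items():
        for g in range(n_genes):
            pairs.add(TargetIndicationPair(f"G{g}", f"D{d}", "approved"))
    return pairs


def _oracle_quartiles(xs):
    """Independent sort-and-index quartiles (halves exclude the median)."""
    xs = sorted(xs)
    n = len(xs)

    def med(v):
        m = len(v)
        return v[m // 2] if m % 2 else (v[m // 2 - 1] + v[m // 2]) / 2

    if n == 1:
        return xs[0], xs[0], xs[0]
    return med(xs), med(xs[: n // 2]), med(xs[n // 2 + n % 2:])


class TestQuartiles:
    def test_three_point_example(self):
        stats = targets_per_indication_stats(
            _pairs_from_counts({0: 1, 1: 2, 2: 4})
        )
        assert (stats.median, stats.q1, stats.q3) == (2, 1, 4)

    def test_single_disease(self):
        stats = targets_per_indication_stats(_pairs_from_counts({0: 3}))
        assert stats.median == stats.q1 == stats.q3 == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            targets_per_indication_stats(set())

    def test_matches_oracle_on_random_pair_sets(self):
        rng = random.Random(11)
        for _ in range(100):
            counts = {
                d: rng.randint(1, 12) for d in range(rng.randint(1, 200))
            }
            stats = targets_per_indication_stats(_pairs_from_counts(counts))
            med, q1, q3 = _oracle_quartiles(list(counts.values()))
            assert (stats.median, stats.q1, stats.q3) == (med, q1, q3)
            assert stats.n == len(counts)


class TestIndicationsPerTarget:
    def test_chapter_sum_exceeds_unique_for_multichapter_disease(self):
        pairs = {
            TargetIndicationPair("G1", f"D{i}", "approved") for i in range(3)
        }
        chapters = {"D0": {"A", "B"}, "D1": {"A"}, "D2": {"C"}}
        out = indications_per_target_counts(pairs, chapters, threshold=0)
        assert len(out) == 1
        assert out[0].unique_diseases == 3
        assert out[0].chapter_sum == 4

    def test_threshold_filters_everything(self):
        pairs = {
            TargetIndicationPair("G1", f"D{i}", "approved") for i in range(10)
        }
        assert indications_per_target_counts(pairs, {}, threshold=25) == []

    def test_sorted_descending_by_unique_count(self, exact_run):
        result, _ = exact_run
        approved = {p for p in result.pairs if p.stage == "approved"}
        out = indications_per_target_counts(approved, {}, threshold=0)
        uniques = [t.unique_diseases for t in out]
        assert uniques == sorted(uniques, reverse=True)


class TestOpportunities:
    @pytest.fixture()
    def scene(self):
        partition = StagePartition(
            approved=frozenset({"GA"}),
            clinical=frozenset({"GA", "GC"}),
            preclinical=frozenset({"GP"}),
            undrugged=frozenset({"GU"}),
            druggable=frozenset({"GA", "GC", "GP", "GU"}),
        )
        pairs = {
            TargetIndicationPair("GA", "D1", "approved"),
            TargetIndicationPair("GC", "D2", "clinical"),
        }
        gwas = {"D1", "D2", "D3"}
        return partition, pairs, gwas

    def test_assignment_rules(self, scene):
        partition, pairs, gwas = scene
        lists = opportunity_lists(partition, pairs, gwas)
        expansion = {(e.gene, e.cui) for e in lists["indication_expansion"].entries}
        repurp = {(e.gene, e.cui) for e in lists["repurposing"].entries}
        de_novo = {(e.gene, e.cui) for e in lists["de_novo"].entries}
        # approved gene x unpaired GWAS disease -> expansion
        assert ("GA", "D3") in expansion
        # existing pair excluded from every list
        for entries in (expansion, repurp, de_novo):
            assert ("GA", "D1") not in entries
            assert ("GC", "D2") not in entries
        # clinical-only and preclinical genes -> repurposing
        assert ("GC", "D1") in repurp and ("GP", "D3") in repurp
        # undrugged druggable gene -> de novo
        assert de_novo == {("GU", d) for d in gwas}

    def test_lists_pairwise_disjoint(self, scene):
        partition, pairs, gwas = scene
        lists = opportunity_lists(partition, pairs, gwas)
        kinds = list(lists)
        for i, a in enumerate(kinds):
            for b in kinds[i + 1:]:
                pa = {(e.gene, e.cui) for e in lists[a].entries}
                pb = {(e.gene, e.cui) for e in lists[b].entries}
                assert not pa & pb

    def test_gene_strata_respect_invariants(self, exact_run):
        result, _ = exact_run
        lists = opportunity_lists(
            result.partition, result.pairs, result.gwas_diseases
        )
        p = result.partition
        existing = {(q.gene, q.cui) for q in result.pairs}
        for e in lists["indication_expansion"].entries:
            assert e.gene in p.approved and (e.gene, e.cui) not in existing
        for e in lists["repurposing"].entries:
            assert e.gene in (p.clinical | p.preclinical) - p.approved
        for e in lists["de_novo"].entries:
            assert e.gene in p.undrugged


def test_sample_space_report_consistency():
    report = make_sample_space_report("C", 10, 20, explored=5)
    assert report.size == 200
    assert report.explored_pct == 2.5
    with pytest.raises(ValueError):
        make_sample_space_report("C", 2, 2, explored=5)
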
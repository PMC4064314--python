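"""Baseline-tolerance pooling: logit/orientation, term ranking, pooling, stats."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from transfic import (
    BUILTIN_TOOLS,
    ConfigurationError,
    DomainError,
    GeneSetCollection,
    Orientation,
    PreTransform,
    ScoredVariant,
    ToolSpec,
    build_baseline_table,
    default_tools,
    index_by_gene,
    logit,
    orient_and_transform,
    pool_for_gene,
    pool_stats,
    rank_terms,
)


class TestLogit:
    def test_symmetry_point(self):
        assert logit(0.5, 1e-3) == 0.0

    def test_clamped_closed_form(self):
        assert logit(0.0, 1e-3) == pytest.approx(math.log(0.001 / 0.999))
        assert logit(0.0, 1e-3) == pytest.approx(-6.9068, abs=1e-4)

    @pytest.mark.parametrize("p", [0.2, 0.7])
    def test_antisymmetry(self, p):
        assert logit(p) == pytest.approx(-logit(1.0 - p))

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            logit(1.2)
        with pytest.raises(DomainError):
            logit(-0.1)
        with pytest.raises(DomainError):
            logit(0.5, epsilon=0.6)

    @given(st.floats(1e-3, 1 - 1e-3), st.floats(1e-3, 1 - 1e-3))
    def test_strictly_increasing_on_interior(self, a, b):
        if a == b:
            return
        lo, hi = min(a, b), max(a, b)
        assert logit(lo) < logit(hi)


class TestOrientAndTransform:
    def test_sift_symmetry_point(self):
        assert orient_and_transform(BUILTIN_TOOLS["sift"], 0.5) == 0.0

    def test_ma_is_identity(self):
        assert orient_and_transform(BUILTIN_TOOLS["ma"], 1.775) == 1.775

    def test_sift_more_damaging_scores_map_higher(self):
        sift = BUILTIN_TOOLS["sift"]
        assert orient_and_transform(sift, 0.01) > orient_and_transform(sift, 0.2)

    def test_bounded_tools_reject_out_of_range(self):
        with pytest.raises(DomainError):
            orient_and_transform(BUILTIN_TOOLS["sift"], 1.5)
        with pytest.raises(DomainError):
            orient_and_transform(BUILTIN_TOOLS["pph2"], -0.2)

    def test_lower_is_damaging_without_logit_negates(self):
        spec = ToolSpec("inv", Orientation.LOWER_IS_DAMAGING, PreTransform.NONE)
        assert orient_and_transform(spec, 3.0) == -3.0

    @pytest.mark.parametrize("name", ["sift", "pph2", "ma"])
    @given(data=st.data())
    def test_builtins_strictly_increase_with_damage(self, name, data):
        """Every built-in spec maps more-damaging raw scores to larger values."""
        spec = BUILTIN_TOOLS[name]
        eps = spec.logit_epsilon
        if spec.pre_transform is PreTransform.LOGIT:
            raw = data.draw(
                st.tuples(st.floats(eps, 1 - eps), st.floats(eps, 1 - eps)).filter(
                    lambda t: abs(t[0] - t[1]) > 1e-9
                )
            )
        else:
            raw = data.draw(
                st.tuples(st.floats(-5, 5), st.floats(-5, 5)).filter(
                    lambda t: abs(t[0] - t[1]) > 1e-9
                )
            )
        lo, hi = sorted(raw)
        less_damaging, more_damaging = (
            (hi, lo) if spec.orientation is Orientation.LOWER_IS_DAMAGING else (lo, hi)
        )
        assert orient_and_transform(spec, more_damaging) > orient_and_transform(
            spec, less_damaging
        )


@pytest.fixture
def three_term_collection():
    return GeneSetCollection(
        "C",
        {
            "T_a": ("big", {f"g{i}" for i in range(50)} | {"X"}),
            "T_b": ("small1", {"g0", "g1", "g2", "g3", "X"}),
            "T_c": ("small2", {"g4", "g5", "g6", "g7", "X"}),
        },
    )


class TestRankTerms:
    def test_ascending_size_with_lexicographic_ties(self, three_term_collection):
        assert rank_terms("X", three_term_collection) == ["T_b", "T_c", "T_a"]

    def test_unannotated_gene_is_empty(self, three_term_collection):
        assert rank_terms("nope", three_term_collection) == []

    def test_single_term_gene(self, three_term_collection):
        assert rank_terms("g10", three_term_collection) == ["T_a"]

    def test_matches_brute_force_on_random_collections(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            genes = [f"g{i}" for i in range(30)]
            terms = {}
            for t in range(12):
                members = set(rng.choice(genes, size=int(rng.integers(1, 15)), replace=False))
                terms[f"T{t:02d}"] = ("d", members)
            coll = GeneSetCollection("R", terms)
            for gene in genes:
                expected = sorted(
                    (t for t in terms if gene in terms[t][1]),
                    key=lambda t: (len(terms[t][1]), t),
                )
                assert rank_terms(gene, coll) == expected


def _mkvar(vid, gene, **scores):
    return ScoredVariant(vid, gene, scores)


class TestPoolForGene:
    TOOLS = default_tools()

    def _catalog(self):
        # T_b genes: 10 fully scored variants; T_c genes: 13; T_a extra: plenty
        cat = []
        for i in range(10):
            cat.append(_mkvar(f"b{i}", f"g{i % 4}", sift=0.5, pph2=0.5, ma=float(i)))
        for i in range(13):
            cat.append(_mkvar(f"c{i}", f"g{4 + i % 4}", sift=0.4, pph2=0.6, ma=float(i)))
        for i in range(40):
            cat.append(_mkvar(f"a{i}", f"g{8 + i % 20}", sift=0.3, pph2=0.7, ma=float(i)))
        return cat

    def test_walk_stops_at_first_sufficient_prefix(self, three_term_collection):
        by_gene = index_by_gene(self._catalog())
        res = pool_for_gene("X", three_term_collection, by_gene, self.TOOLS, min_pool=20)
        assert res is not None
        assert res.terms_used == ("T_b", "T_c")
        assert res.n == 23

    def test_unannotated_gene_falls_back(self, three_term_collection):
        by_gene = index_by_gene(self._catalog())
        assert pool_for_gene("nope", three_term_collection, by_gene, self.TOOLS) is None

    def test_exhausted_terms_fall_back(self, three_term_collection):
        by_gene = index_by_gene(self._catalog())
        assert (
            pool_for_gene("X", three_term_collection, by_gene, self.TOOLS, min_pool=1000)
            is None
        )

    def test_shared_variant_counted_once(self):
        # gene S sits in both terms; its variants must not double-count
        coll = GeneSetCollection("C", {"T1": ("d", {"S", "A"}), "T2": ("d", {"S", "B"})})
        cat = [
            _mkvar("s1", "S", sift=0.5, pph2=0.5, ma=1.0),
            _mkvar("s2", "S", sift=0.5, pph2=0.5, ma=2.0),
            _mkvar("a1", "A", sift=0.5, pph2=0.5, ma=0.0),
            _mkvar("b1", "B", sift=0.5, pph2=0.5, ma=3.0),
        ]
        res = pool_for_gene("S", coll, index_by_gene(cat), self.TOOLS, min_pool=4)
        assert res is not None
        assert res.n == 4  # union, not sum over terms

    def test_only_jointly_scored_variants_qualify(self):
        coll = GeneSetCollection("C", {"T1": ("d", {"A"})})
        cat = [
            _mkvar("v1", "A", sift=0.5, pph2=0.5, ma=1.0),
            _mkvar("v2", "A", ma=2.0),  # missing sift/pph2: must not count
            _mkvar("v3", "A", sift=0.1, pph2=0.9, ma=3.0),
        ]
        res = pool_for_gene("A", coll, index_by_gene(cat), self.TOOLS, min_pool=2)
        assert res is not None
        assert res.n == 2
        assert res.pooled_variant_ids == {"v1", "v3"}

    def test_catalog_order_irrelevant(self, three_term_collection):
        cat = self._catalog()
        rng = np.random.default_rng(0)
        res1 = pool_for_gene("X", three_term_collection, index_by_gene(cat), self.TOOLS)
        shuffled = list(cat)
        rng.shuffle(shuffled)
        res2 = pool_for_gene("X", three_term_collection, index_by_gene(shuffled), self.TOOLS)
        assert res1.terms_used == res2.terms_used
        assert res1.pooled_variant_ids == res2.pooled_variant_ids
        assert res1.per_tool_stats == res2.per_tool_stats

    def test_prefix_minimality(self, three_term_collection):
        """Dropping the last included term leaves the pool under min_pool."""
        by_gene = index_by_gene(self._catalog())
        res = pool_for_gene("X", three_term_collection, by_gene, self.TOOLS, min_pool=20)
        shorter = res.terms_used[:-1]
        pooled = set()
        for t in shorter:
            for g in three_term_collection.members(t):
                for v in by_gene.get(g, []):
                    if v.has_all({"sift", "pph2", "ma"}):
                        pooled.add((v.gene_id, v.variant_id))
        assert len(pooled) < 20


class TestPoolStats:
    def test_simple_moments(self):
        pool = [
            _mkvar("v1", "A", sift=0.5, pph2=0.5, ma=0.0),
            _mkvar("v2", "A", sift=0.5, pph2=0.5, ma=2.0),
        ]
        stats = pool_stats(pool, [BUILTIN_TOOLS["ma"]])
        assert stats["ma"].dm == pytest.approx(1.0)
        assert stats["ma"].dstd == pytest.approx(math.sqrt(2.0))  # n-1 denominator

    def test_reproduces_fixture_moments(self):
        """A pool engineered to the published PIK3CA moments returns them."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=23)
        x = (x - x.mean()) / x.std(ddof=1)  # standardized
        values = 0.853 + 0.327 * x
        pool = [_mkvar(f"v{i}", "A", ma=float(v)) for i, v in enumerate(values)]
        stats = pool_stats(pool, [BUILTIN_TOOLS["ma"]])
        assert stats["ma"].dm == pytest.approx(0.853, abs=1e-12)
        assert stats["ma"].dstd == pytest.approx(0.327, abs=1e-12)

    def test_degenerate_pools_raise(self):
        with pytest.raises(DomainError):
            pool_stats([_mkvar("v1", "A", ma=1.0)], [BUILTIN_TOOLS["ma"]])
        same = [_mkvar(f"v{i}", "A", ma=1.0) for i in range(5)]
        with pytest.raises(DomainError):
            pool_stats(same, [BUILTIN_TOOLS["ma"]])
        with pytest.raises(DomainError):
            pool_stats([], [BUILTIN_TOOLS["ma"]])


class TestBuildBaselineTable:
    def test_unannotated_gene_gets_global_entry(self, universe, baseline_table):
        catalog, collection, _ = universe
        orphan = "ZZZ_NOT_ANNOTATED"
        cat = catalog + [
            ScoredVariant(f"z{i}", orphan, {"sift": 0.5, "pph2": 0.5, "ma": 1.0})
            for i in range(3)
        ]
        table = build_baseline_table(cat, collection)
        entry = table.per_gene[orphan]
        assert entry.fallback
        assert entry.terms_used == ()
        assert entry.stats == table.global_stats
        assert entry.n_pooled == table.global_n

    def test_global_stats_match_whole_catalog_oracle(self, universe, baseline_table):
        catalog, _, _ = universe
        qualifying = [v for v in catalog if v.has_all({"sift", "pph2", "ma"})]
        ma = np.array([v.scores["ma"] for v in qualifying])
        assert baseline_table.global_n == len(qualifying)
        assert baseline_table.global_stats["ma"].dm == pytest.approx(float(ma.mean()))
        assert baseline_table.global_stats["ma"].dstd == pytest.approx(
            float(ma.std(ddof=1))
        )

    def test_min_pool_one_uses_single_most_specific_term(self, universe):
        catalog, collection, _ = universe
        table = build_baseline_table(catalog, collection, min_pool=1)
        for gene, entry in table.per_gene.items():
            if entry.fallback:
                continue
            # with min_pool=1 the first term with any qualifying variant wins
            assert len(entry.terms_used) >= 1
            ranking = rank_terms(gene, collection)
            assert list(entry.terms_used) == ranking[: len(entry.terms_used)]
            # the walk stopped as soon as one variant was pooled
            assert entry.n_pooled >= 1

    def test_group_means_recovered_in_order(self):
        """Per-gene dm follows the generating group means on a 3-group fixture."""
        from transfic import SimConfig, simulate_universe

        cfg = SimConfig(
            n_groups=3,
            group_tolerance_means=[0.0, 1.5, 3.0],
            group_tolerance_stds=[0.2, 0.2, 0.2],
            overlap_fraction=0.0,
            snvs_per_gene=10.0,
            seed=3,
        )
        catalog, collection, truth = simulate_universe(cfg)
        table = build_baseline_table(catalog, collection, min_pool=20)
        group_dm = {g: [] for g in range(3)}
        for gene, t in truth.items():
            entry = table.per_gene[gene]
            if not entry.fallback:
                group_dm[t.group].append(entry.stats["ma"].dm)
        means = [np.mean(group_dm[g]) for g in range(3)]
        assert means[0] < means[1] < means[2]

    def test_empty_catalog_rejected(self, universe):
        _, collection, _ = universe
        with pytest.raises(ConfigurationError):
            build_baseline_table([], collection)

    def test_degenerate_pool_uses_global_spread(self):
        """Constant-scored pools keep their mean but borrow the global dstd."""
        coll = GeneSetCollection("C", {"T1": ("d", {"A"}), "T2": ("d", {"B"})})
        cat = [_mkvar(f"a{i}", "A", ma=1.0) for i in range(25)]  # zero variance
        cat += [_mkvar(f"b{i}", "B", ma=float(i)) for i in range(25)]
        table = build_baseline_table(cat, coll, tools=[BUILTIN_TOOLS["ma"]], min_pool=20)
        entry = table.per_gene["A"]
        assert not entry.fallback
        assert entry.stats["ma"].dm == pytest.approx(1.0)
        assert entry.stats["ma"].dstd == pytest.approx(table.global_stats["ma"].dstd)
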
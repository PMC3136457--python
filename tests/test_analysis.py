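"""Relevance scoring, module creation/editing/algebra, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crosscomp.analysis import (
    clean_module_genes,
    contrast_relevance,
    create_module_from_contrasts,
    create_module_from_genes,
    export_heatmap,
    extend_module,
    go_enrichment,
    merge_modules,
    most_variable_genes,
    select_relevant_contrasts,
    split_module,
    subtract_modules,
    write_module_overview,
)
from crosscomp.compendium import ExpressionModule, LogratioCompendium
from crosscomp.errors import (
    CreationError,
    DegenerateResultError,
    ParameterError,
    ValidationError,
)
from crosscomp.stats import StatParams

P2 = StatParams(min_overlap=2)


def make_comp(data: dict, genes, exp="E1", plat="P1", name="c") -> LogratioCompendium:
    values = pd.DataFrame(data, index=genes)
    meta = pd.DataFrame(
        {"experiment_id": exp, "platform_id": plat}, index=values.columns
    )
    return LogratioCompendium(values, meta, name=name)


# ---------------------------------------------------------------------------
# relevance
# ---------------------------------------------------------------------------


class TestRelevance:
    def test_uniform_unit_response(self):
        comp = make_comp({"c1": [1.0, 1.0]}, ["a", "b"])
        row = contrast_relevance(["a", "b"], comp).loc["c1"]
        assert row["relevance"] == 1.0 and row["coherence"] == 1.0

    def test_perfect_cancellation(self):
        comp = make_comp({"c1": [2.0, -2.0]}, ["a", "b"])
        row = contrast_relevance(["a", "b"], comp).loc["c1"]
        assert row["relevance"] == 0.0 and row["magnitude"] == 2.0

    @pytest.mark.parametrize(
        "profile, magnitude, coherence, relevance",
        [((3.0, 1.0), 2.0, 1.0, 2.0), ((2.0, -1.0), 1.5, 1 / 3, 0.5)],
    )
    def test_hand_decompositions(self, profile, magnitude, coherence, relevance):
        comp = make_comp({"c1": list(profile)}, ["a", "b"])
        row = contrast_relevance(["a", "b"], comp).loc["c1"]
        assert row["magnitude"] == pytest.approx(magnitude, abs=1e-12)
        assert row["coherence"] == pytest.approx(coherence, abs=1e-12)
        assert row["relevance"] == pytest.approx(relevance, abs=1e-12)

    def test_decomposition_identity_random(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 15))
        X[rng.random(X.shape) < 0.2] = np.nan
        comp = make_comp(
            {f"c{j}": X[:, j] for j in range(15)}, [f"g{i}" for i in range(30)]
        )
        table = contrast_relevance([f"g{i}" for i in range(30)], comp)
        assert np.allclose(
            table["relevance"], table["magnitude"] * table["coherence"], atol=1e-12
        )

    def test_duplicating_all_members_leaves_scores_unchanged(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5, 6))
        doubled = np.vstack([X, X])
        genes = [f"g{i}" for i in range(10)]
        comp = make_comp({f"c{j}": doubled[:, j] for j in range(6)}, genes)
        single = contrast_relevance(genes[:5], comp)
        both = contrast_relevance(genes, comp)
        assert np.allclose(single["relevance"], both["relevance"], atol=1e-12)

    def test_unresolvable_genes_raise(self, tiny_compendium):
        with pytest.raises(ValidationError):
            contrast_relevance(["nope"], tiny_compendium)


class TestSelectRelevant:
    COMP = staticmethod(
        lambda: make_comp(
            {"c1": [2.0, 2.0], "c2": [1.0, 1.0], "c3": [0.5, 0.5]}, ["a", "b"]
        )
    )

    def test_cutoff_orders_and_filters(self):
        assert select_relevant_contrasts(["a", "b"], self.COMP(), 1.0) == ["c1", "c2"]

    def test_cutoff_zero_returns_all_observed(self):
        assert select_relevant_contrasts(["a", "b"], self.COMP(), 0.0) == [
            "c1",
            "c2",
            "c3",
        ]

    def test_cutoff_above_max_empty(self):
        assert select_relevant_contrasts(["a", "b"], self.COMP(), 5.0) == []


class TestMostVariable:
    def test_ranking_by_uncentered_std(self):
        comp = make_comp(
            {"c1": [3.0, 1.0, 0.0], "c2": [4.0, 1.0, 0.0]}, ["hi", "lo", "zero"]
        )
        ranked = most_variable_genes(["c1", "c2"], comp, params=P2)
        assert list(ranked.index) == ["hi", "lo", "zero"]
        assert ranked["hi"] == pytest.approx(math.sqrt(12.5))
        assert ranked["lo"] == 1.0

    def test_positive_cutoff_drops_flat_genes_and_topn_caps(self):
        comp = make_comp({"c1": [3.0, 0.0], "c2": [4.0, 0.0]}, ["hi", "zero"])
        assert list(most_variable_genes(["c1", "c2"], comp, cutoff=0.1, params=P2).index) == ["hi"]
        assert len(most_variable_genes(["c1", "c2"], comp, top_n=99, params=P2)) == 2


# ---------------------------------------------------------------------------
# module creation
# ---------------------------------------------------------------------------


class TestCreateModules:
    def test_from_genes_composes_selection(self, recovery_study):
        comp, truth = recovery_study
        members = truth.members_of("regulon")
        module = create_module_from_genes(members, comp, relevance_cutoff=1.0)
        active = set(truth.activity.columns[truth.activity.loc["regulon"].abs() >= 1.0])
        assert set(module.contrast_ids) == active

    def test_from_genes_cutoff_zero_spans_all_observed(self, tiny_compendium):
        module = create_module_from_genes(["g1", "g2"], tiny_compendium, 0.0)
        assert set(module.contrast_ids) == set(tiny_compendium.contrast_ids) - {"E2_c3"}

    def test_empty_selection_raises(self, tiny_compendium):
        with pytest.raises(CreationError):
            create_module_from_genes(["g5"], tiny_compendium, relevance_cutoff=1.0)

    def test_from_contrasts_single_module(self, tiny_compendium):
        (module,) = create_module_from_contrasts(
            ["E1_c1", "E1_c2"], tiny_compendium, top_n=3, params=P2
        )
        assert module.n_genes == 3

    def test_from_contrasts_k_equals_topn_gives_singletons(self, tiny_compendium):
        modules = create_module_from_contrasts(
            ["E1_c1", "E1_c2"], tiny_compendium, top_n=3, k_clusters=3, params=P2
        )
        assert sorted(m.n_genes for m in modules) == [1, 1, 1]

    def test_anticorrelated_groups_partition(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=8)
        X = np.vstack([base + rng.normal(0, 0.05, 8) for _ in range(4)]
                      + [-base + rng.normal(0, 0.05, 8) for _ in range(4)])
        genes = [f"up{i}" for i in range(4)] + [f"down{i}" for i in range(4)]
        comp = make_comp({f"c{j}": X[:, j] for j in range(8)}, genes)
        modules = create_module_from_contrasts(
            [f"c{j}" for j in range(8)], comp, top_n=8, k_clusters=2
        )
        assert {frozenset(genes[:4]), frozenset(genes[4:])} == set(
            frozenset(m.gene_ids) for m in modules
        )

    def test_topn_below_k_raises(self, tiny_compendium):
        with pytest.raises(ParameterError):
            create_module_from_contrasts(["E1_c1"], tiny_compendium, top_n=2, k_clusters=3)


# ---------------------------------------------------------------------------
# cleaning and extension
# ---------------------------------------------------------------------------


class TestCleanModule:
    def test_identical_profiles_keep_everything(self):
        comp = make_comp({"c1": [1.0] * 3, "c2": [2.0] * 3}, ["a", "b", "c"])
        module = ExpressionModule("m", ("a", "b", "c"), ("c1", "c2"), "c")
        cleaned, removed = clean_module_genes(module, comp, 0.8, P2)
        assert cleaned.gene_ids == ("a", "b", "c") and removed.empty

    def test_single_pass_against_initial_mean(self):
        # initial mean of (1,1),(1,1),(1,-1) is (1, 1/3): r(g1)=r(g2)~0.894,
        # r(g3)~0.447 -> only g3 removed, mean NOT recomputed afterwards
        comp = make_comp({"c1": [1.0, 1.0, 1.0], "c2": [1.0, 1.0, -1.0]}, ["g1", "g2", "g3"])
        module = ExpressionModule("m", ("g1", "g2", "g3"), ("c1", "c2"), "c")
        cleaned, removed = clean_module_genes(module, comp, 0.8, P2)
        assert cleaned.gene_ids == ("g1", "g2")
        assert removed["g3"] == pytest.approx(1 / math.sqrt(5), abs=1e-9)

    def test_opposite_gene_removed(self):
        comp = make_comp({"c1": [1.0, 1.0, -1.0], "c2": [2.0, 2.0, -2.0]}, ["a", "b", "anti"])
        module = ExpressionModule("m", ("a", "b", "anti"), ("c1", "c2"), "c")
        cleaned, removed = clean_module_genes(module, comp, 0.8, P2)
        assert "anti" in removed.index and removed["anti"] < 0

    def test_all_removed_is_degenerate(self):
        comp = make_comp({"c1": [1.0, -1.0], "c2": [-1.0, 1.0]}, ["a", "b"])
        module = ExpressionModule("m", ("a", "b"), ("c1", "c2"), "c")
        with pytest.raises(DegenerateResultError):
            clean_module_genes(module, comp, 0.99, P2)


class TestExtendModule:
    def _setup(self):
        comp = make_comp(
            {
                "c1": [1.0, 1.0, 1.0, -1.0, 0.3],
                "c2": [2.0, 2.0, 2.0, -2.0, -0.1],
            },
            ["m1", "m2", "same", "anti", "noise"],
        )
        module = ExpressionModule("m", ("m1", "m2"), ("c1", "c2"), "c")
        return comp, module

    def test_profile_equal_to_mean_ranks_first(self):
        comp, module = self._setup()
        out = extend_module(module, comp, 0.8, "correlated", P2)
        assert list(out.index) == ["same"]
        assert out["same"] == pytest.approx(1.0)

    def test_anticorrelated_retrieval(self):
        comp, module = self._setup()
        out = extend_module(module, comp, 0.8, "anticorrelated", P2)
        assert list(out.index) == ["anti"]
        assert out["anti"] == pytest.approx(-1.0)

    def test_threshold_monotonicity(self, recovery_study):
        comp, truth = recovery_study
        members = truth.members_of("regulon")
        module = create_module_from_genes(members[:20], comp, 1.0)
        previous = None
        for thr in (0.5, 0.7, 0.8, 0.9, 0.99):
            current = set(extend_module(module, comp, thr).index)
            if previous is not None:
                assert current <= previous
            previous = current


# ---------------------------------------------------------------------------
# splitting and algebra
# ---------------------------------------------------------------------------


class TestSplitAndAlgebra:
    def _module(self):
        comp = make_comp(
            {
                "c1": [1.0, 1.1, -1.0, -1.1],
                "c2": [2.0, 2.1, -2.0, -2.1],
                "c3": [1.5, 1.4, -1.5, -1.4],
            },
            ["a1", "a2", "b1", "b2"],
        )
        return comp, ExpressionModule("m", ("a1", "a2", "b1", "b2"), ("c1", "c2", "c3"), "c")

    def test_k1_is_identity(self):
        comp, module = self._module()
        modules, excluded = split_module(module, comp, "gene", 1, P2)
        assert modules == [module] and excluded == []

    def test_opposed_groups_split_exactly(self):
        comp, module = self._module()
        modules, _ = split_module(module, comp, "gene", 2, P2)
        parts = {frozenset(m.gene_ids) for m in modules}
        assert parts == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}
        assert all(m.contrast_ids == module.contrast_ids for m in modules)

    def test_split_partitions_gene_set(self):
        comp, module = self._module()
        for k in (2, 3, 4):
            modules, excluded = split_module(module, comp, "gene", k, P2)
            union = sorted(g for m in modules for g in m.gene_ids) + sorted(excluded)
            assert sorted(union) == sorted(module.gene_ids)
            sizes = sum(m.n_genes for m in modules)
            assert sizes + len(excluded) == module.n_genes

    def test_contrast_direction_split(self):
        comp, module = self._module()
        modules, _ = split_module(module, comp, "contrast", 2, P2)
        union = sorted(c for m in modules for c in m.contrast_ids)
        assert union == sorted(module.contrast_ids)
        assert all(m.gene_ids == module.gene_ids for m in modules)

    def test_merge_idempotent_and_subtract_identities(self):
        a = ExpressionModule("A", ("g1", "g2"), ("c1",), "c")
        b = ExpressionModule("B", ("g2", "g3"), ("c2",), "c")
        assert merge_modules([a, a]).gene_ids == a.gene_ids
        merged = merge_modules([a, b])
        assert set(merged.gene_ids) == {"g1", "g2", "g3"}
        assert set(merged.contrast_ids) == {"c1", "c2"}
        diff = subtract_modules(merged, b, "gene")
        assert set(diff.gene_ids) == {"g1"}
        assert diff.contrast_ids == merged.contrast_ids

    def test_merge_subtract_round_trip_on_disjoint(self):
        a = ExpressionModule("A", ("g1",), ("c1",), "c")
        b = ExpressionModule("B", ("g2",), ("c1",), "c")
        back = subtract_modules(merge_modules([a, b]), b, "gene")
        assert set(back.gene_ids) == set(a.gene_ids)

    def test_subtract_emptying_raises(self):
        a = ExpressionModule("A", ("g1",), ("c1",), "c")
        with pytest.raises(DegenerateResultError):
            subtract_modules(a, a, "gene")


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def brute_hypergeom_upper_tail(M, K, N, k):
    """P(X >= k) by enumerating all C(M, N) draws."""
    universe = range(M)
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, N):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


class TestEnrichment:
    def test_term_covering_universe_is_uninformative(self):
        uni = [f"g{i}" for i in range(10)]
        out = go_enrichment(uni[:3], {"all": uni}, uni)
        assert out.loc[0, "p_value"] == 1.0

    def test_exact_small_case(self):
        uni = [f"g{i}" for i in range(10)]
        out = go_enrichment(uni[:2], {"t": uni[:2]}, uni)
        assert out.loc[0, "p_value"] == pytest.approx(1 / 45, abs=1e-12)

    def test_zero_overlap_p_one(self):
        uni = [f"g{i}" for i in range(10)]
        out = go_enrichment(uni[:2], {"t": uni[5:7]}, uni)
        assert out.loc[0, "p_value"] == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            M = int(rng.integers(4, 13))
            uni = [f"g{i}" for i in range(M)]
            K = int(rng.integers(1, M + 1))
            N = int(rng.integers(1, M + 1))
            term = uni[:K]
            module = list(rng.choice(uni, size=N, replace=False))
            out = go_enrichment(module, {"t": term}, uni)
            k = out.loc[0, "overlap"]
            if k == 0:
                assert out.loc[0, "p_value"] == 1.0
                continue
            expected = brute_hypergeom_upper_tail(M, K, N, k)
            assert out.loc[0, "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_overlap_bounded_and_adjustment_present(self):
        uni = [f"g{i}" for i in range(20)]
        out = go_enrichment(uni[:5], {"a": uni[:3], "b": uni[10:]}, uni)
        assert (out["overlap"] <= out[["module_size", "term_size"]].min(axis=1)).all()
        assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def test_heatmap_and_overview_exports(tmp_path, tiny_compendium):
    module = ExpressionModule("m", ("g1", "g2"), ("E1_c1", "E1_c2"), "tiny")
    png = tmp_path / "module.png"
    export_heatmap(module, tiny_compendium, png)
    assert png.stat().st_size > 0
    report = tmp_path / "overview.txt"
    write_module_overview(
        module,
        tiny_compendium,
        report,
        term_sets={"t": ["g1", "g2", "g3"]},
        universe=list(tiny_compendium.gene_ids),
    )
    text = report.read_text()
    assert "n_genes\t2" in text and "term_id" in text
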
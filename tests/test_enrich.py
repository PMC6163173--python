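import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from coexnet import synthetic
from coexnet.enrich import (
    bh_adjust,
    count_modules_by_term,
    enrich_gene_sets,
    hypergeom_log_tail,
    load_module_annotation,
    overlap_comparison,
    positional_enrichment,
)


def exact_log10_tail(N: int, K: int, n: int, k: int) -> float:
    """Rational-arithmetic upper-tail oracle, exact until the final log10."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    if total == 0:
        raise ValueError("empty tail")
    return math.log10(total.numerator) - math.log10(total.denominator)


class TestHypergeomLogTail:
    def test_small_case_by_enumeration(self):
        # C(5,3)C(5,1) + C(5,4)C(5,0) = 55 over C(10,4) = 210
        expected = math.log10(55.0 / 210.0)
        assert hypergeom_log_tail(10, 5, 4, 3) == pytest.approx(expected, abs=1e-12)

    def test_k_zero_is_certain(self):
        assert hypergeom_log_tail(100, 10, 10, 0) == 0.0

    def test_forced_draw_is_certain(self):
        assert hypergeom_log_tail(10, 10, 10, 10) == 0.0

    @pytest.mark.parametrize(
        "args", [(10, 11, 5, 2), (10, 5, 11, 2), (10, 5, 4, 5), (10, -1, 4, 2)]
    )
    def test_inconsistent_counts_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeom_log_tail(*args)

    def test_exhaustive_small_N_against_rational_oracle(self):
        for N in range(1, 16):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(1, n + K - N), min(n, K) + 1):
                        got = hypergeom_log_tail(N, K, n, k)
                        expected = exact_log10_tail(N, K, n, k)
                        assert abs(got - expected) <= 1e-10 * max(1.0, abs(expected))

    def test_deep_tail_stays_finite_in_log_space(self):
        log10_p = hypergeom_log_tail(20000, 2000, 1000, 900)
        assert -2000 < log10_p < -500
        assert math.isfinite(log10_p)


class TestBHAdjust:
    def test_three_values_by_hand(self):
        adj = bh_adjust([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_statsmodels_and_dominates_raw(self, p_values):
        adj = bh_adjust(p_values)
        _, expected, _, _ = multipletests(p_values, method="fdr_bh")
        assert adj == pytest.approx(expected, abs=1e-12)
        assert (adj >= np.asarray(p_values) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p_values, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


@pytest.fixture(scope="module")
def planted_sets():
    config = synthetic.SyntheticConfig(
        n_samples=30, module_sizes=(20, 25, 30), n_background=125, seed=13
    )
    _, truth = synthetic.generate_expression(config)
    collection = synthetic.generate_gene_sets(truth, n_decoy_sets=10, seed=14)
    background = set(truth.partition)
    return truth, collection, background


class TestEnrichGeneSets:
    def test_true_set_ranks_first(self, planted_sets):
        truth, collection, background = planted_sets
        for label in truth.module_labels():
            table = enrich_gene_sets(set(truth.module_genes(label)), collection, background)
            assert table.iloc[0]["term"] == f"true_{label}"
            assert table.iloc[0]["adjusted_p"] == table["adjusted_p"].min()

    def test_disjoint_term_has_p_one(self, planted_sets):
        truth, _, background = planted_sets
        query = set(truth.module_genes("M1"))
        other = {"other": set(truth.module_genes("M2"))}
        table = enrich_gene_sets(query, other, background)
        assert table.iloc[0]["log10_p"] == 0.0
        assert table.iloc[0]["p"] == 1.0

    def test_term_outside_background_skipped(self, planted_sets):
        truth, _, background = planted_sets
        query = set(truth.module_genes("M1"))
        with pytest.warns(UserWarning, match="skipped"):
            table = enrich_gene_sets(
                query, {"alien": {"not_a_gene"}, "real": query}, background
            )
        assert list(table["term"]) == ["real"]

    def test_duplicate_ids_are_deduplicated(self, planted_sets):
        truth, collection, background = planted_sets
        query = truth.module_genes("M1")
        a = enrich_gene_sets(set(query), collection, background)
        b = enrich_gene_sets(set(list(query) + query[:5]), collection, background)
        pd.testing.assert_frame_equal(a, b)

    def test_query_outside_background_rejected(self, planted_sets):
        _, collection, background = planted_sets
        with pytest.raises(ValueError, match="not in background"):
            enrich_gene_sets({"stray"}, collection, background)


class TestPositionalEnrichment:
    def test_fully_clustered_module_found(self):
        config = synthetic.SyntheticConfig(
            n_samples=10, module_sizes=(50,), n_background=950,
            position_clustering=1.0, seed=5,
        )
        _, truth = synthetic.generate_expression(config)
        positions = synthetic.generate_positions(truth, n_chromosomes=5, seed=6)
        regions = positional_enrichment(set(truth.module_genes("M1")), positions)
        windows = regions[~regions["whole_chromosome"]]
        assert len(windows) >= 1
        # hypergeometric with k = n = 50, K about 50, N = 1000 is astronomically small
        assert windows["log10_p"].min() < math.log10(7e-7) - 20

    def test_scattered_module_rarely_significant(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            truth = synthetic.SyntheticTruth(
                partition={
                    str(170_000 + i): ("M1" if i < 50 else "background")
                    for i in range(1000)
                },
                factors=pd.DataFrame([[0.0]], index=["M1"], columns=["S1"]),
                loadings={},
            )
            positions = synthetic.generate_positions(
                truth, n_chromosomes=5, seed=seed, position_clustering=0.0
            )
            regions = positional_enrichment(set(truth.module_genes("M1")), positions)
            hits += len(regions) > 0
        assert hits / n_seeds <= 0.05

    def test_module_covering_everything_flagged_degenerate(self):
        positions = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(60)],
                "chromosome": ["chr1"] * 60,
                "start": np.arange(60) * 100,
                "end": np.arange(60) * 100 + 50,
            }
        )
        with pytest.warns(UserWarning, match="degenerate"):
            regions = positional_enrichment(set(positions["gene_id"]), positions)
        assert (regions["whole_chromosome"]).any()

    def test_unpositioned_gene_rejected(self):
        positions = pd.DataFrame(
            {"gene_id": ["g1"], "chromosome": ["chr1"], "start": [0], "end": [10]}
        )
        with pytest.raises(ValueError, match="ghost"):
            positional_enrichment({"g1", "ghost"}, positions, window_size=2)


class TestOverlapComparison:
    def test_disjoint_sets(self):
        result = overlap_comparison({"a", "b"}, {"c", "d"}, N=10)
        assert result.k == 0
        assert result.log10_p == 0.0

    def test_subset_certain_overlap(self):
        a = {f"g{i}" for i in range(3)}
        b = {f"g{i}" for i in range(10)}
        result = overlap_comparison(a, b, N=10)
        assert result.k == 3
        assert result.log10_p == 0.0  # drawing only marked items: P = 1

    def test_background_too_small_rejected(self):
        with pytest.raises(ValueError):
            overlap_comparison({"a", "b"}, {"c"}, N=2)

    @given(
        n_a=st.integers(min_value=1, max_value=12),
        n_b=st.integers(min_value=1, max_value=12),
        k=st.integers(min_value=0, max_value=12),
        extra=st.integers(min_value=0, max_value=10),
    )
    def test_symmetry_in_log_p(self, n_a, n_b, k, extra):
        k = min(k, n_a, n_b)
        union = n_a + n_b - k
        N = union + extra
        genes = [f"g{i}" for i in range(N)]
        shared = set(genes[:k])
        a = shared | set(genes[k : k + n_a - k])
        b = shared | set(genes[k + n_a - k : k + n_a - k + n_b - k])
        ab = overlap_comparison(a, b, N)
        ba = overlap_comparison(b, a, N)
        assert ab.log10_p == pytest.approx(ba.log10_p, abs=1e-10)
        assert ab.fraction_of_a == pytest.approx(ab.k / len(a))


class TestModuleAnnotationFixture:
    def test_has_48_rows(self):
        assert len(load_module_annotation()) == 48

    def test_embryo_development_count(self):
        fixture = load_module_annotation()
        count = count_modules_by_term(
            fixture, "BP", "Embryo development ending in birth or egg hatching"
        )
        assert count == 10

    def test_ion_transport_count(self):
        fixture = load_module_annotation()
        assert count_modules_by_term(fixture, "BP", "ion transport") == 3

    def test_nonexistent_term_counts_zero(self):
        fixture = load_module_annotation()
        assert count_modules_by_term(fixture, "BP", "nonexistent term") == 0

    def test_chromosome_field(self):
        fixture = load_module_annotation()
        assert count_modules_by_term(fixture, "chromosome", "X") >= 5

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="unknown field"):
            count_modules_by_term(load_module_annotation(), "ZZ", "anything")

    def test_gene_counts_positive(self):
        fixture = load_module_annotation()
        assert (fixture["n_genes"] > 0).all()
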
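"""Replicate averaging, filtering, tau and classification."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tissueatlas import ExpressionAtlas
from tissueatlas.atlas import (
    average_replicates,
    classify_genes,
    compute_tau,
    filter_genes,
    foldchange_tau_correlation,
    tissue_correlation,
)

from .conftest import make_profile


def _atlas_from(values, design):
    expr = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"g{i}" for i in range(len(values))],
        columns=design["sample_id"],
    )
    return ExpressionAtlas(expression=expr, design=design)


class TestAverageReplicates:
    def test_two_replicates_mean(self):
        design = pd.DataFrame({"sample_id": ["a1", "a2", "b1", "b2"],
                               "tissue": ["A", "A", "B", "B"]})
        atlas = _atlas_from([[4.0, 6.0, 1.0, 3.0]], design)
        prof = average_replicates(atlas)
        assert prof.loc["g0", "A"] == 5.0
        assert prof.loc["g0", "B"] == 2.0

    def test_single_replicate_passes_through(self):
        design = pd.DataFrame({"sample_id": ["a1", "b1"], "tissue": ["A", "B"]})
        atlas = _atlas_from([[7.5, 2.25]], design)
        prof = average_replicates(atlas)
        assert prof.loc["g0", "A"] == 7.5

    def test_matches_elementwise_loop(self, rng):
        n_genes, tissues, reps = 20, list("ABCDE"), 4
        design = pd.DataFrame({
            "sample_id": [f"{t}{r}" for t in tissues for r in range(reps)],
            "tissue": [t for t in tissues for _ in range(reps)],
        })
        X = rng.uniform(0, 100, (n_genes, len(design)))
        atlas = _atlas_from(X, design)
        prof = average_replicates(atlas)
        for gi in range(n_genes):
            for ti, t in enumerate(tissues):
                cols = [ti * reps + r for r in range(reps)]
                expected = sum(X[gi, c] for c in cols) / reps
                assert prof.iloc[gi][t] == pytest.approx(expected, abs=1e-12)


class TestFilterGenes:
    def test_mean_exactly_one_removed_inclusively(self):
        prof = make_profile([[1.0] * 10, [1.01] * 10, [0.5] * 10])
        kept = filter_genes(prof)
        assert list(kept.index) == ["g1"]

    def test_ncrna_removed(self):
        prof = make_profile([[10.0] * 10, [10.0] * 10])
        kept = filter_genes(prof, ncrna_ids={"g0"})
        assert list(kept.index) == ["g1"]

    def test_planted_subthreshold_genes_all_removed(self, rng):
        high = rng.uniform(5, 50, (200, 10))
        low = rng.uniform(0, 0.9, (100, 10))
        prof = make_profile(np.vstack([high, low]))
        kept = filter_genes(prof)
        assert len(kept) == 200
        assert set(kept.index) == {f"g{i}" for i in range(200)}

    def test_empty_result_raises(self):
        prof = make_profile([[0.1] * 10])
        with pytest.raises(ValueError, match="every gene"):
            filter_genes(prof)


class TestComputeTau:
    def test_uniform_profile_is_zero(self):
        tau = compute_tau(make_profile([[8.0] * 10]))
        assert tau.loc["g0", "tau"] == 0.0

    def test_single_tissue_profile_is_one(self):
        tau = compute_tau(make_profile([[0, 0, 0, 0, 0, 0, 0, 0, 0, 7.0]]))
        assert tau.loc["g0", "tau"] == 1.0
        assert tau.loc["g0", "max_tpm"] == 7.0

    def test_printed_formula_example(self):
        tau = compute_tau(make_profile([[10, 5, 0, 0, 0, 0, 0, 0, 0, 0]]))
        assert tau.loc["g0", "tau"] == pytest.approx(8.5 / 9, abs=1e-15)

    def test_all_zero_gene_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            compute_tau(make_profile([[0.0] * 10]))

    def test_vectorized_matches_scalar_loop(self, rng):
        X = rng.uniform(0, 1000, (1000, 10))
        prof = make_profile(X)
        tau = compute_tau(prof)["tau"].values
        N = X.shape[1]
        for g in range(X.shape[0]):
            xmax = max(X[g])
            expected = sum(1 - x / xmax for x in X[g]) / (N - 1)
            assert abs(tau[g] - expected) <= 1e-12

    @given(st.lists(st.floats(0.01, 1e6), min_size=2, max_size=12))
    def test_tau_bounds(self, values):
        tau = compute_tau(make_profile([values]))["tau"].iloc[0]
        assert 0.0 <= tau <= 1.0

    @given(
        st.lists(st.floats(0.01, 1e3), min_size=3, max_size=10),
        st.floats(1.01, 100.0),
    )
    def test_raising_max_tissue_never_decreases_tau(self, values, factor):
        base = np.asarray(values)
        bumped = base.copy()
        bumped[np.argmax(base)] *= factor
        t0 = compute_tau(make_profile([base]))["tau"].iloc[0]
        t1 = compute_tau(make_profile([bumped]))["tau"].iloc[0]
        assert t1 >= t0 - 1e-12


class TestClassifyGenes:
    def _classify(self, rows):
        prof = make_profile(rows)
        return classify_genes(prof, compute_tau(prof))

    def test_tissue_specific_rule(self):
        out = self._classify([[50, 2, 1, 1, 1, 1, 1, 1, 1, 1]])
        row = out.iloc[0]
        assert row["category"] == "TissueSpecific"
        assert row["max_tissue"] == "t00"
        assert row["group"] == "t00"
        assert row["tau"] == pytest.approx((1 - 2 / 50 + 8 * (1 - 1 / 50)) / 9, abs=1e-12)
        assert row["fold_over_rest"] == 25.0

    def test_group_enriched_smallest_k(self):
        out = self._classify([[40, 35, 2, 2, 1, 1, 1, 1, 1, 1]])
        row = out.iloc[0]
        assert row["category"] == "GroupEnriched"
        assert row["group"] == "t00;t01"

    def test_expressed_in_all(self):
        out = self._classify([[1.2, 1.0, 1.1, 1.3, 1.0, 1.2, 1.1, 1.0, 1.3, 1.2]])
        assert out.iloc[0]["category"] == "ExpressedInAll"
        assert out.iloc[0]["tau"] < 0.5

    def test_mixed_is_remainder(self):
        # enriched in 2 tissues below five-fold, two tissues undetected
        out = self._classify([[4, 4, 1.5, 1.5, 1.5, 1.5, 1.5, 1.5, 0.2, 0.2]])
        assert out.iloc[0]["category"] == "Mixed"
        assert out.iloc[0]["group"] == ""

    def test_boundary_fold_exactly_five_is_specific(self):
        out = self._classify([[50, 10, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]])
        assert out.iloc[0]["category"] == "TissueSpecific"

    def test_partition_covers_all_genes(self, default_sim):
        _, atlas, _, _ = default_sim
        prof = filter_genes(average_replicates(atlas))
        out = classify_genes(prof, compute_tau(prof))
        counts = out["category"].value_counts()
        assert counts.sum() == len(prof)
        assert (counts > 0).all()

    def test_noiseless_recovery_is_exact(self, noiseless_sim):
        _, atlas, _, truth = noiseless_sim
        prof = filter_genes(average_replicates(atlas))
        out = classify_genes(prof, compute_tau(prof))
        truth_cat = truth.genes.loc[out.index, "category"]
        assert (out["category"].astype(str) == truth_cat).all()

    def test_housekeeping_band(self, noiseless_sim):
        _, atlas, _, truth = noiseless_sim
        prof = filter_genes(average_replicates(atlas))
        tau = compute_tau(prof)
        hk = truth.genes.index[truth.genes["category"] == "ExpressedInAll"]
        assert (tau.loc[hk, "tau"] < 0.3).all()


class TestTissueCorrelation:
    def test_identical_columns_correlate_perfectly(self):
        col = np.array([1.0, 5.0, 20.0, 3.0])
        prof = make_profile(np.column_stack([col, col, col * 1.0]))
        corr = tissue_correlation(prof)
        np.testing.assert_allclose(corr.values, 1.0, atol=1e-12)

    def test_antiproportional_log_columns(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        a = 2.0**u - 1.0
        b = 2.0 ** (5.0 - u) - 1.0
        prof = make_profile(np.column_stack([a, b]))
        corr = tissue_correlation(prof)
        assert corr.iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_column_reported_missing(self):
        prof = make_profile(np.column_stack([
            [1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0],
        ]))
        corr = tissue_correlation(prof)
        assert np.isnan(corr.iloc[0, 1])
        assert corr.iloc[0, 0] == pytest.approx(1.0)

    def test_matches_pairwise_loop(self, rng):
        X = rng.uniform(0, 100, (50, 5))
        prof = make_profile(X)
        corr = tissue_correlation(prof)
        logx = np.log2(X + 1)
        for i in range(5):
            for j in range(5):
                xi, xj = logx[:, i], logx[:, j]
                num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
                den = np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
                assert corr.iloc[i, j] == pytest.approx(num / den, abs=1e-10)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="3 genes"):
            tissue_correlation(make_profile([[1, 2], [3, 4]]))


class TestFoldchangeTauCorrelation:
    @staticmethod
    def _table(tau, fold):
        return pd.DataFrame({"tau": tau, "fold_over_rest": fold},
                            index=[f"g{i}" for i in range(len(tau))])

    def test_monotone_association_is_one(self):
        tau = np.linspace(0.1, 0.9, 12)
        rho, _ = foldchange_tau_correlation(self._table(tau, 2.0 ** np.arange(12)))
        assert rho == pytest.approx(1.0)

    def test_reversed_association_is_minus_one(self):
        tau = np.linspace(0.1, 0.9, 12)
        rho, _ = foldchange_tau_correlation(self._table(tau, 2.0 ** -np.arange(12.0)))
        assert rho == pytest.approx(-1.0)

    def test_synthetic_atlas_shows_positive_association(self, default_sim):
        _, atlas, _, _ = default_sim
        prof = filter_genes(average_replicates(atlas))
        out = classify_genes(prof, compute_tau(prof))
        rho, p = foldchange_tau_correlation(out)
        assert rho > 0
        assert p < 0.01

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="10 genes"):
            foldchange_tau_correlation(self._table([0.5] * 5, [2.0] * 5))
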
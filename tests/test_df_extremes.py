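"""DF extremes: proband selection, transformation, regression identities,
capping, and the extremes genetic correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from twinace import df_extremes as dfx
from twinace import preprocess as prep
from twinace import synthetic_twins as st

from conftest import univariate_paths


def _frame(zygosity, t1, t2, sex="M", start_id=0):
    n = len(t1)
    return pd.DataFrame(
        {
            "family_id": np.arange(start_id, start_id + n),
            "zygosity": zygosity,
            "sex": sex,
            "age": 12.0,
            "x_t1": np.asarray(t1, dtype=float),
            "x_t2": np.asarray(t2, dtype=float),
        }
    )


@pytest.fixture(scope="module")
def balanced_toy():
    """Proband scores identical across zygosity groups (orthogonal design).

    Twin-1 scores sit above every twin-2 score, so a 50% selection picks
    exactly the twin-1s; the proband-score column is then identical in the
    MZ and DZ cells, which makes the relatedness regressor orthogonal to it.
    """
    proband = np.array([9.0, 10.0, 11.0])
    mz = _frame("MZ", proband, [7.5, 8.0, 8.5], start_id=0)
    dz = _frame("DZ", proband, [6.25, 6.75, 7.25], start_id=3)
    return pd.concat([mz, dz], ignore_index=True)


class TestSelection:
    def test_top_five_percent_of_forty_values(self):
        rec = _frame("MZ", np.arange(20, dtype=float), np.arange(20, 40, dtype=float))
        pb = dfx.select_probands(rec, "x", "high", 0.05)
        assert pb.n == 2
        assert sorted(s for f, t in pb.ids for s in [rec.iloc[f][f"x_t{t}"]]) == [38.0, 39.0]

    def test_low_tail_mirrors_high_tail_on_negated_scores(self):
        rng = np.random.default_rng(0)
        rec = _frame("MZ", rng.standard_normal(200), rng.standard_normal(200))
        neg = rec.copy()
        neg[["x_t1", "x_t2"]] = -neg[["x_t1", "x_t2"]]
        high = dfx.select_probands(rec, "x", "high", 0.1)
        low = dfx.select_probands(neg, "x", "low", 0.1)
        assert sorted(high.ids) == sorted(low.ids)
        assert high.proband_mean == pytest.approx(-low.proband_mean)

    def test_ties_at_threshold_included(self):
        scores = np.array([1.0, 2.0, 3.0, 3.0, 3.0, 0.0, 1.5, 2.5, 0.5, 2.0])
        rec = _frame("MZ", scores[:5], scores[5:])
        pb = dfx.select_probands(rec, "x", "high", 0.3)
        vals = [rec.iloc[f][f"x_t{t}"] for f, t in pb.ids]
        assert vals.count(3.0) == 3

    def test_proband_mean_matches_truncated_normal_oracle(self):
        # E[Z | Z > z_0.95] = phi(z_0.95)/0.05 ~= 2.063
        pm = univariate_paths(0.0, 0.0, 1.0)
        cfg = st.SimulationConfig(
            n_pairs_per_group=25_000, true_paths={"M": pm, "F": pm},
            phenotype_names=("x",), seed=31,
        )
        rec = st.simulate_twin_dataset(cfg)
        prepared, _ = prep.preprocess_dataset(rec, [prep.PhenotypeSpec("x")])
        pb = dfx.select_probands(prepared, "x", "high", 0.05)
        from scipy import stats as ss

        z95 = ss.norm.ppf(0.95)
        assert pb.proband_mean == pytest.approx(ss.norm.pdf(z95) / 0.05, abs=0.03)

    def test_proportion_out_of_range_rejected(self):
        rec = _frame("MZ", [1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError, match="proportion"):
            dfx.select_probands(rec, "x", "high", 0.6)


class TestTransform:
    def test_endpoints(self):
        assert dfx.df_transform([3.0], 5.0, 3.0)[0] == 0.0
        assert dfx.df_transform([5.0], 5.0, 3.0)[0] == 1.0

    def test_proband_mean_maps_to_one_exactly(self, two_trait_prepared):
        pb = dfx.select_probands(two_trait_prepared, "traits", "high", 0.05)
        scores = []
        idx = two_trait_prepared.set_index("family_id")
        for fam, twin in pb.ids:
            scores.append(idx.loc[fam][f"traits_t{twin}"])
        out = dfx.df_transform(scores, pb.proband_mean, pb.population_mean)
        assert out.mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            dfx.df_transform([1.0], 2.0, 2.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        pm=hst.floats(min_value=0.5, max_value=5.0),
        pop=hst.floats(min_value=-0.4, max_value=0.4),
    )
    def test_transform_is_affine_with_fixed_points(self, pm, pop):
        x = np.array([pop, pm, (pop + pm) / 2])
        out = dfx.df_transform(x, pm, pop)
        np.testing.assert_allclose(out, [0.0, 1.0, 0.5], atol=1e-9)


class TestCotwinMeans:
    def test_identical_cotwins_give_unit_mz_mean(self):
        scores = np.array([5.0, 6.0, 7.0, 0.0, 0.1, -0.1])
        rec = _frame("MZ", scores[:3], scores[:3], start_id=0)
        rec2 = _frame("DZ", scores[:3], scores[3:], start_id=3)
        rec = pd.concat([rec, rec2], ignore_index=True)
        pb = dfx.select_probands(rec, "x", "high", 0.5)
        mu_mz, _ = dfx.transformed_cotwin_means(pb, rec, "x")
        assert mu_mz == pytest.approx(1.0)

    def test_mz_regresses_less_than_dz_under_genetic_influence(self):
        pm = univariate_paths(0.6, 0.2)
        cfg = st.SimulationConfig(
            n_pairs_per_group=25_000, true_paths={"M": pm, "F": pm},
            phenotype_names=("x",), seed=33,
        )
        prepared, _ = prep.preprocess_dataset(
            st.simulate_twin_dataset(cfg), [prep.PhenotypeSpec("x")]
        )
        pb = dfx.select_probands(prepared, "x", "high", 0.05)
        mu_mz, mu_dz = dfx.transformed_cotwin_means(pb, prepared, "x")
        assert mu_mz > mu_dz > 0.0

    def test_independent_outcome_means_near_zero(self):
        pm2 = st.paths_from_structure(
            {"A": (0.6, 0.6), "E": (0.4, 0.4)}, {"A": np.eye(2), "E": np.eye(2)}
        )
        cfg = st.SimulationConfig(
            n_pairs_per_group=25_000, true_paths={"M": pm2, "F": pm2},
            phenotype_names=("x", "y"), seed=34,
        )
        prepared, _ = prep.preprocess_dataset(
            st.simulate_twin_dataset(cfg),
            [prep.PhenotypeSpec("x"), prep.PhenotypeSpec("y")],
        )
        pb = dfx.select_probands(prepared, "x", "high", 0.05)
        py = dfx.select_probands(prepared, "y", "high", 0.05)
        mu_mz, mu_dz = dfx.transformed_cotwin_means(
            pb, prepared, "y", (py.proband_mean, py.population_mean)
        )
        assert abs(mu_mz) < 0.05 and abs(mu_dz) < 0.05


class TestUnivariateDF:
    def test_beta2_equals_twice_mean_difference_on_balanced_design(self, balanced_toy):
        pb = dfx.select_probands(balanced_toy, "x", "high", 0.5)
        res = dfx.univariate_df(pb, balanced_toy, covariates=())
        assert res.zygosity_coef == pytest.approx(2 * (res.mu_mz - res.mu_dz), abs=1e-10)

    def test_capping_engages_exactly_when_beta2_exceeds_mz_mean(self, balanced_toy):
        # wide MZ/DZ gap: beta2 = 2(mu_mz - mu_dz) overshoots mu_mz -> capped
        low = balanced_toy.copy()
        low.loc[low.zygosity == "DZ", "x_t2"] = [0.0, 0.5, 1.0]
        pb = dfx.select_probands(low, "x", "high", 0.5)
        res = dfx.univariate_df(pb, low, covariates=())
        assert res.cap_applied == (res.zygosity_coef > res.mu_mz)
        assert res.cap_applied
        assert res.capped_estimate == pytest.approx(res.mu_mz)
        # shared-environment-dominated trait: mu_dz > mu_mz/2 -> no cap
        pm = univariate_paths(0.2, 0.6)
        cfg = st.SimulationConfig(
            n_pairs_per_group=5000, true_paths={"M": pm, "F": pm},
            phenotype_names=("x",), seed=44,
        )
        prepared, _ = prep.preprocess_dataset(
            st.simulate_twin_dataset(cfg), [prep.PhenotypeSpec("x")]
        )
        pb2 = dfx.select_probands(prepared, "x", "high", 0.05)
        res2 = dfx.univariate_df(pb2, prepared)
        assert res2.cap_applied == (res2.zygosity_coef > res2.mu_mz)
        assert not res2.cap_applied
        assert res2.capped_estimate == pytest.approx(res2.zygosity_coef)

    def test_equal_cotwin_means_give_zero_heritability(self):
        proband = np.array([9.0, 10.0, 11.0])
        cot = np.array([4.0, 5.0, 6.0])
        rec = pd.concat(
            [_frame("MZ", proband, cot), _frame("DZ", proband, cot, start_id=3)],
            ignore_index=True,
        )
        pb = dfx.select_probands(rec, "x", "high", 0.5)
        res = dfx.univariate_df(pb, rec, covariates=())
        assert res.zygosity_coef == pytest.approx(0.0, abs=1e-10)

    def test_twin_order_permutation_invariance(self, two_trait_prepared):
        pb = dfx.select_probands(two_trait_prepared, "traits", "high", 0.1)
        base = dfx.univariate_df(pb, two_trait_prepared)
        rec = two_trait_prepared.copy()
        rng = np.random.default_rng(1)
        swap = rng.random(len(rec)) < 0.5
        for p in ("traits", "vocabulary"):
            rec.loc[swap, [f"{p}_t1", f"{p}_t2"]] = rec.loc[
                swap, [f"{p}_t2", f"{p}_t1"]
            ].to_numpy()
        pb2 = dfx.select_probands(rec, "traits", "high", 0.1)
        res2 = dfx.univariate_df(pb2, rec)
        assert res2.zygosity_coef == pytest.approx(base.zygosity_coef, abs=1e-10)
        assert res2.mu_mz == pytest.approx(base.mu_mz, abs=1e-12)

    def test_group_heritability_tracks_generating_a2(self):
        pm = univariate_paths(0.6, 0.2)
        cfg = st.SimulationConfig(
            n_pairs_per_group=25_000, true_paths={"M": pm, "F": pm},
            phenotype_names=("x",), seed=35,
        )
        prepared, _ = prep.preprocess_dataset(
            st.simulate_twin_dataset(cfg), [prep.PhenotypeSpec("x")]
        )
        pb = dfx.select_probands(prepared, "x", "high", 0.05)
        res = dfx.univariate_df(pb, prepared)
        assert res.capped_estimate == pytest.approx(0.6, abs=0.07)


class TestBivariateDF:
    @pytest.fixture(scope="class")
    def overlap(self):
        corr = {"A": np.full((2, 2), 1.0), "C": np.eye(2), "E": np.eye(2)}
        np.fill_diagonal(corr["A"], 1.0)
        pm = st.paths_from_structure({"A": (0.6, 0.6), "C": (0.2, 0.2), "E": (0.2, 0.2)}, corr)
        cfg = st.SimulationConfig(
            n_pairs_per_group=25_000, true_paths={"M": pm, "F": pm},
            phenotype_names=("x", "y"), seed=36,
        )
        prepared, _ = prep.preprocess_dataset(
            st.simulate_twin_dataset(cfg),
            [prep.PhenotypeSpec("x"), prep.PhenotypeSpec("y")],
        )
        return prepared

    def test_same_outcome_reduces_to_univariate(self, two_trait_prepared):
        pb = dfx.select_probands(two_trait_prepared, "traits", "high", 0.1)
        uni = dfx.univariate_df(pb, two_trait_prepared)
        biv = dfx.bivariate_df(pb, two_trait_prepared, "traits", pb)
        assert biv.zygosity_coef == pytest.approx(uni.zygosity_coef, abs=1e-12)
        assert biv.capped_estimate == pytest.approx(uni.capped_estimate, abs=1e-12)

    def test_no_shared_etiology_gives_zero_bivariate_heritability(self):
        pm2 = st.paths_from_structure(
            {"A": (0.6, 0.6), "C": (0.2, 0.2), "E": (0.2, 0.2)},
            {"A": np.eye(2), "C": np.eye(2), "E": np.eye(2)},
        )
        cfg = st.SimulationConfig(
            n_pairs_per_group=25_000, true_paths={"M": pm2, "F": pm2},
            phenotype_names=("x", "y"), seed=37,
        )
        prepared, _ = prep.preprocess_dataset(
            st.simulate_twin_dataset(cfg),
            [prep.PhenotypeSpec("x"), prep.PhenotypeSpec("y")],
        )
        px = dfx.select_probands(prepared, "x", "high", 0.05)
        py = dfx.select_probands(prepared, "y", "high", 0.05)
        res = dfx.bivariate_df(px, prepared, "y", py)
        assert abs(res.zygosity_coef) < 0.06

    def test_full_genetic_overlap_explains_group_correlation(self, overlap):
        px = dfx.select_probands(overlap, "x", "high", 0.05)
        py = dfx.select_probands(overlap, "y", "high", 0.05)
        res = dfx.bivariate_df(px, overlap, "y", py)
        assert res.ratio_to_group_correlation == pytest.approx(1.0, abs=0.12)

    def test_extremes_rg_recovers_full_overlap(self, overlap):
        px = dfx.select_probands(overlap, "x", "high", 0.05)
        py = dfx.select_probands(overlap, "y", "high", 0.05)
        fwd = dfx.bivariate_df(px, overlap, "y", py)
        rev = dfx.bivariate_df(py, overlap, "x", px)
        ux = dfx.univariate_df(px, overlap)
        uy = dfx.univariate_df(py, overlap)
        rg = dfx.extremes_genetic_correlation(
            fwd.capped_estimate, rev.capped_estimate, ux.capped_estimate, uy.capped_estimate
        )
        assert rg.valid
        assert rg.r_g == pytest.approx(1.0, abs=0.1)


class TestGroupCorrelation:
    def test_self_correlation_is_one(self, two_trait_prepared):
        pb = dfx.select_probands(two_trait_prepared, "traits", "high", 0.05)
        assert dfx.group_phenotypic_correlation(
            pb, two_trait_prepared, "traits"
        ) == pytest.approx(1.0)

    def test_matches_population_correlation_oracle(self):
        # truncated bivariate normal: E[Y | X > t] / E[X | X > t] = rho
        rho = 0.6
        pm = st.paths_from_structure(
            {"A": (0.5, 0.5), "E": (0.5, 0.5)},
            {"A": np.full((2, 2), rho) + np.eye(2) * (1 - rho),
             "E": np.full((2, 2), rho) + np.eye(2) * (1 - rho)},
        )
        cfg = st.SimulationConfig(
            n_pairs_per_group=25_000, true_paths={"M": pm, "F": pm},
            phenotype_names=("x", "y"), seed=38,
        )
        prepared, _ = prep.preprocess_dataset(
            st.simulate_twin_dataset(cfg),
            [prep.PhenotypeSpec("x"), prep.PhenotypeSpec("y")],
        )
        px = dfx.select_probands(prepared, "x", "high", 0.05)
        got = dfx.group_phenotypic_correlation(px, prepared, "y")
        assert got == pytest.approx(rho, abs=0.05)


class TestExtremesRg:
    def test_equal_inputs_give_unity(self):
        assert dfx.extremes_genetic_correlation(0.4, 0.4, 0.4, 0.4).r_g == pytest.approx(1.0)

    def test_zero_cross_heritability_gives_zero(self):
        assert dfx.extremes_genetic_correlation(0.0, 0.3, 0.6, 0.5).r_g == 0.0

    def test_arithmetic_oracle(self):
        got = dfx.extremes_genetic_correlation(0.2, 0.3, 0.6, 0.5)
        assert got.r_g == pytest.approx(np.sqrt(0.06 / 0.30), abs=1e-12)

    def test_symmetric_in_trait_labels(self):
        a = dfx.extremes_genetic_correlation(0.2, 0.3, 0.6, 0.5)
        b = dfx.extremes_genetic_correlation(0.3, 0.2, 0.5, 0.6)
        assert a.r_g == pytest.approx(b.r_g, abs=1e-12)

    def test_invalid_when_group_heritabilities_not_positive(self):
        got = dfx.extremes_genetic_correlation(0.2, 0.3, -0.1, 0.5)
        assert not got.valid and np.isnan(got.r_g)

    def test_clipped_when_ratio_exceeds_one(self):
        got = dfx.extremes_genetic_correlation(0.9, 0.9, 0.3, 0.3)
        assert got.clipped and got.r_g == 1.0
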
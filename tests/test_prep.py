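"""Generation windows, response aggregation, filters, PCA and screens."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from vinescape import prep
from vinescape.prep import (
    FALLBACK_WINDOWS,
    apply_filters,
    assign_generations,
    build_responses,
    climate_pca,
    collinearity_screen,
    estimate_generation_windows,
    flag_never_sprayers,
)


def _mixture(doy):
    """Three-peaked seasonal curve used as a known phenology."""
    return (
        6.0 * np.exp(-((doy - 100.0) ** 2) / (2 * 14.0**2))
        + 9.0 * np.exp(-((doy - 170.0) ** 2) / (2 * 14.0**2))
        + 13.0 * np.exp(-((doy - 235.0) ** 2) / (2 * 16.0**2))
    )


class TestGenerationWindows:
    def test_boundaries_near_analytic_troughs(self, rng):
        days = rng.integers(60, 274, 4000)
        dates = pd.to_datetime("2010-01-01") + pd.to_timedelta(
            days - 1, unit="D"
        )
        visits = pd.DataFrame(
            {
                "date": dates,
                "infested_pct": _mixture(days) + rng.normal(0, 1.0, len(days)),
            }
        )
        windows = estimate_generation_windows(visits)
        # analytic troughs of the known mixture
        t1 = minimize_scalar(_mixture, bounds=(100, 170), method="bounded").x
        t2 = minimize_scalar(_mixture, bounds=(170, 235), method="bounded").x
        assert abs(windows[0].end_day - t1) <= 10
        assert abs(windows[1].end_day - t2) <= 10
        assert [w.generation for w in windows] == [1, 2, 3]
        assert windows[0].start_day == 60 and windows[2].end_day == 273

    def test_monotone_curve_falls_back(self, rng):
        days = rng.integers(60, 274, 800)
        visits = pd.DataFrame(
            {
                "date": pd.to_datetime("2010-01-01")
                + pd.to_timedelta(days - 1, unit="D"),
                "infested_pct": 0.1 * days + rng.normal(0, 0.5, len(days)),
            }
        )
        with pytest.warns(UserWarning, match="falling back"):
            windows = estimate_generation_windows(visits)
        assert windows == list(FALLBACK_WINDOWS)

    def test_mid_june_is_generation_two_under_fallback(self):
        visits = pd.DataFrame(
            {"date": [pd.Timestamp("2010-06-15")], "infested_pct": [1.0]}
        )
        out = assign_generations(visits, list(FALLBACK_WINDOWS))
        assert out["generation"].iloc[0] == 2

    def test_no_seasonal_visits_raises(self):
        visits = pd.DataFrame(
            {"date": [pd.Timestamp("2010-01-05")], "infested_pct": [0.0]}
        )
        with pytest.raises(ValueError):
            estimate_generation_windows(visits)


class TestBuildResponses:
    def _mgmt(self, rows):
        return pd.DataFrame(
            rows, columns=["farm_id", "year", "date", "event_type",
                           "target_pest"]
        )

    def test_strict_threshold_exceedance(self, toy_visits):
        gen, season = build_responses(
            toy_visits, self._mgmt([]), list(FALLBACK_WINDOWS)
        )
        assert season["n_exceed"].iloc[0] == 2  # 9 and 12; 8 does not exceed
        assert season["n_visits"].iloc[0] == 5
        assert season["mean_infestation"].iloc[0] == pytest.approx(6.8)

    def test_no_row_for_empty_generation(self, toy_visits):
        gen, _ = build_responses(
            toy_visits, self._mgmt([]), list(FALLBACK_WINDOWS)
        )
        # toy visits cover generations 1 (2 visits), 2 (2), 3 (1)
        got = gen.set_index("generation")["n_visits"].to_dict()
        assert got == {1: 2, 2: 2, 3: 1}

    def test_spray_count_only_targeted_rows(self, toy_visits):
        rows = [
            (1, 2010, pd.Timestamp("2010-06-25"), "insecticide",
             "lobesia_botrana")
        ] * 3 + [
            (1, 2010, pd.Timestamp("2010-07-01"), "insecticide", "other")
        ] * 2
        _, season = build_responses(
            toy_visits, self._mgmt(rows), list(FALLBACK_WINDOWS)
        )
        assert season["spray_count"].iloc[0] == 3
        assert season["ever_exceeded"].iloc[0] == 1

    def test_unknown_farm_in_management(self, toy_visits):
        rows = [(99, 2010, pd.Timestamp("2010-06-25"), "insecticide",
                 "lobesia_botrana")]
        with pytest.raises(ValueError, match="unknown farms"):
            build_responses(toy_visits, self._mgmt(rows),
                            list(FALLBACK_WINDOWS))

    def test_exceedance_conservation(self, small_study):
        gen, _ = build_responses(
            small_study.visits, small_study.management,
            list(FALLBACK_WINDOWS),
        )
        per_fy = gen.groupby(["farm_id", "year"])[["n_exceed", "n_visits"]]
        sums = per_fy.sum()
        assert (sums["n_exceed"] <= sums["n_visits"]).all()


class TestFilters:
    def _tables(self):
        gen = pd.DataFrame(
            {
                "farm_id": [1, 2, 3],
                "year": 2010,
                "generation": 1,
                "n_visits": [3, 4, 10],
            }
        )
        season = pd.DataFrame(
            {"farm_id": [1, 2], "year": 2010, "n_visits": [9, 10]}
        )
        return gen, season

    def test_boundaries(self):
        gen, season = self._tables()
        g, s, report = apply_filters(gen, season)
        assert g["farm_id"].tolist() == [2, 3]  # 3 visits dropped, 4 kept
        assert s["farm_id"].tolist() == [2]  # 9 season visits dropped
        assert report["generation_rows_dropped"] == 1
        assert report["season_rows_dropped"] == 1

    def test_idempotent_and_never_grows(self):
        gen, season = self._tables()
        g1, s1, _ = apply_filters(gen, season)
        g2, s2, _ = apply_filters(g1, s1)
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(s1, s2)
        assert len(g1) <= len(gen) and len(s1) <= len(season)


class TestClimatePCA:
    def _weather(self, temps, precs=None):
        n_st, n_m = temps.shape
        rows = []
        for s in range(n_st):
            for m in range(n_m):
                rows.append(
                    (s, float(s), 0.0, 2010, m + 1, temps[s, m],
                     precs[s, m] if precs is not None else temps[s, m] + 1)
                )
        return pd.DataFrame(
            rows, columns=["station_id", "x", "y", "year", "month",
                           "temperature_c", "precip_mm"],
        )

    def test_rank_one_matrix_first_axis_explains_all(self, rng):
        base = rng.normal(0, 1, 12)
        coef = rng.normal(0, 1, 8)
        temps = np.outer(coef, base) + 5.0
        pca_t, _, _ = climate_pca(
            self._weather(temps + rng.normal(0, 1e-9, temps.shape)),
            pd.DataFrame({"farm_id": [0], "x": [0.0], "y": [0.0]}),
        )
        assert pca_t.variance_explained[0] == pytest.approx(1.0, abs=1e-6)

    def test_variance_explained_matches_eigendecomposition(self, rng):
        temps = rng.normal(15, 4, (10, 12))
        pca_t, _, _ = climate_pca(
            self._weather(temps),
            pd.DataFrame({"farm_id": [0], "x": [0.0], "y": [0.0]}),
        )
        Xc = temps - temps.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        k = min(len(eig), len(pca_t.variance_explained))
        np.testing.assert_allclose(
            pca_t.variance_explained[:k], (eig / eig.sum())[:k], atol=1e-9
        )
        assert np.all(np.diff(pca_t.variance_explained) <= 1e-12)

    def test_rank_two_reconstruction_error(self, rng):
        """Scores+loadings reproduce the centred station matrix up to the
        trailing eigenvalues (best rank-2 approximation)."""
        temps = rng.normal(15, 4, (10, 12))
        pca_t, _, _ = climate_pca(
            self._weather(temps),
            pd.DataFrame({"farm_id": [0], "x": [0.0], "y": [0.0]}),
        )
        Xc = temps - temps.mean(axis=0)
        approx = pca_t.scores.to_numpy() @ pca_t.loadings.T
        err = np.sum((Xc - approx) ** 2)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        assert err == pytest.approx(eig[2:].sum(), rel=1e-9)

    def test_farm_inherits_nearest_station_ties_to_lowest_id(self, rng):
        temps = rng.normal(15, 4, (4, 12))
        weather = self._weather(temps)
        # farm at x=0.5 equidistant from stations 0 (x=0) and 1 (x=1)
        farms = pd.DataFrame({"farm_id": [7], "x": [0.5], "y": [0.0]})
        _, _, scores = climate_pca(weather, farms)
        assert scores["station_id"].iloc[0] == 0

    def test_too_few_stations(self, rng):
        temps = rng.normal(15, 4, (2, 12))
        with pytest.raises(ValueError, match="3 weather stations"):
            climate_pca(
                self._weather(temps),
                pd.DataFrame({"farm_id": [0], "x": [0.0], "y": [0.0]}),
            )


class TestCollinearityScreen:
    def test_slope_dropped_in_favour_of_altitude(self, rng):
        alt = rng.normal(300, 50, 200)
        df = pd.DataFrame(
            {
                "altitude": alt,
                "slope": 0.05 * alt + rng.normal(0, 1.2, 200),
                "aspect": rng.uniform(0, 360, 200),
            }
        )
        assert abs(df["altitude"].corr(df["slope"])) > 0.5
        kept, report = collinearity_screen(df)
        assert "slope" not in kept and "altitude" in kept
        assert report["dropped"][0]["covariate"] == "slope"

    def test_orthogonal_covariates_all_retained(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (500, 4)),
                          columns=list("abcd"))
        kept, _ = collinearity_screen(df)
        assert kept == list("abcd")

    def test_survivors_have_no_high_correlation(self, rng):
        z = rng.normal(0, 1, 300)
        df = pd.DataFrame(
            {
                "a": z + rng.normal(0, 0.3, 300),
                "b": z + rng.normal(0, 0.3, 300),
                "c": z + rng.normal(0, 0.3, 300),
                "d": rng.normal(0, 1, 300),
            }
        )
        kept, _ = collinearity_screen(df)
        sub = df[kept].corr().abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.5

    def test_constant_covariate_dropped_with_warning(self, rng):
        df = pd.DataFrame(
            {"a": rng.normal(0, 1, 50), "flat": np.ones(50)}
        )
        with pytest.warns(UserWarning, match="constant"):
            kept, _ = collinearity_screen(df)
        assert kept == ["a"]


class TestNeverSprayers:
    def _mgmt(self):
        return pd.DataFrame(
            {
                "farm_id": [1, 1, 2, 3],
                "year": 2010,
                "date": pd.Timestamp("2010-06-01"),
                "event_type": ["insecticide", "fungicide", "insecticide",
                               "herbicide"],
                "target_pest": ["other", "", "lobesia_botrana", ""],
            }
        )

    def test_other_target_insecticide_counts_as_spraying(self):
        flagged = flag_never_sprayers(self._mgmt())
        assert 1 not in flagged  # sprayed, though at another pest
        assert flagged == {3}

    def test_universe_extension(self):
        flagged = flag_never_sprayers(self._mgmt(), farms=[1, 2, 3, 4])
        assert flagged == {3, 4}

    def test_set_complement_oracle(self, small_study):
        m = small_study.management
        flagged = flag_never_sprayers(m)
        oracle = set(m["farm_id"]) - set(
            m.loc[m["event_type"] == "insecticide", "farm_id"]
        )
        assert flagged == oracle
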
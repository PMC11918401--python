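import numpy as np
import pandas as pd
import pytest

import sulaniche as sn
from sulaniche.geo import haversine_km
from sulaniche.synthetic import (
    ColonySpec,
    IsotopeGroupSpec,
    MorphoGroupSpec,
    RegurgitateSpec,
    StateKinematics,
    gen_isotopes,
    gen_morphometrics,
    gen_regurgitates,
    gen_tracks,
)


class TestSpecs:
    def test_colony_validates_ranges(self):
        with pytest.raises(ValueError):
            ColonySpec(latitude=95.0, longitude=0.0)
        with pytest.raises(ValueError):
            ColonySpec(latitude=0.0, longitude=0.0, exclusion_radius_m=0.0)

    def test_state_rejects_bad_label_and_moments(self):
        with pytest.raises(ValueError):
            StateKinematics("XX", 1.0, 0.5, 0.9, 60.0)
        with pytest.raises(ValueError):
            StateKinematics("LL", 1.0, 0.0, 0.9, 60.0)

    def test_isotope_spec_rejects_degenerate_correlation(self):
        with pytest.raises(ValueError):
            IsotopeGroupSpec("g", -15.0, 12.0, 0.4, 0.2, correlation=1.0, n=10)

    def test_regurgitate_spec_rejects_negative_allometry(self):
        with pytest.raises(ValueError):
            RegurgitateSpec("f", 13.6, 0.6, 8.0, length_mass_a=-1.0)

    def test_morpho_spec_rejects_non_pd_covariance(self):
        spec = MorphoGroupSpec("female", (1542, 96.3, 53.4, 409), (89, 3, 2.1, 8), n=5, correlation=1.0)
        with pytest.raises(ValueError):
            spec.covariance()


class TestTracks:
    def test_same_seed_byte_identical(self):
        a = gen_tracks(n_individuals=2, trips_per_individual=1, seed=3)
        b = gen_tracks(n_individuals=2, trips_per_individual=1, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_trips_stay_inside_radius(self, colony):
        fx = gen_tracks(colony, n_individuals=3, trips_per_individual=0, seed=1)
        d_km = haversine_km(fx["lat"], fx["lon"], colony.latitude, colony.longitude)
        assert (np.asarray(d_km) <= colony.exclusion_radius_km).all()
        assert sn.tracks.segment_trips(fx, colony) == []

    def test_duplicate_state_labels_rejected(self, colony):
        states = sn.synthetic.default_states()
        states[1] = StateKinematics("LL", 3.5, 1.2, 0.6, 120.0)
        with pytest.raises(ValueError, match="exactly once"):
            gen_tracks(colony, states, n_individuals=1, seed=0)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            gen_tracks(n_individuals=0, seed=0)
        with pytest.raises(ValueError):
            gen_tracks(n_individuals=1, fix_interval_s=0.0, seed=0)

    def test_tracks_start_and_end_at_colony(self, benchmark_fixes, colony):
        for _, grp in benchmark_fixes.groupby("id"):
            for row in (grp.iloc[0], grp.iloc[-1]):
                d = haversine_km(row["lat"], row["lon"], colony.latitude, colony.longitude)
                assert d <= colony.exclusion_radius_km

    def test_ground_truth_labels_retained(self, benchmark_fixes):
        assert set(benchmark_fixes["true_state"]) == {"LL", "LH", "HL", "HH"}


class TestIsotopes:
    def test_reproducible_and_grouped(self):
        a = gen_isotopes(seed=5)
        b = gen_isotopes(seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert a.groupby("group").size().to_dict() == {
            "female_2016": 14,
            "male_2016": 9,
            "female_2019": 20,
            "male_2019": 12,
        }

    def test_sd_to_zero_collapses_to_mean(self):
        spec = IsotopeGroupSpec("g_1", -15.0, 12.6, 1e-9, 1e-9, n=10)
        df = gen_isotopes([spec], seed=0)
        assert np.allclose(df["d13C"], -15.0)
        assert sn.trophic.mdc(df[["d13C", "d15N"]].to_numpy()) < 1e-7

    def test_moment_recovery_at_large_n(self):
        spec = IsotopeGroupSpec("g_1", -15.0, 12.6, 0.4, 0.2, correlation=0.3, n=5000)
        df = gen_isotopes([spec], seed=2)
        # CLT bound: sample mean within 3 sd / sqrt(n)
        assert abs(df["d13C"].mean() + 15.0) < 3 * 0.4 / np.sqrt(5000)
        assert abs(df["d15N"].mean() - 12.6) < 3 * 0.2 / np.sqrt(5000)
        assert df["d13C"].std() == pytest.approx(0.4, rel=0.1)

    def test_identical_specs_give_nominal_rejection_rate(self):
        """Two groups from one distribution: the position test rejects ~5%."""
        rejections = 0
        reps = 200
        for r in range(reps):
            df = gen_isotopes(
                [
                    IsotopeGroupSpec("a_1", -15.0, 12.6, 0.4, 0.2, n=14),
                    IsotopeGroupSpec("b_1", -15.0, 12.6, 0.4, 0.2, n=12),
                ],
                seed=10_000 + r,
            )
            a = df[df["group"] == "a_1"][["d13C", "d15N"]].to_numpy()
            b = df[df["group"] == "b_1"][["d13C", "d15N"]].to_numpy()
            if sn.trophic.position_permutation_test(a, b, n_perm=199, seed=r).p <= 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.10


class TestRegurgitates:
    def test_single_species_full_occurrence(self):
        spec = RegurgitateSpec("female", 13.6, 0.6, 8.0)
        items = gen_regurgitates([spec], n_samples=20, seed=0)
        summary = sn.morpho_diet.diet_summary(items)
        assert summary["fo_pct"]["anchoveta"] == 100.0
        assert summary["mass_pct"]["anchoveta"] == 100.0

    def test_single_sample_single_item(self):
        spec = RegurgitateSpec("f", 13.6, 0.6, mean_n_items=1e-9)
        items = gen_regurgitates([spec], n_samples=1, seed=0)
        assert len(items) == 1

    def test_cv_of_sample_means_matches_study_scale(self):
        """Female 13.6 +/- 0.6 cm and male 11.6 +/- 2.8 cm prey give CVs near 4.4% and 24.1%."""
        items = gen_regurgitates(
            [
                RegurgitateSpec("female", 13.6, 0.6, 8.0),
                RegurgitateSpec("male", 11.6, 2.8, 8.0),
            ],
            n_samples=200,
            seed=3,
        )
        per_sex = {
            sex: grp.groupby("sample_id")["length_mm"].mean()
            for sex, grp in items.groupby("sex")
        }
        cv_f = sn.morpho_diet.cv_percent(per_sex["female"])
        cv_m = sn.morpho_diet.cv_percent(per_sex["male"])
        assert cv_f == pytest.approx(4.4, abs=1.0)
        assert cv_m == pytest.approx(24.1, abs=4.0)

    def test_masses_follow_allometry(self):
        spec = RegurgitateSpec("f", 13.6, 0.6, 5.0, length_mass_a=0.0055, length_mass_b=3.0)
        items = gen_regurgitates([spec], n_samples=5, seed=1)
        expected = 0.0055 * (items["length_mm"] / 10.0) ** 3.0
        assert np.allclose(items["mass_g"], expected)


class TestMorphometrics:
    def test_same_seed_identical(self):
        pd.testing.assert_frame_equal(gen_morphometrics(seed=9), gen_morphometrics(seed=9))

    def test_zero_offdiag_gives_small_correlations(self):
        specs = [MorphoGroupSpec("female", (1542, 96.3, 53.4, 409), (89, 3, 2.1, 8), n=4000, correlation=0.0)]
        df = gen_morphometrics(specs, seed=4)
        corr = df[["mass_g", "culmen_mm", "tarsus_mm", "wing_mm"]].corr().to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.06

    def test_table_scale_means_reproduce_sdi(self):
        """Pooled-sex generator means recover the printed dimorphism at large n."""
        specs = [
            MorphoGroupSpec("female", (1542, 96.3, 53.4, 409), (89, 3, 2.1, 8), n=20000),
            MorphoGroupSpec("male", (1274, 90.5, 50.5, 395), (80, 3.1, 1.5, 9), n=20000),
        ]
        df = gen_morphometrics(specs, seed=6)
        female = df[df["sex"] == "female"]
        male = df[df["sex"] == "male"]
        assert sn.morpho_diet.sdi(male["mass_g"].mean(), female["mass_g"].mean()) == pytest.approx(17.4, abs=0.3)
        assert sn.morpho_diet.sdi(male["culmen_mm"].mean(), female["culmen_mm"].mean()) == pytest.approx(6.0, abs=0.2)
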
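import numpy as np
import pytest
from scipy.stats import chisquare

from rangerisk import (GridSpec, ScenarioDelta, apply_delta, generate_climate,
                       make_virtual_species, sample_presences, synthesize_study,
                       true_loss_fraction)
from rangerisk.grids import cell_area_km2


@pytest.fixture
def stack(small_grid):
    return generate_climate(small_grid, n_variables=3, seed=11)


class TestGenerateClimate:
    def test_same_seed_same_spec_is_bit_identical(self, small_grid):
        a = generate_climate(small_grid, 3, seed=5)
        b = generate_climate(small_grid, 3, seed=5)
        for name in a.layers:
            assert np.array_equal(a.layers[name], b.layers[name])

    def test_noiseless_duplicate_is_perfectly_correlated(self, small_grid):
        s = generate_climate(small_grid, 2, seed=1, duplicate_of="temp",
                             duplicate_noise_sd=0.0)
        r = np.corrcoef(s.layers["temp"].ravel(), s.layers["temp_dup"].ravel())
        assert r[0, 1] == pytest.approx(1.0)

    def test_noisy_duplicate_still_trips_the_correlation_filter(self, small_grid):
        s = generate_climate(small_grid, 2, seed=1, duplicate_of="temp",
                             duplicate_noise_sd=1.0)
        r = np.corrcoef(s.layers["temp"].ravel(), s.layers["temp_dup"].ravel())[0, 1]
        assert 0.8 < r < 1.0

    def test_invalid_specs_rejected(self, small_grid):
        with pytest.raises(ValueError):
            generate_climate(small_grid, 1, seed=0)
        with pytest.raises(KeyError):
            generate_climate(small_grid, 2, seed=0, duplicate_of="nope")


class TestApplyDelta:
    def test_zero_delta_is_identity(self, stack):
        out = apply_delta(stack, ScenarioDelta("S/h", {"temp": 0.0}))
        assert np.array_equal(out.layers["temp"], stack.layers["temp"])

    def test_shift_is_exactly_additive(self, stack):
        out = apply_delta(stack, ScenarioDelta("S/h", {"temp": 2.0}))
        assert np.allclose(out.layers["temp"] - stack.layers["temp"], 2.0)
        assert np.array_equal(out.layers["precip"], stack.layers["precip"])

    def test_delta_then_negation_restores_original(self, stack):
        fwd = apply_delta(stack, ScenarioDelta("S/h", {"temp": 1.7, "precip": -40.0}))
        back = apply_delta(fwd, ScenarioDelta("S/h", {"temp": -1.7, "precip": 40.0}))
        for name in stack.layers:
            assert np.allclose(back.layers[name], stack.layers[name], atol=1e-9)

    def test_unknown_variable_rejected(self, stack):
        with pytest.raises(KeyError):
            apply_delta(stack, ScenarioDelta("S/h", {"bogus": 1.0}))


class TestVirtualSpecies:
    def test_suitability_peaks_at_one_on_the_niche_center(self, stack):
        # pick a real cell's climate as the niche center
        mu = [stack.layers["temp"][10, 7], stack.layers["precip"][10, 7]]
        vs = make_virtual_species(stack, mu, np.diag([9.0, 1e4]), 0.3, "sp",
                                  niche_variables=["temp", "precip"])
        assert vs.suitability["current"][10, 7] == pytest.approx(1.0)
        assert vs.suitability["current"].max() == pytest.approx(1.0)

    def test_superlevel_sets_nested_in_threshold(self, stack):
        mu = [10.0, 1000.0]
        lo = make_virtual_species(stack, mu, np.diag([16.0, 4e4]), 0.1, "a",
                                  niche_variables=["temp", "precip"])
        hi = make_virtual_species(stack, mu, np.diag([16.0, 4e4]), 0.6, "b",
                                  niche_variables=["temp", "precip"])
        assert np.all(lo.true_ranges["current"][hi.true_ranges["current"]])
        assert hi.true_ranges["current"].sum() < lo.true_ranges["current"].sum()

    def test_invalid_niche_parameters_rejected(self, stack):
        with pytest.raises(np.linalg.LinAlgError):
            make_virtual_species(stack, [0, 0], np.zeros((2, 2)), 0.5, "x",
                                 niche_variables=["temp", "precip"])
        with pytest.raises(ValueError):
            make_virtual_species(stack, [0, 0], np.eye(2), 1.5, "x",
                                 niche_variables=["temp", "precip"])
        with pytest.raises(ValueError):
            make_virtual_species(stack, [0], np.eye(2), 0.5, "x",
                                 niche_variables=["temp", "precip"])

    def test_warming_shifts_range_poleward_with_countable_loss(self, small_grid):
        # temperature-only niche on a clean latitudinal gradient
        stack = generate_climate(small_grid, 2, seed=3, noise_sd=0.0)
        fut = apply_delta(stack, ScenarioDelta("W/x", {"temp": 3.0}))
        vs = make_virtual_species(stack, [-5.0], np.array([[9.0]]), 0.1, "cold",
                                  niche_variables=["temp"],
                                  future_stacks={"W/x": fut})
        cur_lats = small_grid.lat_centers()[np.any(vs.true_ranges["current"], axis=1)]
        fut_lats = small_grid.lat_centers()[np.any(vs.true_ranges["W/x"], axis=1)]
        assert np.abs(fut_lats).mean() > np.abs(cur_lats).mean()
        # oracle: exhaustive area-weighted count over both truth grids
        areas = small_grid.cell_areas_km2()
        expected = 1 - (areas[vs.true_ranges["W/x"]].sum()
                        / areas[vs.true_ranges["current"]].sum())
        assert true_loss_fraction(vs, "W/x") == pytest.approx(expected)


class TestSamplePresences:
    def _species(self, stack, mu_t=10.0):
        return make_virtual_species(stack, [mu_t, 1000.0], np.diag([16.0, 9e4]),
                                    0.1, "sp", niche_variables=["temp", "precip"])

    def test_exact_record_count(self, stack):
        occ = sample_presences(self._species(stack), 1, seed=0)
        assert occ.n_records("sp") == 1

    def test_degenerate_suitability_sends_all_draws_to_one_cell(self, small_grid):
        stack = generate_climate(small_grid, 2, seed=3, noise_sd=0.0)
        vs = self._species(stack)
        vs.suitability["current"] = np.zeros(small_grid.shape)
        vs.suitability["current"][4, 9] = 1.0
        occ = sample_presences(vs, 20, seed=1)
        lons = {r.lon for r in occ.records["sp"]}
        lats = {r.lat for r in occ.records["sp"]}
        assert len(lons) == 1 and len(lats) == 1

    def test_two_level_surface_draws_in_nine_to_one_ratio(self, small_grid):
        stack = generate_climate(small_grid, 2, seed=3, noise_sd=0.0)
        vs = self._species(stack)
        surf = np.full(small_grid.shape, 0.1)
        surf[:, :30] = 0.9
        vs.suitability["current"] = surf
        occ = sample_presences(vs, 500, seed=2)
        n_high = sum(1 for r in occ.records["sp"] if r.lon < 0)
        # binomial(500, 0.9): 3.5 sigma is about 23 draws
        assert abs(n_high - 450) < 24

    def test_empirical_frequencies_converge_to_suitability(self, small_grid):
        # chi-square goodness of fit at n = 5000 on a coarse cell partition
        stack = generate_climate(small_grid, 2, seed=3, noise_sd=0.0)
        vs = self._species(stack)
        occ = sample_presences(vs, 5000, seed=3)
        s = vs.suitability["current"]
        counts = np.zeros(small_grid.shape)
        for r in occ.records["sp"]:
            counts[small_grid.cell_index(r.lon, r.lat)] += 1
        keep = s.ravel() / s.sum() > 1e-4
        obs = counts.ravel()[keep]
        exp = 5000 * s.ravel()[keep] / s.sum()
        obs = np.append(obs, 5000 - obs.sum())
        exp = np.append(exp, 5000 - exp.sum())
        stat, p = chisquare(obs, exp * (obs.sum() / exp.sum()))
        assert p > 0.01

    def test_zero_suitability_everywhere_rejected(self, stack):
        vs = self._species(stack)
        vs.suitability["current"] = np.zeros(stack.grid.shape)
        with pytest.raises(ValueError):
            sample_presences(vs, 5, seed=0)


class TestTrueLossFraction:
    def _vs(self, small_grid, cur, fut):
        stack = generate_climate(small_grid, 2, seed=0)
        vs = make_virtual_species(stack, [10, 1000], np.diag([16, 9e4]), 0.1,
                                  "sp", niche_variables=["temp", "precip"])
        vs.true_ranges = {"current": cur, "F/x": fut}
        return vs

    def test_identical_truth_ranges_give_zero(self, small_grid):
        flags = np.zeros(small_grid.shape, bool)
        flags[3, 4] = True
        assert true_loss_fraction(self._vs(small_grid, flags, flags.copy()),
                                  "F/x") == 0.0

    def test_empty_future_gives_one(self, small_grid):
        cur = np.zeros(small_grid.shape, bool)
        cur[3, 4] = True
        fut = np.zeros(small_grid.shape, bool)
        assert true_loss_fraction(self._vs(small_grid, cur, fut), "F/x") == 1.0

    def test_loss_is_area_weighted_not_cell_counted(self, small_grid):
        # two-cell range: equator cell + 60N cell; keep only the 60N one.
        res = small_grid.resolution_arcmin
        lats = small_grid.lat_centers()
        r_eq = int(np.argmin(np.abs(lats - 3.0)))    # cell centered at 3N
        r_60 = int(np.argmin(np.abs(lats - 63.0)))   # cell centered at 63N
        cur = np.zeros(small_grid.shape, bool)
        cur[r_eq, 0] = cur[r_60, 0] = True
        fut = np.zeros(small_grid.shape, bool)
        fut[r_60, 0] = True
        a_eq = cell_area_km2(lats[r_eq], res)
        a_60 = cell_area_km2(lats[r_60], res)
        expected = 1 - a_60 / (a_eq + a_60)
        got = true_loss_fraction(self._vs(small_grid, cur, fut), "F/x")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got != pytest.approx(0.5)  # cell counting would say half

    def test_empty_current_rejected(self, small_grid):
        empty = np.zeros(small_grid.shape, bool)
        with pytest.raises(ZeroDivisionError):
            true_loss_fraction(self._vs(small_grid, empty, empty), "F/x")


class TestSynthesizeStudy:
    def test_study_is_deterministic(self, small_grid):
        a = synthesize_study(3, 2, seed=9, grid=small_grid)
        b = synthesize_study(3, 2, seed=9, grid=small_grid)
        assert a.true_loss == b.true_loss
        for sp in a.occurrences.records:
            assert [(r.lon, r.lat) for r in a.occurrences.records[sp]] == \
                   [(r.lon, r.lat) for r in b.occurrences.records[sp]]

    def test_data_poor_species_have_one_to_three_records(self, small_grid):
        study = synthesize_study(2, 3, seed=9, grid=small_grid)
        dp = [sp for sp in study.occurrences.records if sp.startswith("dp")]
        counts = sorted(len(study.occurrences.records[sp]) for sp in dp)
        assert counts == [1, 2, 3]

    def test_truth_covers_every_scenario(self, small_grid):
        study = synthesize_study(2, 0, seed=9, grid=small_grid)
        for sp, losses in study.true_loss.items():
            assert set(losses) == set(study.futures)
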
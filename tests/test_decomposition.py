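"""Shapley driver decomposition: exactness, symmetry, zero-robustness."""

import numpy as np
import pandas as pd
import pytest

from pmforge import (
    FactorPanel,
    accumulate_effects,
    compute_emissions,
    counterfactual_series,
    decompose,
    driver_size_ratio,
    inventory_factor_panel,
    shapley_step,
)
from pmforge.core_inventory import species_series
from pmforge.decomposition import abatement_bookkeeping

from _reference import shapley_by_orderings


def random_factor_snapshots(rng, n_factors, n_cells, zero_prob=0.1):
    names = [f"f{i}" for i in range(n_factors)]

    def snap():
        return {
            n: np.where(rng.random(n_cells) < zero_prob, 0.0, rng.uniform(0.1, 5.0, n_cells))
            for n in names
        }

    return snap(), snap()


class TestShapleyStep:
    def test_no_change_gives_zero_effects(self):
        f = {"a": np.array([1.0, 2.0]), "b": np.array([3.0, 4.0])}
        effects = shapley_step(f, f)
        assert all(v == 0.0 for v in effects.values())

    def test_single_changed_factor_takes_whole_change(self):
        f0 = {"activity": np.array([1.0]), "intensity": np.array([1.0])}
        f1 = {"activity": np.array([2.0]), "intensity": np.array([1.0])}
        effects = shapley_step(f0, f1)
        assert effects["activity"] == pytest.approx(1.0)
        assert effects["intensity"] == 0.0

    def test_two_factor_worked_example_exact(self):
        # E = A * F with A: 1 -> 2 and F: 1 -> 3; averaging the two
        # orderings gives activity effect 2 and intensity effect 3.
        f0 = {"activity": np.array([1.0]), "intensity": np.array([1.0])}
        f1 = {"activity": np.array([2.0]), "intensity": np.array([3.0])}
        effects = shapley_step(f0, f1)
        assert effects["activity"] == 2.0
        assert effects["intensity"] == 3.0
        assert effects["activity"] + effects["intensity"] == 5.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_ordering_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        f0, f1 = random_factor_snapshots(rng, k, int(rng.integers(1, 21)))
        got = shapley_step(f0, f1)
        want = shapley_by_orderings(f0, f1)
        for name in want:
            assert got[name] == pytest.approx(want[name], rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_effects_sum_to_delta_e(self, seed):
        rng = np.random.default_rng(100 + seed)
        k = int(rng.integers(2, 6))
        f0, f1 = random_factor_snapshots(rng, k, int(rng.integers(1, 21)))
        effects = shapley_step(f0, f1)

        def agg(s):
            return float(np.prod(np.vstack(list(s.values())), axis=0).sum())

        delta = agg(f1) - agg(f0)
        assert sum(effects.values()) == pytest.approx(delta, rel=1e-9, abs=1e-12)

    def test_symmetry_under_relabeling(self):
        rng = np.random.default_rng(5)
        f0, f1 = random_factor_snapshots(rng, 3, 4)
        base = shapley_step(f0, f1)
        renamed0 = {f"x_{k}": v for k, v in f0.items()}
        renamed1 = {f"x_{k}": v for k, v in f1.items()}
        renamed = shapley_step(renamed0, renamed1)
        for k in base:
            assert renamed[f"x_{k}"] == pytest.approx(base[k], rel=1e-12, abs=1e-15)

    def test_zero_factor_values_stay_finite(self):
        # a technology phasing in: share 0 -> 0.4
        f0 = {"share": np.array([0.0]), "ef": np.array([2.0])}
        f1 = {"share": np.array([0.4]), "ef": np.array([5.0])}
        effects = shapley_step(f0, f1)
        assert np.isfinite(list(effects.values())).all()
        assert sum(effects.values()) == pytest.approx(0.4 * 5.0 - 0.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        f0, f1 = random_factor_snapshots(rng, 3, 5, zero_prob=0.0)
        base = shapley_step(f0, f1)
        c = 3.7
        s0 = dict(f0, f0_scaled=f0["f0"] * c)
        s0.pop("f0")
        s1 = dict(f1, f0_scaled=f1["f0"] * c)
        s1.pop("f0")
        scaled = shapley_step(s0, s1)
        for k, v in scaled.items():
            ref = base["f0"] if k == "f0_scaled" else base[k]
            assert v == pytest.approx(ref * c, rel=1e-12)

    def test_too_many_factors_rejected(self):
        f = {f"f{i}": np.array([1.0]) for i in range(9)}
        with pytest.raises(ValueError, match="guard"):
            shapley_step(f, f)

    def test_mismatched_factor_names_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            shapley_step({"a": np.array([1.0])}, {"b": np.array([1.0])})


class TestAccumulation:
    def test_running_sum_with_sign_changes(self):
        steps = pd.DataFrame({2001: [1.0], 2002: [1.0], 2003: [-3.0]}, index=["f"])
        cum = accumulate_effects(steps, 2000)
        assert cum.loc["f", 2000] == 0.0
        assert cum.loc["f", 2003] == pytest.approx(-1.0)

    def test_year_gap_rejected(self):
        steps = pd.DataFrame({2001: [1.0], 2003: [1.0]}, index=["f"])
        with pytest.raises(ValueError, match="contiguous"):
            accumulate_effects(steps, 2000)

    def test_cumulative_effects_close_against_inventory(self, default_tables):
        """Sum of cumulative driver effects equals the emission change since baseline."""
        panel = inventory_factor_panel(*default_tables, species="PM2.5", unit="g")
        cum = accumulate_effects(decompose(panel, 1960), 1960)
        em = compute_emissions(*default_tables)
        series = species_series(em, "PM2.5")
        for year in (1961, 1995, 2019):
            delta = series.loc[year] - series.loc[1960]
            assert cum[year].sum() == pytest.approx(delta, rel=1e-9)


class TestCounterfactual:
    @pytest.fixture()
    def small_panel(self):
        idx = pd.MultiIndex.from_tuples([("s", "t")], names=["source", "technology"])
        years = [2000, 2001, 2002]
        return FactorPanel(
            {
                "activity": pd.DataFrame([[1.0, 1.5, 2.0]], index=idx, columns=years),
                "control": pd.DataFrame([[1.0, 0.8, 0.5]], index=idx, columns=years),
            }
        )

    def test_empty_frozen_set_is_identity(self, small_panel):
        cf = counterfactual_series(small_panel, [])
        pd.testing.assert_series_equal(cf, small_panel.emission_series())

    def test_all_frozen_is_flat_baseline(self, small_panel):
        cf = counterfactual_series(small_panel, ["activity", "control"])
        assert (cf == small_panel.emissions(2000)).all()

    def test_frozen_control_hand_arithmetic(self, small_panel):
        # A grows 1 -> 2 while the control term falls 1 -> 0.5: freezing the
        # control leaves 2.0, the actual series ends at 1.0.
        cf = counterfactual_series(small_panel, ["control"])
        assert cf.loc[2002] == pytest.approx(2.0)
        assert small_panel.emissions(2002) == pytest.approx(1.0)

    def test_unknown_factor_rejected(self, small_panel):
        with pytest.raises(ValueError, match="unknown factor"):
            counterfactual_series(small_panel, ["fairy_dust"])

    def test_bookkeeping_difference(self):
        assert abatement_bookkeeping(48.7, 6.8) == pytest.approx(41.9)


class TestDriverSizeRatio:
    def make(self, vals):
        return pd.DataFrame({2000: vals}, index=["a", "b"][: len(vals)])

    def test_plain_division(self):
        ratio, undef = driver_size_ratio(self.make([2.0]), self.make([4.0]))
        assert ratio.loc["a", 2000] == pytest.approx(0.5)
        assert not undef.loc["a", 2000]

    def test_zero_coarse_flagged_undefined(self):
        ratio, undef = driver_size_ratio(self.make([2.0]), self.make([0.0]))
        assert undef.loc["a", 2000]
        assert np.isnan(ratio.loc["a", 2000])

    def test_equal_series_ratio_one(self):
        f = self.make([2.0, 3.0])
        ratio, undef = driver_size_ratio(f, f.copy())
        assert (ratio == 1.0).all().all()
        assert not undef.any().any()


class TestInventoryFactorPanel:
    @pytest.mark.parametrize("species", ["PM2.5", "PM>2.5", "TSP", "BC", "OC"])
    def test_panel_product_reproduces_inventory_series(self, default_tables, species):
        panel = inventory_factor_panel(*default_tables, species=species, unit="g")
        em = compute_emissions(*default_tables)
        if species == "PM>2.5":
            want = species_series(em, "PM2.5-10").add(species_series(em, "PM>10"))
        else:
            want = species_series(em, species)
        got = panel.emission_series()
        np.testing.assert_allclose(got.to_numpy(), want.to_numpy(), rtol=1e-9)

    def test_population_split_preserves_product(self, default_tables):
        from pmforge.synthetic_data import default_config, population_series

        pop = population_series(default_config())
        panel4 = inventory_factor_panel(*default_tables, species="PM2.5", unit="g")
        panel5 = inventory_factor_panel(
            *default_tables, species="PM2.5", unit="g", population=pop
        )
        assert "population" in panel5.factor_names
        assert "activity_per_capita" in panel5.factor_names
        np.testing.assert_allclose(
            panel5.emission_series().to_numpy(),
            panel4.emission_series().to_numpy(),
            rtol=1e-9,
        )
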
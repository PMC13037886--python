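"""Conservation-indicator translation and aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from landgen.forecast import ForecastTable
from landgen.indicators import (
    aggregate,
    gbf_population_loss,
    lpi_decline,
    predict_species,
    redlist_to_area_loss,
    sample_fst,
    sample_z,
)


class TestRedList:
    def test_critically_endangered_mean_of_range(self):
        assert redlist_to_area_loss("CR") == pytest.approx(0.875)

    def test_least_concern_zero(self):
        assert redlist_to_area_loss("LC") == 0.0

    def test_custom_range(self):
        assert redlist_to_area_loss("EN", {"EN": (50, 80)}) == pytest.approx(0.65)

    def test_unknown_category(self):
        with pytest.raises(KeyError):
            redlist_to_area_loss("UNKNOWN")


class TestLpiDecline:
    def test_constant_abundance_is_non_declining(self):
        loss, declining = lpi_decline({"p1": [(1970, 500), (2020, 500)]})
        assert loss == pytest.approx(0.0, abs=0.01)

    def test_hand_computed_two_population_average(self):
        series = {"p1": [(1970, 100), (2020, 30)], "p2": [(1970, 200), (2020, 100)]}
        loss, declining = lpi_decline(series)
        expected = 1 - 0.5 * (30 / 101 + 100 / 201)
        assert loss == pytest.approx(expected)
        assert declining

    def test_zero_baseline_is_finite(self):
        loss, _ = lpi_decline({"p1": [(1970, 0), (2020, 5)]})
        assert np.isfinite(loss)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            lpi_decline({})


class TestGbf:
    @pytest.mark.parametrize("past,present,expected", [(10, 10, 0.0), (10, 0, 1.0), (8, 6, 0.25)])
    def test_fraction_lost(self, past, present, expected):
        assert gbf_population_loss(past, present) == pytest.approx(expected)

    def test_zero_past_rejected(self):
        with pytest.raises(ValueError):
            gbf_population_loss(0, 0)


class TestSampling:
    def test_fst_draws_bounded_and_seeded(self):
        a = sample_fst(500, seed=11)
        b = sample_fst(500, seed=11)
        assert np.array_equal(a, b)
        assert (a >= 0).all() and (a < 1).all()

    def test_fst_mean_matches_truncated_normal(self):
        draws = sample_fst(10_000, seed=5)
        tmean = stats.truncnorm.mean((0 - 0.270) / 0.211, (1 - 0.270) / 0.211,
                                     loc=0.270, scale=0.211)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(tmean, abs=3 * se)

    def test_fst_resampling_from_empirical_table(self):
        vals = [0.1, 0.5]
        draws = sample_fst(200, seed=2, empirical=vals)
        assert set(np.unique(draws)) <= set(vals)

    def test_z_single_value_table_is_constant(self):
        assert np.all(sample_z(50, seed=1, empirical_values=[0.03]) == 0.03)

    def test_z_resample_mean_matches_table(self):
        vals = np.array([0.0, 0.01, 0.03, 0.1, 0.45])
        draws = sample_z(20_000, seed=3, empirical_values=vals)
        se = vals.std() / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(vals.mean(), abs=4 * se)

    def test_z_fallback_mean_and_support(self):
        draws = sample_z(20_000, seed=4)
        assert draws.mean() == pytest.approx(0.03, abs=0.005)
        assert draws.min() >= 0 and draws.max() <= 0.45

    def test_negative_z_table_rejected(self):
        with pytest.raises(ValueError):
            sample_z(5, seed=0, empirical_values=[-0.1])


def toy_table() -> ForecastTable:
    rows = []
    for fst in (0.1, 0.5):
        for loss in (0.0, 0.3, 0.6, 0.9):
            for hor in ("short", "mid"):
                for scen in ("contraction", "fragmentation"):
                    base = loss * (0.1 if hor == "short" else 0.3)
                    rows.append(
                        {"fst": fst, "loss": loss, "horizon": hor, "scenario": scen,
                         "mean_loss_species": base, "iqr_lo": base, "iqr_hi": base,
                         "mean_loss_local": 2 * base, "reps": 1, "seed": 0}
                    )
    return ForecastTable(pd.DataFrame(rows))


class TestPredictSpecies:
    def records(self, **over):
        rec = {"species": "sp1", "source": "redlist", "area_loss": 0.8,
               "fst": 0.1, "z": 0.02809}
        rec.update(over)
        return pd.DataFrame([rec])

    def test_short_contraction_uses_gdar_worked_example(self):
        preds = predict_species(self.records(), toy_table())
        hit = preds[(preds.horizon == "short") & (preds.scenario == "contraction")]
        assert round(100 * float(hit.predicted_loss.iloc[0]), 1) == 4.4
        assert hit.method.iloc[0] == "gdar"

    def test_zero_loss_species_predicts_zero_everywhere(self):
        preds = predict_species(self.records(area_loss=0.0), toy_table())
        assert np.allclose(preds.predicted_loss, 0.0)

    def test_fragmentation_reports_local_loss(self):
        preds = predict_species(self.records(), toy_table())
        frag = preds[(preds.horizon == "mid") & (preds.scenario == "fragmentation")]
        # toy table encodes local loss = 2 x species loss
        assert float(frag.predicted_loss.iloc[0]) == pytest.approx(
            2 * float(frag.loss_species.iloc[0])
        )

    def test_assumption_recorded(self):
        preds = predict_species(self.records(), toy_table())
        assert (preds.assumption == "population loss = habitat area loss").all()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            predict_species(pd.DataFrame([{"species": "x"}]), toy_table())


class TestAggregate:
    def make_preds(self, values, source="lpi"):
        return pd.DataFrame(
            {"species": [f"s{i}" for i in range(len(values))],
             "source": source, "horizon": "short", "scenario": "contraction",
             "predicted_loss": values}
        )

    def test_identical_predictions_have_zero_iqr(self):
        out = aggregate(self.make_preds([0.2] * 6))
        assert float(out.iqr_hi.iloc[0] - out.iqr_lo.iloc[0]) == 0.0

    def test_hand_computed_quartiles(self):
        vals = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
        out = aggregate(self.make_preds(vals))
        assert float(out.mean_loss.iloc[0]) == pytest.approx(np.mean(vals))
        assert float(out.iqr_lo.iloc[0]) == pytest.approx(np.quantile(vals, 0.25))
        assert float(out.iqr_hi.iloc[0]) == pytest.approx(np.quantile(vals, 0.75))

    def test_mean_invariant_to_order(self, rng):
        vals = rng.uniform(0, 1, 11)
        a = aggregate(self.make_preds(list(vals)))
        b = aggregate(self.make_preds(list(vals[::-1])))
        assert float(a.mean_loss.iloc[0]) == pytest.approx(float(b.mean_loss.iloc[0]))


class TestPipelineProperties:
    def test_determinism_under_fixed_seeds(self):
        from landgen.synth import make_redlist_table

        df, _ = make_redlist_table({"CR": 5, "EN": 5, "VU": 5, "LC": 5}, seed=1)
        runs = []
        for _ in range(2):
            rec = pd.DataFrame(
                {"species": df.species, "source": "redlist",
                 "area_loss": [redlist_to_area_loss(c) for c in df.category]}
            )
            rec["fst"] = sample_fst(len(rec), seed=3)
            rec["z"] = sample_z(len(rec), seed=4)
            runs.append(aggregate(predict_species(rec, toy_table())))
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_worse_categories_increase_global_mean(self):
        def mean_for(counts):
            from landgen.synth import make_redlist_table

            df, _ = make_redlist_table(counts, seed=1)
            rec = pd.DataFrame(
                {"species": df.species, "source": "redlist",
                 "area_loss": [redlist_to_area_loss(c) for c in df.category]}
            )
            rec["fst"] = sample_fst(len(rec), seed=3)
            rec["z"] = sample_z(len(rec), seed=4)
            out = aggregate(predict_species(rec, toy_table()))
            return float(out.mean_loss.mean())

        mild = mean_for({"LC": 15, "VU": 5})
        severe = mean_for({"VU": 5, "CR": 15})
        assert severe > mild

    def test_out_of_range_loss_raises_without_clamping(self):
        rec = pd.DataFrame(
            [{"species": "a", "source": "lpi", "area_loss": 0.99, "fst": 0.1, "z": 0.01}]
        )
        with pytest.raises(KeyError):
            predict_species(rec, toy_table())

    def test_clamping_maps_extreme_losses_to_edge_bin(self):
        rec = pd.DataFrame(
            [{"species": "a", "source": "lpi", "area_loss": 0.99, "fst": 0.1, "z": 0.01}]
        )
        preds = predict_species(rec, toy_table(), clamp=True)
        mid = preds[(preds.horizon == "mid") & (preds.scenario == "contraction")]
        assert float(mid.predicted_loss.iloc[0]) == pytest.approx(0.27)  # 0.9 bin
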
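import numpy as np
import pandas as pd
import pytest

import plastevol as pe
from plastevol.exceptions import ConfoundedSamplesError, NotComputableError
from plastevol.mixedmodel import InsufficientData
from plastevol.simulate import TraitParams


def cg_dataset(seed=0, mean_count=10.0, species=("PA",), **bio_kwargs):
    sel = pe.enumerate_selection_design()
    cg = pe.enumerate_common_garden_design(sel)
    tp = {
        "bio_area": TraitParams(intercept=2500.0, **bio_kwargs),
        "aspect_ratio": TraitParams(intercept=1.8, sigma_residual=0.1),
        "gross_speed": TraitParams(intercept=500.0, sigma_residual=50.0),
    }
    params = pe.SimulationParams(
        traits={sp: tp for sp in ("PA", "ST", "TT")},
        extinction_rules=(
            pe.ExtinctionRule("TT", requires_competition=True),
            pe.ExtinctionRule("ST", requires_competition=True, salinities=(2.0, 4.0)),
        ),
        mean_count=mean_count,
    )
    rec = pe.simulate_experiment(params, sel, cg, seed=seed)
    return pe.prepare_analysis_table(rec)


@pytest.fixture(scope="module")
def cg_slope_table():
    return cg_dataset(seed=21, plastic_slope=-50.0, sigma_residual=40.0,
                      sigma_microcosm=10.0, sigma_cg_microcosm=10.0)


class TestCommonGardenModel:
    def test_cg_salinity_slope_recovered(self, cg_slope_table):
        fit = pe.fit_commongarden_model(cg_slope_table, "PA", "bio_area")
        est = fit.coefficients["cg_salinity"]
        se = fit.standard_errors["cg_salinity"]
        assert abs(est - (-50.0)) < 3 * se
        for term in ("historical_salinity", "competition",
                     "historical_salinity:cg_salinity"):
            assert abs(fit.coefficients[term]) < 3.5 * fit.standard_errors[term]

    def test_competition_by_cg_interaction_recovered(self):
        # competition-history populations respond more steeply to salinity:
        # emulate with an extra evolved slope plus a competition shift
        table = cg_dataset(seed=22, plastic_slope=-30.0, competition_shift=100.0,
                           sigma_residual=40.0)
        fit = pe.fit_commongarden_model(table, "PA", "bio_area")
        term = "competition"
        assert abs(fit.coefficients[term] - 100.0) < 3 * fit.standard_errors[term]

    def test_single_historical_salinity_rejected(self, cg_slope_table):
        sub = cg_slope_table[cg_slope_table["historical_salinity"] == 0.0]
        with pytest.raises(NotComputableError, match="historical"):
            pe.fit_commongarden_model(sub, "PA", "bio_area")

    def test_r2_ordering(self, cg_slope_table):
        fit = pe.fit_commongarden_model(cg_slope_table, "PA", "bio_area")
        r2 = pe.compute_r2(fit)
        assert 0.0 <= r2.r2_marginal <= r2.r2_conditional <= 1.0


class TestSelectedPlasticity:
    def test_noise_free_slope(self):
        table = cg_dataset(seed=23, plastic_slope=4.0)
        res = pe.fit_selected_plasticity(table, "PA", "bio_area", 0.0, False,
                                         (0.5, 1.0))
        assert res.slope == pytest.approx(4.0, abs=1e-6)

    def test_flat_reaction_norm(self):
        table = cg_dataset(seed=24, sigma_residual=30.0, mean_count=25.0)
        res = pe.fit_selected_plasticity(table, "PA", "bio_area", 0.0, False,
                                         (0.5, 1.0))
        assert abs(res.slope) < 3 * res.se
        assert res.p > 0.05

    def test_slope_recovery_with_noise(self):
        table = cg_dataset(seed=25, plastic_slope=2.0, sigma_residual=1.0,
                           mean_count=100.0)
        res = pe.fit_selected_plasticity(table, "PA", "bio_area", 1.0, False,
                                         (0.5, 1.0))
        assert abs(res.slope - 2.0) < 3 * res.se

    def test_missing_environment_signalled(self):
        table = cg_dataset(seed=26, sigma_residual=10.0)
        # non-zero-salinity lines were never inoculated at 0 g/l
        res = pe.fit_selected_plasticity(table, "PA", "bio_area", 2.0, False,
                                         (0.0, 1.0))
        assert isinstance(res, InsufficientData)

    def test_identical_environments_rejected(self):
        table = cg_dataset(seed=26, sigma_residual=10.0)
        with pytest.raises(ValueError):
            pe.fit_selected_plasticity(table, "PA", "bio_area", 0.0, False,
                                       (1.0, 1.0))


class TestGeneticContrast:
    def test_history_shift_recovered_where_competitors_extinct(self):
        table = cg_dataset(seed=27, competition_shift=-300.0,
                           sigma_residual=50.0, sigma_microcosm=10.0)
        res = pe.fit_genetic_contrast(table, "PA", "bio_area", 4.0, 2.0)
        assert not res.confounded
        assert abs(res.effect - (-300.0)) < 3 * res.se

    def test_null_contrast(self):
        table = cg_dataset(seed=28, sigma_residual=50.0)
        res = pe.fit_genetic_contrast(table, "PA", "bio_area", 4.0, 2.0)
        assert abs(res.effect) < 3.5 * res.se

    def test_refusal_when_competitors_present(self):
        table = cg_dataset(seed=29, sigma_residual=50.0)
        # at low historical salinity ST survived alongside PA
        with pytest.raises(ConfoundedSamplesError):
            pe.fit_genetic_contrast(table, "PA", "bio_area", 0.5, 1.0)

    def test_override_acknowledges_confounding(self):
        table = cg_dataset(seed=29, sigma_residual=50.0)
        res = pe.fit_genetic_contrast(table, "PA", "bio_area", 0.5, 1.0,
                                      allow_confounded=True)
        assert res.confounded

    def test_exclude_units_removes_contamination(self):
        table = cg_dataset(seed=30, sigma_residual=50.0)
        # inject a single stray competitor record into one compared tube,
        # mirroring a contaminated-microcosm judgement call
        tube = table[(table["phase"] == "common_garden_day82")
                     & (table["historical_salinity"] == 4.0)
                     & (table["cg_salinity"] == 2.0)]["cg_id"].iloc[0]
        stray = table[table["species"] == "PA"].iloc[[0]].copy()
        stray["species"] = "ST"
        stray["cg_id"] = tube
        stray["phase"] = "common_garden_day82"
        stray["historical_salinity"] = 4.0
        stray["cg_salinity"] = 2.0
        contaminated = pd.concat([table, stray], ignore_index=True)
        with pytest.raises(ConfoundedSamplesError) as err:
            pe.fit_genetic_contrast(contaminated, "PA", "bio_area", 4.0, 2.0)
        assert tube in err.value.contaminated_samples
        res = pe.fit_genetic_contrast(contaminated, "PA", "bio_area", 4.0, 2.0,
                                      exclude_units=[tube])
        assert not res.confounded

    def test_balanced_noise_free_equals_group_mean_difference(self):
        """On balanced noise-free data the contrast is exactly the difference
        of group means (density constant, so no adjustment)."""
        rows = []
        for comp in (0, 1):
            for rep in (1, 2, 3):
                for i in range(5):
                    rows.append(dict(
                        species="PA", phase="common_garden_day82",
                        historical_salinity=4.0, cg_salinity=2.0,
                        competition=comp, replicate=rep,
                        microcosm_id=f"m{comp}{rep}", cg_id=f"c{comp}{rep}",
                        density=90.0 + 10.0 * rep,  # balanced across histories
                        bio_area=2000.0 + 111.0 * comp,
                    ))
        table = pd.DataFrame(rows)
        res = pe.fit_genetic_contrast(table, "PA", "bio_area", 4.0, 2.0)
        assert res.effect == pytest.approx(111.0, abs=1e-8)
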
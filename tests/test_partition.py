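import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plastevol as pe
from plastevol.exceptions import NotComputableError
from plastevol.partition import PartitionInput, partition_oracle


def make_cells(anc_ref, anc_test, sel_ref, sel_test, n=10, n_units=2,
               noise=0.0, density=0.0, seed=0):
    """Four-cell partition input with constant (or noisy) trait values."""
    rng = np.random.default_rng(seed)
    frames = []
    for mean, pop, env, tag in [
        (anc_ref, "anc", "ref", "ar"), (anc_test, "anc", "test", "at"),
        (sel_ref, "sel", "ref", "sr"), (sel_test, "sel", "test", "st"),
    ]:
        units = [f"{tag}{u}" for u in range(n_units) for _ in range(n)]
        vals = mean + (rng.normal(0, noise, n * n_units) if noise > 0 else 0.0)
        frames.append(pd.DataFrame(dict(
            bio_area=vals, unit_id=units, density=density,
            competition=False, species="PA",
        )))
    return PartitionInput(
        ancestral_ref=frames[0], ancestral_test=frames[1],
        selected_ref=frames[2], selected_test=frames[3],
        env_ref=0.5, env_test=1.0,
    )


class TestOracle:
    @pytest.mark.parametrize(
        "cells,expected",
        [((10, 12, 15, 20), (2, 5, 3)),
         ((7, 7, 7, 7), (0, 0, 0)),
         ((0, 1, 0, 2), (1, 0, 1))],
    )
    def test_hand_arithmetic(self, cells, expected):
        assert partition_oracle(*cells) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(st.tuples(*[st.floats(-1e4, 1e4) for _ in range(4)]))
    def test_conservation_identity(self, cells):
        """sel@test - anc@ref == plasticity + MTE + EoP, exactly."""
        p, m, e = partition_oracle(*cells)
        assert (p + m + e) == pytest.approx(cells[3] - cells[0], abs=1e-8)


class TestBuildTable:
    def test_coding(self):
        inp = make_cells(10, 12, 15, 20, n=10, n_units=1)
        table = pe.build_partition_table(inp)
        assert len(table) == 40
        sel_test = table[(table["population"] == 1) & (table["environment"] == 1)]
        assert len(sel_test) == 10
        assert (sel_test["bio_area"] == 20).all()
        anc_ref = table[(table["population"] == 0) & (table["environment"] == 0)]
        assert (anc_ref["bio_area"] == 10).all()

    def test_empty_cell_rejected(self):
        with pytest.raises(NotComputableError, match="selected_test"):
            inp = make_cells(10, 12, 15, 20)
            PartitionInput(
                ancestral_ref=inp.ancestral_ref,
                ancestral_test=inp.ancestral_test,
                selected_ref=inp.selected_ref,
                selected_test=inp.selected_test.iloc[:0],
                env_ref=0.5, env_test=1.0,
            )

    def test_ancestral_competition_rejected(self):
        inp = make_cells(10, 12, 15, 20)
        bad = inp.ancestral_ref.assign(competition=True)
        with pytest.raises(ValueError, match="competition-free"):
            PartitionInput(bad, inp.ancestral_test, inp.selected_ref,
                           inp.selected_test, 0.5, 1.0)


class TestPartitionFit:
    def test_noise_free_equals_oracle(self):
        inp = make_cells(10.0, 12.0, 15.0, 20.0)
        res = pe.partition_trait_change(inp, "bio_area", include_density=False)
        assert res.plasticity.estimate == pytest.approx(2.0, abs=1e-6)
        assert res.mean_trait_evolution.estimate == pytest.approx(5.0, abs=1e-6)
        assert res.evolution_of_plasticity.estimate == pytest.approx(3.0, abs=1e-6)

    def test_equal_cells_give_zero(self):
        inp = make_cells(9.0, 9.0, 9.0, 9.0)
        res = pe.partition_trait_change(inp, "bio_area", include_density=False)
        for comp in res.components().values():
            assert comp.estimate == pytest.approx(0.0, abs=1e-8)

    def test_reference_swap_negates_evolution_components(self):
        inp = make_cells(10.0, 13.0, 14.0, 21.0, noise=0.8, seed=3)
        a = pe.partition_trait_change(inp, "bio_area", include_density=False)
        b = pe.partition_trait_change(inp, "bio_area", include_density=False,
                                      reference_population="selected")
        # exact reparameterization: with P' = 1 - P the coefficients become
        # MTE' = -MTE, EoP' = -EoP, and the environment coefficient now
        # describes the *selected* population's response (plasticity + EoP)
        assert b.mean_trait_evolution.estimate == pytest.approx(
            -a.mean_trait_evolution.estimate, abs=1e-6)
        assert b.evolution_of_plasticity.estimate == pytest.approx(
            -a.evolution_of_plasticity.estimate, abs=1e-6)
        assert b.plasticity.estimate == pytest.approx(
            a.plasticity.estimate + a.evolution_of_plasticity.estimate, abs=1e-6)

    def test_recovery_with_noise_and_random_effects(self):
        rng = np.random.default_rng(42)
        within = 0
        for rep in range(20):
            inp = make_cells(2000.0, 2030.0, 2100.0, 2180.0, n=10, n_units=3,
                             noise=40.0, seed=rep)
            res = pe.partition_trait_change(inp, "bio_area", include_density=False)
            truth = partition_oracle(2000.0, 2030.0, 2100.0, 2180.0)
            ok = all(
                abs(c.estimate - t) < 3 * c.se
                for c, t in zip(
                    (res.plasticity, res.mean_trait_evolution,
                     res.evolution_of_plasticity), truth)
            )
            within += ok
        assert within >= 18


class TestPartitionAll:
    def test_cg4_refused(self, analysis_table):
        with pytest.raises(NotComputableError, match="4 g/l"):
            pe.partition_all(analysis_table, "PA", "bio_area", 4.0, False)

    def test_no_competition_populations_not_confounded(self, analysis_table):
        batch = pe.partition_all(analysis_table, "PA", "bio_area", 1.0, False)
        assert len(batch.results) == 5  # one per historical salinity
        assert all(not r.confounded for r in batch.results)

    def test_competition_history_confounding_flags(self, analysis_table):
        batch = pe.partition_all(analysis_table, "PA", "bio_area", 2.0, True)
        flags = {r.historical_salinity: r.confounded for r in batch.results}
        # ST (and TT) extinct under competition at 2 and 4 g/l: genuinely genetic
        assert flags[2.0] is False and flags[4.0] is False
        # at low salinity ST persisted alongside PA: confounded
        assert flags[0.0] is True and flags[0.5] is True and flags[1.0] is True

    def test_st_extinct_populations_skipped(self, analysis_table):
        batch = pe.partition_all(analysis_table, "ST", "bio_area", 1.0, True)
        skipped_hists = {h for h, _ in batch.skipped}
        assert {2.0, 4.0} <= skipped_hists
        assert all(r.historical_salinity in (0.0, 0.5, 1.0) for r in batch.results)

    def test_ground_truth_recovery_from_experiment(self, small_experiment,
                                                   analysis_table):
        params, _ = small_experiment
        batch = pe.partition_all(analysis_table, "PA", "bio_area", 1.0, False)
        for res in batch.results:
            gt = pe.ground_truth_components(
                params, "PA", "bio_area", res.historical_salinity, (0.5, 1.0))
            for comp, truth in (
                (res.plasticity, gt.plasticity),
                (res.mean_trait_evolution, gt.mean_trait_evolution),
                (res.evolution_of_plasticity, gt.evolution_of_plasticity),
            ):
                assert abs(comp.estimate - truth) < 4 * comp.se

    def test_results_frame_shape(self, analysis_table):
        batch = pe.partition_all(analysis_table, "PA", "bio_area", 1.0, False)
        frame = pe.partition_results_frame(batch)
        assert len(frame) == 3 * len(batch.results)
        assert set(frame["component"]) == {
            "plasticity", "mean_trait_evolution", "evolution_of_plasticity"}
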
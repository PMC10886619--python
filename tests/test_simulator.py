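"""Synthetic assay generator: dilution noise model, Poisson spotting,
anomaly injection, throughput arithmetic, rate recovery."""

import numpy as np
import pytest

from phagedrop import (
    SimulationConfig,
    SpotStatus,
    TitrationStatus,
    apply_coalescence,
    estimate_anomaly_rates,
    plan_run,
    resolve_anomalies,
    simulate_assay,
    simulate_dilution_series,
    simulate_spot,
    study_panel_config,
    titrate,
)
from conftest import make_spot


def quiet_config(**overrides):
    base = dict(susceptibility={("P1", "S1"): 1e9}, pipetting_cv=0.0,
                drop_volume_cv=0.0, p_no_drop=0.0, p_coalescence=0.0, seed=0)
    base.update(overrides)
    return SimulationConfig(**base)


class TestDilutionSeries:
    def test_noise_free_series_is_exact_decades(self):
        rng = np.random.default_rng(0)
        series = simulate_dilution_series(1e9, 0.0, 8, rng)
        assert series == pytest.approx([1e9 / 10 ** k for k in range(8)])
        assert series[6] == pytest.approx(1e3)  # 5 expected PFU per 5 uL drop

    def test_pipetting_error_has_median_one(self):
        """The multiplicative transfer error is lognormal with median 1:
        over many series the median realized c1/(stock/10) is 1."""
        rng = np.random.default_rng(1)
        ratios = [simulate_dilution_series(1e9, 0.05, 2, rng)[1] / 1e8
                  for _ in range(10_000)]
        assert np.median(ratios) == pytest.approx(1.0, abs=0.01)

    def test_invalid_stock_rejected(self):
        with pytest.raises(ValueError):
            simulate_dilution_series(0.0, 0.05, 8, np.random.default_rng(0))


class TestSimulateSpot:
    def test_zero_concentration_never_lyses(self):
        config = quiet_config()
        rng = np.random.default_rng(2)
        spots = [simulate_spot(0.0, 5.0, config, rng) for _ in range(50)]
        assert {s.status for s in spots} == {SpotStatus.NO_LYSIS}

    def test_overwhelming_concentration_is_confluent(self):
        config = quiet_config()
        rng = np.random.default_rng(3)
        spot = simulate_spot(2e6 * 1e4, 5.0, config, rng)  # ~1e4 expected PFU
        assert spot.status is SpotStatus.CONFLUENT

    def test_counts_are_poisson(self):
        """At expected count 20 the sample mean matches lambda and the
        variance matches the mean (Poisson dispersion)."""
        config = quiet_config(max_countable=10_000)
        rng = np.random.default_rng(4)
        conc = 20 / (5.0 * 1e-3)
        counts = np.array([
            simulate_spot(conc, 5.0, config, rng).plaque_count or 0.0
            for _ in range(100_000)])
        assert counts.mean() == pytest.approx(20.0, rel=0.005)
        assert counts.var() == pytest.approx(counts.mean(), rel=0.03)

    def test_no_drop_probability_respected(self):
        config = quiet_config(p_no_drop=1.0)
        spot = simulate_spot(1e5, 5.0, config, np.random.default_rng(5))
        assert spot.status is SpotStatus.NO_DROP


class TestApplyCoalescence:
    def triplet(self, counts):
        return [make_spot(float(c), SpotStatus.COUNTED, 2, i + 1)
                for i, c in enumerate(counts)]

    def test_zero_probability_is_identity(self):
        spots = self.triplet([10, 12, 7])
        assert apply_coalescence(spots, 0.0, np.random.default_rng(0)) == spots

    def test_certain_merge_takes_first_pair_only(self):
        out = apply_coalescence(self.triplet([10, 12, 7]), 1.0,
                                np.random.default_rng(0))
        assert out[0].status is SpotStatus.MERGED and out[1].status is SpotStatus.MERGED
        assert out[0].plaque_count == out[1].plaque_count == 22.0
        assert (out[0].merge_partner, out[1].merge_partner) == (2, 1)
        assert out[2].status is SpotStatus.COUNTED and out[2].plaque_count == 7.0

    def test_merge_conserves_total_count(self):
        out = apply_coalescence(self.triplet([9, 14, 7]), 1.0,
                                np.random.default_rng(1))
        resolved = resolve_anomalies(out)
        assert sum(resolved.counts.values()) == pytest.approx(30.0)


class TestSimulateAssay:
    def test_study_scale_table_shape(self):
        spots, _ = simulate_assay(study_panel_config(seed=0))
        assert len(spots) == 126 * 11 * 8 * 3

    def test_same_seed_reproduces_identical_table(self):
        config = study_panel_config(seed=5, n_strains=4, n_phages=2,
                                    n_positive_interactions=5)
        a, _ = simulate_assay(config)
        b, _ = simulate_assay(config)
        assert a == b

    def test_different_seed_same_shape_different_anomalies(self):
        kwargs = dict(n_strains=12, n_phages=3, n_positive_interactions=12)
        a, _ = simulate_assay(study_panel_config(seed=1, **kwargs))
        b, _ = simulate_assay(study_panel_config(seed=2, **kwargs))
        assert len(a) == len(b)
        key = lambda spots: [(s.phage_id, s.strain_id, s.dilution_exponent,
                              s.replicate_index) for s in spots]
        assert key(a) == key(b)
        assert a != b

    def test_empty_susceptibility_gives_sterile_plates(self):
        config = SimulationConfig(susceptibility={}, phage_ids=("P1",),
                                  strain_ids=("S1", "S2"), seed=3)
        spots, _ = simulate_assay(config)
        allowed = {SpotStatus.NO_LYSIS, SpotStatus.NO_DROP, SpotStatus.MERGED}
        assert {s.status for s in spots} <= allowed
        merged = [s for s in spots if s.status is SpotStatus.MERGED]
        assert all(s.plaque_count == 0.0 for s in merged)

    def test_coalescence_never_crosses_phage_or_dilution(self):
        spots, _ = simulate_assay(study_panel_config(seed=11, p_coalescence=0.5))
        by_key = {(s.phage_id, s.strain_id, s.dilution_exponent,
                   s.replicate_index): s for s in spots}
        for s in spots:
            if s.status is SpotStatus.MERGED:
                partner = by_key[(s.phage_id, s.strain_id, s.dilution_exponent,
                                  s.merge_partner)]
                assert partner.status is SpotStatus.MERGED
                assert partner.merge_partner == s.replicate_index
                assert abs(s.replicate_index - s.merge_partner) == 1

    def test_truth_concentrations_cover_every_pair(self):
        config = study_panel_config(seed=7, n_strains=6, n_phages=2,
                                    n_positive_interactions=6)
        spots, truth = simulate_assay(config)
        assert set(truth.concentrations) == {(p, s) for p in config.phage_ids
                                             for s in config.strain_ids}
        n_no_drop = sum(1 for s in spots if s.status is SpotStatus.NO_DROP)
        assert n_no_drop == sum(1 for e in truth.events if e["kind"] == "no_drop")

    def test_noise_free_closed_loop_recovers_titer(self):
        """With pipetting, volume, and anomaly noise off, the titration of a
        simulated series returns the true stock titer within Poisson
        counting error at the selected dilution."""
        truth_titer = 3e8
        ratios = []
        for seed in range(40):
            spots, _ = simulate_assay(quiet_config(
                susceptibility={("P1", "S1"): truth_titer}, seed=seed))
            result = titrate(spots)
            assert result.status is TitrationStatus.QUANTIFIED
            ratios.append(result.mean_titer / truth_titer)
        # expected ~15 PFU/spot at the countable dilution: sd ~ 15% per assay
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.08)
        assert all(0.4 < r < 1.9 for r in ratios)


class TestPlanRun:
    def test_published_run_geometry(self):
        plan = plan_run(10, 4)
        assert plan.spots_per_plate == 96
        assert plan.spots_per_run == 960
        assert plan.aspiration_volume_per_tip_ul == pytest.approx(160.0)

    def test_study_scale_campaign(self):
        plan = plan_run(126, 11)
        assert plan.total_spots == 33_264
        assert plan.total_plates == 378
        assert plan.plates_per_strain == 3
        assert plan.total_runs == 38

    def test_single_pair_minimal_plan(self):
        plan = plan_run(1, 1)
        assert plan.spots_per_plate == 24
        assert plan.total_plates == 1
        assert plan.total_runs == 1

    def test_zero_inputs_rejected(self):
        with pytest.raises(ValueError):
            plan_run(0, 4)


class TestEstimateAnomalyRates:
    def test_clean_table_has_zero_rates(self):
        spots, _ = simulate_assay(quiet_config())
        est = estimate_anomaly_rates(spots)
        assert est.no_drop_rate == 0.0
        assert est.coalescence_rate == 0.0

    def test_hand_built_counting(self):
        spots = []
        for i in range(100):
            status = SpotStatus.NO_DROP if i < 2 else SpotStatus.NO_LYSIS
            spots.append(make_spot(None, status, exponent=i % 8,
                                   rep=i % 3 + 1, phage=f"P{i // 24}"))
        est = estimate_anomaly_rates(spots)
        assert est.no_drop_rate == pytest.approx(0.02)
        assert est.no_drop_ci[0] < 0.02 < est.no_drop_ci[1]

    def test_default_rates_recovered_from_study_scale_table(self):
        spots, _ = simulate_assay(study_panel_config(seed=13))
        est = estimate_anomaly_rates(spots)
        assert est.no_drop_ci[0] <= 0.0093 <= est.no_drop_ci[1]
        assert est.coalescence_ci[0] <= 0.0197 <= est.coalescence_ci[1]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            estimate_anomaly_rates([])
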
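"""Mixture calibration, cohort sampling, phantoms, end-to-end recovery."""

import math

import numpy as np
import pytest

from paencase import (
    EncasementDiagnosticModel,
    RelationType,
    SyntheticConfig,
    calibrate_degree_mixture,
    cohens_kappa,
    degree_of_encasement,
    make_vessel_phantom,
    measure_phantom,
    sample_cohort,
    sample_degrees,
    simulate_second_observer,
    validate_record,
)
from paencase.model import _kappa_label
from paencase.scoring import EncasementType, classify_encasement_type
from paencase.synth import CalibrationError, PhantomVessel


def mixture_population_moments(spec, n=200_000, seed=5):
    d = sample_degrees(spec, n, seed)
    return d.mean(), d.std(ddof=1)


class TestMixtureCalibration:
    def test_zero_variance_target_is_infeasible_for_continuous_family(self):
        with pytest.raises(CalibrationError):
            calibrate_degree_mixture(50.0, 0.0, 0.0)

    @pytest.mark.parametrize("mean, sd, w, m_c, s_c", [
        (71.8, 18.8, 11 / 58, 65.2, 14.4),  # malignant group targets
        (52.1, 27.3, 1 / 8, 45.3, 21.8),  # benign group targets
    ])
    def test_component_moments_by_hand_algebra(self, mean, sd, w, m_c, s_c):
        spec = calibrate_degree_mixture(mean, sd, w)
        assert spec.m_c == pytest.approx(m_c, abs=0.05)
        assert spec.s_c == pytest.approx(s_c, abs=0.05)
        # mixture identities hold exactly
        mix_mean = (1 - w) * spec.m_c + 100 * w
        mix_second = (1 - w) * (spec.s_c**2 + spec.m_c**2) + 1e4 * w
        assert mix_mean == pytest.approx(mean, abs=1e-9)
        assert mix_second == pytest.approx(sd**2 + mean**2, abs=1e-6)

    @pytest.mark.parametrize("family", ["beta", "truncnorm"])
    def test_monte_carlo_moments_recover_targets(self, family):
        spec = calibrate_degree_mixture(71.8, 18.8, 11 / 58, family=family)
        mean, sd = mixture_population_moments(spec)
        n = 200_000
        assert mean == pytest.approx(71.8, abs=3 * 18.8 / math.sqrt(n))
        assert sd == pytest.approx(18.8, abs=0.5)

    def test_infeasible_moments_report_bounds(self):
        with pytest.raises(CalibrationError, match="mu"):
            calibrate_degree_mixture(50.0, 51.0, 0.0)


class TestSampleDegrees:
    def test_pure_amputation_mass(self):
        spec = calibrate_degree_mixture(71.8, 18.8, 11 / 58)
        spec = spec.__class__(**{**spec.__dict__, "w": 1.0 - 1e-12})
        assert np.all(sample_degrees(spec, 50, 3) == 100.0)

    def test_same_seed_reproduces_exactly(self):
        spec = calibrate_degree_mixture(52.1, 27.3, 1 / 8)
        a = sample_degrees(spec, 1000, 42)
        b = sample_degrees(spec, 1000, 42)
        assert np.array_equal(a, b)

    def test_amputation_fraction_near_w(self):
        spec = calibrate_degree_mixture(71.8, 18.8, 11 / 58)
        d = sample_degrees(spec, 50_000, 9)
        frac = np.mean(d == 100.0)
        se = math.sqrt(spec.w * (1 - spec.w) / 50_000)
        assert frac == pytest.approx(spec.w, abs=3 * se)


class TestSampleCohort:
    def test_records_all_validate(self):
        cohort = sample_cohort(SyntheticConfig(seed=11))
        assert len(cohort) == 100
        for rec in cohort.records:
            assert validate_record(rec) == []

    def test_deterministic_under_fixed_seed(self):
        a = sample_cohort(SyntheticConfig(seed=5))
        b = sample_cohort(SyntheticConfig(seed=5))
        assert a.records == b.records

    def test_all_malignant_cohort(self):
        cohort = sample_cohort(SyntheticConfig(seed=1, n_benign=0))
        assert all(r.truth == "malignant" for r in cohort.records)

    def test_dual_probability_zero_means_single_relations(self):
        cfg = SyntheticConfig(seed=2, dual_probability=0.0, n_malignant=150)
        cohort = sample_cohort(cfg)
        assert all(len(r.final_relations) == 1 for r in cohort.records)

    def test_primary_relation_proportions_match_published_frequencies(self):
        n = 4000
        cfg = SyntheticConfig(seed=13, n_benign=n, n_malignant=n,
                              dual_probability=0.0)
        cohort = sample_cohort(cfg)
        for group, probs in (("benign", cfg.benign_relation_probs),
                             ("malignant", cfg.malignant_relation_probs)):
            recs = cohort.subset(group)
            order = (RelationType.ENCASEMENT, RelationType.DISPLACEMENT,
                     RelationType.PENETRATION, RelationType.IN_MARGIN,
                     RelationType.DISCONNECTION)
            for rel, p in zip(order, probs):
                observed = sum(rel in r.final_relations for r in recs) / n
                se = math.sqrt(max(p * (1 - p), 1e-9) / n)
                assert observed == pytest.approx(p, abs=max(3 * se, 1e-9))

    def test_config_json_round_trip(self):
        cfg = SyntheticConfig(seed=8, n_benign=10, observer_agreement=0.5)
        assert SyntheticConfig.from_json(cfg.to_json()) == cfg


class TestSecondObserver:
    def test_full_agreement_gives_kappa_one(self):
        cohort = sample_cohort(SyntheticConfig(seed=4, observer_agreement=1.0))
        obs2 = simulate_second_observer(cohort, 1.0, 0)
        assert obs2 == [r.obs1_relations for r in cohort.records]

    def test_calibrated_agreement_recovers_requested_kappa(self):
        target = 0.64
        cfg = SyntheticConfig(seed=6, n_benign=2000, n_malignant=6000,
                              observer_agreement=target)
        cohort = sample_cohort(cfg)
        cats = list(RelationType)
        idx = {c: i for i, c in enumerate(cats)}
        table = np.zeros((5, 5), dtype=int)
        for r in cohort.records:
            table[idx[_kappa_label(r.obs1_relations)],
                  idx[_kappa_label(r.obs2_relations)]] += 1
        assert cohens_kappa(table).kappa == pytest.approx(target, abs=0.05)

    def test_zero_agreement_approaches_independence(self):
        cfg = SyntheticConfig(seed=7, n_benign=2000, n_malignant=6000,
                              observer_agreement=0.0)
        cohort = sample_cohort(cfg)
        cats = list(RelationType)
        idx = {c: i for i, c in enumerate(cats)}
        table = np.zeros((5, 5), dtype=int)
        for r in cohort.records:
            table[idx[_kappa_label(r.obs1_relations)],
                  idx[_kappa_label(r.obs2_relations)]] += 1
        assert cohens_kappa(table).kappa == pytest.approx(0.0, abs=0.05)


class TestPhantoms:
    def test_depth_zero_is_penetration(self):
        v = make_vessel_phantom(stenosis_depth=0.0)
        assert v.truth_relation is RelationType.PENETRATION
        m = measure_phantom(v)
        assert m.CD / m.AB == pytest.approx(1.0, abs=0.02)

    def test_depth_100_measures_as_amputation(self):
        v = make_vessel_phantom(stenosis_depth=100.0)
        m = measure_phantom(v)
        assert m.amputated and m.CD is None
        assert degree_of_encasement(m).degree == 100.0

    def test_untapered_depth_50_halves_the_caliber(self):
        v = make_vessel_phantom(stenosis_depth=50.0, taper_per_mm=0.0)
        m = measure_phantom(v)
        assert m.CD / m.AB == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("taper", [0.0, 0.02, 0.05])
    @pytest.mark.parametrize("depth", list(range(10, 100, 10)))
    def test_degree_recovery_within_two_points(self, depth, taper):
        """End-to-end: measured degree via the interpolated reference tracks
        the constructed truth across the depth x taper grid."""
        v = make_vessel_phantom(
            base_diameter=6.0, taper_per_mm=taper, lesion_radius=10.0,
            stenosis_depth=float(depth), stenosis_position=1.5,
            bifurcation_arcs=(-4.0, 5.0))
        m = measure_phantom(v)
        assert classify_encasement_type(m) is EncasementType.D
        r = degree_of_encasement(m)
        assert abs(r.degree - v.truth_degree) <= 2.0

    def test_stenosis_outside_lesion_rejected(self):
        with pytest.raises(ValueError, match="outside the lesion"):
            make_vessel_phantom(lesion_radius=5.0, stenosis_position=6.0)

    def test_vessel_swallowed_by_lesion_rejected(self):
        v = make_vessel_phantom()
        big = PhantomVessel(
            centerline=v.centerline, diameter_profile=v.diameter_profile,
            lesion_center=v.lesion_center, lesion_radius=1e4,
            truth_degree=v.truth_degree, truth_relation=v.truth_relation)
        with pytest.raises(ValueError, match="inside the lesion"):
            measure_phantom(big)

    def test_phantom_json_round_trip(self):
        v = make_vessel_phantom(stenosis_depth=30.0, bifurcation_arcs=(-2.0, 3.0))
        back = PhantomVessel.from_json(v.to_json())
        assert np.array_equal(back.centerline, v.centerline)
        assert np.array_equal(back.diameter_profile, v.diameter_profile)
        assert back.truth_degree == v.truth_degree
        assert back.bifurcation_arcs == v.bifurcation_arcs


class TestEndToEnd:
    def test_default_conditions_recover_the_diagnostic_signal(self):
        """A cohort drawn under the default (published-moment) conditions
        shows encasement as a malignancy marker: OR > 1 and AUC > 0.5."""
        cfg = SyntheticConfig(seed=17, n_benign=150, n_malignant=500)
        results = EncasementDiagnosticModel(sample_cohort(cfg)).fit()
        assert results.odds_ratios["encasement"].odds_ratio > 1.0
        assert results.roc is not None and results.roc.auc > 0.5
        assert results.fisher_p < 0.05
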
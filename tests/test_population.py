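"""Depth-stratified abundance arithmetic and migration metrics."""

import math

import numpy as np
import pytest

from zoopop import (
    STANDARD_LAYERS,
    DepthLayer,
    Detection,
    TowMetadata,
    areal_from_concentration,
    build_profile,
    concentration,
    dvm_amplitude,
    weighted_mean_depth,
)
from zoopop.population import LayerMeasure, VerticalProfile

from conftest import split_day_night


def _meta(sample_id, top, bottom, vol=100.0, aliquot=1.0, phase=None):
    return TowMetadata(
        sample_id=sample_id,
        layer=DepthLayer(top, bottom),
        filtered_volume_m3=vol,
        aliquot_fraction=aliquot,
        day_night=phase,
    )


def _det(obj, sample, esd=1.0, species="mpacifica", stage=None):
    return Detection(object_id=obj, sample_id=sample, species=species,
                     stage=stage, esd_mm=esd)


def _profile_from_areals(areals, layers):
    total = sum(areals)
    lms = tuple(
        LayerMeasure(layer=l, conc=a / l.thickness_m, areal=a,
                     fraction=a / total if total else float("nan"))
        for l, a in zip(layers, areals)
    )
    return VerticalProfile(layers=lms, column_total=total, measure="abundance")


class TestScalingArithmetic:
    @pytest.mark.parametrize(
        "count, aliquot, volume, expected",
        [(20, 1 / 8, 400.0, 0.4), (0, 1 / 2, 100.0, 0.0), (5, 1.0, 5.0, 1.0)],
    )
    def test_concentration(self, count, aliquot, volume, expected):
        m = _meta("s", 0, 50, vol=volume, aliquot=aliquot)
        assert concentration(count, m) == pytest.approx(expected)

    def test_concentration_guards(self):
        with pytest.raises(ValueError):
            concentration(-1, _meta("s", 0, 50))
        with pytest.raises(ValueError):
            _meta("s", 0, 50, vol=-5.0)
        with pytest.raises(ValueError):
            _meta("s", 0, 50, aliquot=0.0)

    @pytest.mark.parametrize(
        "conc, top, bottom, expected",
        [(0.4, 0, 50, 20.0), (1.0, 300, 500, 200.0)],
    )
    def test_areal_is_conc_times_thickness(self, conc, top, bottom, expected):
        assert areal_from_concentration(conc, DepthLayer(top, bottom)) == expected

    def test_degenerate_layer_rejected(self):
        with pytest.raises(ValueError):
            DepthLayer(50, 50)

    def test_aliquot_invariance_of_expectation(self):
        """Halving the aliquot while halving counts leaves conc unchanged."""
        m1 = _meta("a", 0, 50, aliquot=1 / 4)
        m2 = _meta("b", 0, 50, aliquot=1 / 8)
        assert concentration(40, m1) == concentration(20, m2)


class TestBuildProfile:
    def _three_layer_setup(self):
        layers = [(0, 50), (50, 100), (100, 150)]
        metas = [_meta(f"s{i}", t, b) for i, (t, b) in enumerate(layers)]
        return metas

    def test_fractions_are_proportions(self):
        metas = self._three_layer_setup()
        # counts 20/60/20 in equal layers & volumes -> fractions 0.2/0.6/0.2
        dets = (
            [_det(f"a{i}", "s0") for i in range(20)]
            + [_det(f"b{i}", "s1") for i in range(60)]
            + [_det(f"c{i}", "s2") for i in range(20)]
        )
        prof = build_profile(dets, metas, expected_layers=None)
        assert prof.fractions() == pytest.approx([0.2, 0.6, 0.2])
        assert sum(lm.fraction for lm in prof.layers) == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_fraction_is_one(self):
        metas = self._three_layer_setup()
        dets = [_det(f"a{i}", "s1") for i in range(7)]
        prof = build_profile(dets, metas, expected_layers=None)
        assert prof.layers[1].fraction == pytest.approx(1.0)

    def test_areal_equals_conc_times_thickness_everywhere(self):
        metas = self._three_layer_setup()
        dets = [_det(f"a{i}", f"s{i % 3}") for i in range(30)]
        prof = build_profile(dets, metas, expected_layers=None)
        for lm in prof.layers:
            assert lm.areal == pytest.approx(lm.conc * lm.layer.thickness_m)
        assert prof.column_total == pytest.approx(sum(lm.areal for lm in prof.layers))

    def test_orphan_sample_id_raises(self):
        metas = self._three_layer_setup()
        with pytest.raises(KeyError, match="unknown sample_id"):
            build_profile([_det("x", "nope")], metas, expected_layers=None)

    def test_overlapping_layers_rejected(self):
        metas = [_meta("a", 0, 100), _meta("b", 50, 150)]
        with pytest.raises(ValueError, match="overlap"):
            build_profile([], metas, expected_layers=None)

    def test_missing_layer_is_error_unless_partial(self):
        metas = [_meta(f"s{i}", l.top_m, l.bottom_m) for i, l in enumerate(STANDARD_LAYERS[:-1])]
        with pytest.raises(ValueError, match="not sampled"):
            build_profile([], metas)
        prof = build_profile([], metas, allow_partial=True)
        assert len(prof.layers) == 7

    def test_linearity_of_groups(self):
        """Profile of A∪B equals the element-wise sum of the two profiles."""
        metas = self._three_layer_setup()
        a = [_det(f"a{i}", f"s{i % 3}", species="mpacifica") for i in range(12)]
        b = [_det(f"b{i}", f"s{(i + 1) % 3}", species="ebungii") for i in range(9)]
        pa = build_profile(a + b, metas, species="mpacifica", expected_layers=None)
        pb = build_profile(a + b, metas, species="ebungii", expected_layers=None)
        pall = build_profile(a + b, metas, expected_layers=None)
        assert pall.column_total == pytest.approx(pa.column_total + pb.column_total)
        for la, lb, lall in zip(pa.layers, pb.layers, pall.layers):
            assert lall.areal == pytest.approx(la.areal + lb.areal)

    def test_biovolume_profile_sums_spheres(self):
        metas = [_meta("s0", 0, 50, vol=10.0, aliquot=1 / 2)]
        dets = [_det("a", "s0", esd=1.0), _det("b", "s0", esd=2.0)]
        prof = build_profile(dets, metas, measure="biovolume",
                             expected_layers=None)
        per_aliquot = math.pi / 6 + (4 / 3) * math.pi
        assert prof.layers[0].conc == pytest.approx(per_aliquot * 2 / 10.0)


class TestMigrationMetrics:
    def test_wmd_single_layer_is_midpoint(self):
        prof = _profile_from_areals([5.0], [DepthLayer(0, 50)])
        assert weighted_mean_depth(prof) == 25.0

    def test_wmd_symmetric_layers(self):
        prof = _profile_from_areals([1.0, 1.0], [DepthLayer(0, 50), DepthLayer(750, 1000)])
        assert weighted_mean_depth(prof) == pytest.approx((25 + 875) / 2)

    def test_wmd_hand_sum(self):
        layers = [DepthLayer(0, 50), DepthLayer(50, 100), DepthLayer(100, 150)]
        prof = _profile_from_areals([1.0, 2.0, 1.0], layers)
        assert weighted_mean_depth(prof) == pytest.approx(75.0)

    def test_wmd_empty_profile_undefined(self):
        prof = _profile_from_areals([0.0], [DepthLayer(0, 50)])
        with pytest.raises(ValueError):
            weighted_mean_depth(prof)

    def test_dvm_amplitude_identical_profiles_zero(self):
        prof = _profile_from_areals([1.0, 2.0], [DepthLayer(0, 50), DepthLayer(50, 100)])
        assert dvm_amplitude(prof, prof) == 0.0

    def test_dvm_amplitude_ascent_positive(self):
        day = _profile_from_areals([0.0, 3.0], [DepthLayer(0, 50), DepthLayer(100, 150)])
        night = _profile_from_areals([3.0, 0.0], [DepthLayer(0, 50), DepthLayer(100, 150)])
        assert dvm_amplitude(day, night) == pytest.approx(100.0)

    def test_dvm_amplitude_layer_scheme_mismatch(self):
        a = _profile_from_areals([1.0], [DepthLayer(0, 50)])
        b = _profile_from_areals([1.0], [DepthLayer(0, 100)])
        with pytest.raises(ValueError, match="layer schemes"):
            dvm_amplitude(a, b)


class TestScenarioRecovery:
    def test_night_surface_dominance_in_dvm_scenario(self, dvm_scenario):
        """At night the diel migrant concentrates above 50 m (>50% of the
        column), while by day the surface layer is nearly empty."""
        _, detections, metas, _ = dvm_scenario
        (day_d, day_m), (night_d, night_m) = split_day_night(detections, metas)
        night = build_profile(night_d, night_m)
        day = build_profile(day_d, day_m)
        assert night.layers[0].fraction > 0.5
        assert night.layers[0].fraction > day.layers[0].fraction

    def test_estimated_fractions_track_generator_truth(self, dvm_scenario):
        """Pipeline-estimated layer fractions agree with the generator's
        mixture distribution within a binomial 95% band at n=2,000."""
        cfg, detections, metas, truth = dvm_scenario
        (_, _), (night_d, night_m) = split_day_night(detections, metas)
        prof = build_profile(night_d, night_m)
        n = cfg.n_individuals
        for i, lm in enumerate(prof.layers):
            p = truth.true_fraction("N", i)
            # effective binomial n in a layer is the number of individuals
            # actually counted there: n * p thinned by the layer's aliquot
            n_eff = n * cfg.aliquot_fraction[i]
            se = math.sqrt(p * (1 - p) / n_eff)
            assert abs(lm.fraction - p) <= 1.96 * se + 0.01
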
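"""Simulator morphologies and the geometric descriptors that verify them."""

from dataclasses import replace

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from talsrx import synth
from talsrx.geometry import (
    NTC_SPECIFICITY_THRESHOLD,
    descriptor_features,
    morphology_descriptors,
)
from talsrx.plate import DNA, NTC, PlateRecord, Well
from talsrx.synth import default_spec, generate_dataset, jitter_spec, sample_plate


def noiseless(spec):
    return replace(spec, cluster_sd=0.0, tail_scale=0.0, ntc_sd=0.0)


class TestDefaultSpecs:
    def test_class_100_het_is_midpoint(self):
        spec = default_spec(100)
        a, b = spec.hom_centroids()
        np.testing.assert_allclose(spec.het_center(), 0.5 * (a + b))

    def test_class_10_has_specific_ntc(self):
        assert default_spec(10).ntc_mode == synth.NTC_SPECIFIC
        for s in (100, 90, 50, 0):
            assert default_spec(s).ntc_mode == synth.NTC_BACKGROUND

    def test_diffusion_grows_toward_zero_score(self):
        assert default_spec(0).diffusion_factor > default_spec(100).diffusion_factor

    def test_class_90_deviates_perpendicular_and_80_along(self):
        assert default_spec(90).het_offset_perp > 0
        assert default_spec(80).het_shift_along > 0

    def test_class_70_shifts_one_homozygote_only(self):
        spec = default_spec(70)
        assert spec.hom_shift > 0 and spec.hom_shift_which == "A"
        assert default_spec(60).hom_shift_which == "both"

    def test_score_70_trailing_alternative(self):
        alt = synth.score70_trailing_spec()
        assert alt.hom_shift == 0 and alt.tail_scale > 0

    def test_class_50_trails(self):
        assert default_spec(50).tail_scale > 0

    def test_invalid_score_rejected(self):
        with pytest.raises(Exception):
            default_spec(55)

    def test_counts_must_sum_to_94(self):
        with pytest.raises(ValueError, match="94"):
            synth.MorphologySpec(score=100, n_AA=40, n_BB=40, n_AB=15)


class TestSamplePlate:
    def test_zero_noise_class_100_geometry(self, rng):
        plate = sample_plate(noiseless(default_spec(100)), rng)
        rep = morphology_descriptors(plate)
        assert rep.het_midpoint_deviation == pytest.approx((0.0, 0.0), abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in rep.within_spread.values())

    def test_signal_range_matches_relative_fluorescence_scale(self):
        plate = sample_plate(default_spec(100), np.random.default_rng(1))
        coords = np.array([(w.x, w.y) for w in plate.wells])
        assert coords.min() >= 0.0
        assert coords.max() <= 1.6

    def test_label_and_genotype_recorded(self, rng):
        plate = sample_plate(default_spec(80), rng)
        assert plate.label == 80
        genos = {w.genotype for w in plate.wells if w.role == DNA}
        assert genos == {"AA", "BB", "AB"}
        assert len(plate.ntc_wells()) == 2

    def test_ntc_specific_class_scores_above_clean_class(self):
        p10 = sample_plate(default_spec(10), np.random.default_rng(1))
        p100 = sample_plate(default_spec(100), np.random.default_rng(1))
        i10 = morphology_descriptors(p10).ntc_specificity_index
        i100 = morphology_descriptors(p100).ntc_specificity_index
        assert i10 > i100


class TestGenerateDataset:
    def test_counts_and_labels(self):
        data = generate_dataset({100: 5, 0: 5}, 0)
        assert len(data) == 10
        assert sorted(data.scores()) == [0] * 5 + [100] * 5

    def test_deterministic_under_seed(self):
        a = generate_dataset({100: 4, 50: 4}, 11)
        b = generate_dataset({100: 4, 50: 4}, 11)
        np.testing.assert_array_equal(a.feature_matrix(), b.feature_matrix())

    def test_all_eleven_classes(self):
        counts = {s: 2 for s in range(0, 101, 10)}
        data = generate_dataset(counts, 0)
        assert len(data) == 22
        assert len(set(data.scores().tolist())) == 11

    def test_empty_counts_give_empty_dataset(self):
        assert len(generate_dataset({}, 0)) == 0

    def test_jitter_stays_within_twenty_percent(self, rng):
        base = default_spec(90)
        for _ in range(50):
            j = jitter_spec(base, rng)
            assert abs(j.het_offset_perp - base.het_offset_perp) <= 0.2 * base.het_offset_perp + 1e-12
            assert abs(j.cluster_sd - base.cluster_sd) <= 0.2 * base.cluster_sd + 1e-12


class TestDescriptors:
    def test_separation_strictly_decreases_along_diffusion_classes(self):
        seps = []
        for s in (100, 40, 30, 20, 0):
            plate = sample_plate(default_spec(s), np.random.default_rng(1))
            seps.append(morphology_descriptors(plate).separation_index)
        assert all(a > b for a, b in zip(seps, seps[1:]))

    def test_only_class_10_trips_ntc_threshold(self):
        for s in range(0, 101, 10):
            plate = sample_plate(default_spec(s), np.random.default_rng(1))
            rep = morphology_descriptors(plate)
            assert rep.ntc_specific == (s == 10)

    def test_hand_geometry_parallel_deviation(self):
        # homozygote line along x; shifting hom_A by +0.2 moves the midpoint
        # by +0.1, so the het deviation has parallel magnitude 0.1
        def well(x, y, g):
            return Well(x=x, y=y, role=DNA, genotype=g)

        def build(hom_a_x):
            wells = [well(hom_a_x, 0.5, "AA")] * 40 + [well(0.5, 0.5, "BB")] * 40
            wells += [well(0.9, 0.5, "AB")] * 14
            wells += [Well(x=0.3, y=0.3, role=NTC)] * 2
            return PlateRecord(snp_id="G", wells=tuple(wells))

        base = morphology_descriptors(build(1.3))
        assert base.het_midpoint_deviation == pytest.approx((0.0, 0.0))
        shifted = morphology_descriptors(build(1.5))
        par, perp = shifted.het_midpoint_deviation
        assert abs(par) == pytest.approx(0.1)
        assert perp == pytest.approx(0.0, abs=1e-12)

    def test_missing_genotype_class_fields_absent(self, rng):
        spec = replace(default_spec(100), n_AA=47, n_BB=47, n_AB=0)
        rep = morphology_descriptors(sample_plate(spec, rng))
        assert "AB" not in rep.centroids
        assert rep.het_midpoint_deviation is None
        assert rep.separation_index is not None  # two clusters remain

    def test_relabel_reflection_invariance(self):
        # swap AA <-> BB together with (x, y) -> (y, x): scale-covariant
        # descriptors are unchanged; deviation components keep magnitude
        plate = sample_plate(default_spec(90), np.random.default_rng(5))
        swap_geno = {"AA": "BB", "BB": "AA", "AB": "AB", "unknown": "unknown"}
        mirrored = PlateRecord(
            snp_id=plate.snp_id,
            wells=tuple(
                Well(x=w.y, y=w.x, role=w.role, genotype=swap_geno[w.genotype])
                for w in plate.wells
            ),
            label=plate.label,
        )
        a = morphology_descriptors(plate)
        b = morphology_descriptors(mirrored)
        assert a.separation_index == pytest.approx(b.separation_index)
        assert a.ntc_specificity_index == pytest.approx(b.ntc_specificity_index)
        assert a.within_spread["AA"] == pytest.approx(b.within_spread["BB"])
        assert abs(a.het_midpoint_deviation[0]) == pytest.approx(
            abs(b.het_midpoint_deviation[0])
        )
        assert abs(a.het_midpoint_deviation[1]) == pytest.approx(
            abs(b.het_midpoint_deviation[1])
        )

    def test_tailed_class_has_higher_tailing_index(self):
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
        tailed = morphology_descriptors(sample_plate(default_spec(50), rng1))
        clean = morphology_descriptors(sample_plate(default_spec(100), rng2))
        assert max(tailed.tailing_index.values()) > max(clean.tailing_index.values())


def test_descriptor_classifier_separates_extremes():
    """A plain classifier on descriptor features tells class 100 from class 0
    perfectly — the sanity floor for anything downstream."""
    rng = np.random.default_rng(0)
    X, y = [], []
    for score, label in ((100, 1), (0, 0)):
        for _ in range(50):
            plate = sample_plate(jitter_spec(default_spec(score), rng), rng)
            X.append(descriptor_features(plate))
            y.append(label)
    X, y = np.asarray(X), np.asarray(y)
    clf = LogisticRegression(max_iter=1000).fit(X, y)
    assert clf.score(X, y) == 1.0
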
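"""Concept detectors: GA-stratified thresholds, vocal/physio/facial rules,
and the learned concept heads."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neopain.concepts import (ConceptHeads, ConceptVector,
                              concept_heads_forward, detect_facial_concepts,
                              detect_physio_concepts, detect_vocal_concepts,
                              ga_stratum, resolve_thresholds)
from neopain.errors import ShapeError, ValidationError

AUDIO_RATE = 16_000


def harmonic_stack(f0, seconds=2.0, rms=0.4, n_harm=6):
    t = np.arange(int(seconds * AUDIO_RATE)) / AUDIO_RATE
    x = sum(np.sin(2 * np.pi * h * f0 * t) / h for h in range(1, n_harm + 1))
    return x / np.sqrt(np.mean(x ** 2)) * rms


def physio_frame(hr, spo2=97.0, rr=45.0, seconds=10.0, mp=None):
    n = int(seconds * 100)
    cols = {"time": np.arange(n) / 100, "hr": np.full(n, float(hr)),
            "spo2": np.full(n, float(spo2)), "rr": np.full(n, float(rr))}
    if mp is not None:
        cols["map"] = np.full(n, float(mp))
    return pd.DataFrame(cols)


class TestThresholdResolution:
    @pytest.mark.parametrize("ga,expected", [
        (26.0, 0.60), (39.0, 0.75), (28.0, 0.65), (32.0, 0.70), (36.9, 0.70)])
    def test_facial_threshold_by_stratum(self, table, ga, expected):
        assert resolve_thresholds(table, ga)["C1"]["threshold"] == expected

    def test_stratum_boundaries_are_half_open(self, table):
        assert ga_stratum(28.0) == "28-32"
        assert ga_stratum(27.999) == "<28"
        assert ga_stratum(37.0) == ">=37"

    def test_f0_threshold_splits_at_term(self, table):
        assert resolve_thresholds(table, 30.0)["C6"]["threshold"] == 450.0
        assert resolve_thresholds(table, 39.0)["C6"]["threshold"] == 500.0

    def test_ga_out_of_range_raises(self, table):
        with pytest.raises(ValidationError):
            resolve_thresholds(table, 50.0)

    def test_invalid_table_rejected(self, table):
        bad = {k: (dict(v) if isinstance(v, dict) else v)
               for k, v in table.raw.items()}
        bad["concepts"] = {k: dict(v) for k, v in table.raw["concepts"].items()}
        bad["concepts"]["C1"] = dict(bad["concepts"]["C1"],
                                     by_stratum={"<28": 0.75, "28-32": 0.65,
                                                 "32-37": 0.70, ">=37": 0.60})
        from neopain.concepts import ThresholdTable
        with pytest.raises(ValidationError, match="C1"):
            ThresholdTable.from_dict(bad)


class TestVocalConcepts:
    def test_sustained_loud_cry_fires_intensity(self, table):
        th = resolve_thresholds(table, 39.0)
        res = detect_vocal_concepts(harmonic_stack(400.0, rms=0.4), 39.0, th)
        assert res["C5"]["fired"] and res["C5"]["activation"] > 0.5

    @pytest.mark.parametrize("ga,f0,fires", [
        (39.0, 520.0, True), (39.0, 470.0, False), (30.0, 470.0, True)])
    def test_f0_elevation_respects_term_preterm_split(self, table, ga, f0, fires):
        th = resolve_thresholds(table, ga)
        res = detect_vocal_concepts(harmonic_stack(f0), ga, th)
        assert res["C6"]["fired"] is fires
        assert abs(res["C6"]["value"] - f0) < 15.0   # tracker recovers F0

    def test_digital_silence_leaves_all_vocal_concepts_inactive(self, table):
        th = resolve_thresholds(table, 39.0)
        res = detect_vocal_concepts(np.zeros(AUDIO_RATE * 2), 39.0, th)
        for cid in ("C5", "C6", "C7", "C8"):
            assert res[cid]["available"] and not res[cid]["fired"]
            assert res[cid]["activation"] <= 0.5

    def test_absent_waveform_marks_unavailable(self, table):
        th = resolve_thresholds(table, 39.0)
        res = detect_vocal_concepts(None, 39.0, th)
        assert not any(res[c]["available"] for c in ("C5", "C6", "C7", "C8"))

    def test_pause_gaps_detected_between_cries(self, table):
        th = resolve_thresholds(table, 39.0)
        cry = harmonic_stack(400.0, seconds=0.8)
        gap = np.zeros(int(0.3 * AUDIO_RATE))
        wave = np.concatenate([cry, gap, cry, gap, cry])
        res = detect_vocal_concepts(wave, 39.0, th)
        assert res["C8"]["fired"]
        assert res["C8"]["value"] == pytest.approx(300.0, abs=51)

    def test_noise_dominated_cry_fires_harmonic_distortion(self, table):
        rng = np.random.default_rng(0)
        th = resolve_thresholds(table, 39.0)
        harm = harmonic_stack(450.0, rms=1.0)
        noise = rng.normal(size=len(harm))
        noise /= np.sqrt(np.mean(noise ** 2))
        wave = 0.4 * (np.sqrt(0.2) * harm + np.sqrt(0.8) * noise)
        res = detect_vocal_concepts(wave, 39.0, th)
        assert res["C7"]["fired"]
        clean = detect_vocal_concepts(0.4 * harm, 39.0, th)
        assert not clean["C7"]["fired"]


class TestPhysioConcepts:
    def _run(self, table, base_hr, clip_hr, mp=None, base_mp=None, **kw):
        th = resolve_thresholds(table, 39.0)
        baseline = physio_frame(base_hr, seconds=120.0,
                                mp=base_mp if base_mp is not None else mp)
        clip = physio_frame(clip_hr, mp=mp, **kw)
        return detect_physio_concepts(clip, th, baseline)

    def test_hr_relative_branch(self, table):
        assert self._run(table, 150, 180)["C9"]["fired"]          # +20 %
        assert not self._run(table, 150, 160)["C9"]["fired"]      # +6.7 %

    def test_hr_absolute_branch(self, table):
        res = self._run(table, 170, 182)                          # +7.1 % but > 180
        assert res["C9"]["fired"]

    def test_spo2_absolute_branch_fires_at_steady_91(self, table):
        th = resolve_thresholds(table, 39.0)
        res = detect_physio_concepts(physio_frame(140, spo2=91.0), th,
                                     physio_frame(140, spo2=91.0, seconds=120))
        assert res["C10"]["fired"]

    def test_respiratory_cv_above_quarter_fires(self, table):
        th = resolve_thresholds(table, 39.0)
        rng = np.random.default_rng(1)
        clip = physio_frame(140)
        base = physio_frame(140, seconds=120.0)
        base["rr"] = 45.0 * (1 + 0.3 * np.sign(np.sin(
            2 * np.pi * 0.5 * base["time"])))
        res = detect_physio_concepts(clip, th, base)
        assert res["C11"]["fired"]

    def test_map_missing_makes_c12_unavailable(self, table):
        res = self._run(table, 140, 145)
        assert not res["C12"]["available"]
        res2 = self._run(table, 140, 145, mp=60.0)
        assert res2["C12"]["available"]

    def test_absent_physio_marks_unavailable(self, table):
        th = resolve_thresholds(table, 39.0)
        res = detect_physio_concepts(None, th)
        assert not any(res[c]["available"] for c in ("C9", "C10", "C11", "C12"))


class TestFacialConcepts:
    def test_term_threshold(self, table):
        th = resolve_thresholds(table, 39.0)
        res = detect_facial_concepts(np.full((300, 4), 0.8), 39.0, th)
        assert all(res[c]["fired"] for c in ("C1", "C2", "C3", "C4"))

    def test_preterm_lower_threshold(self, table):
        th26 = resolve_thresholds(table, 26.0)
        th39 = resolve_thresholds(table, 39.0)
        channels = np.full((300, 4), 0.65)
        assert detect_facial_concepts(channels, 26.0, th26)["C1"]["fired"]
        assert not detect_facial_concepts(channels, 39.0, th39)["C1"]["fired"]

    def test_zero_channels_inactive(self, table):
        th = resolve_thresholds(table, 39.0)
        res = detect_facial_concepts(np.zeros((300, 4)), 39.0, th)
        assert not any(res[c]["fired"] for c in ("C1", "C2", "C3", "C4"))

    def test_firing_monotone_in_ga_threshold(self, table, rng):
        """A clip firing at the term threshold fires at every lower one."""
        for _ in range(25):
            channels = np.clip(rng.uniform(0, 1.2, (60, 4)), 0, 1)
            fired = []
            for ga in (39.0, 33.0, 29.0, 26.0):
                th = resolve_thresholds(table, ga)
                fired.append(detect_facial_concepts(channels, ga, th)["C1"]["fired"])
            for hi, lo in zip(fired, fired[1:]):
                assert (not hi) or lo


class TestConceptVector:
    def test_unavailable_never_fires(self):
        cv = ConceptVector(np.full(12, 0.9), np.zeros(12, bool),
                           np.ones(12, bool))
        assert not cv.fired.any()

    def test_activation_bounds_enforced(self):
        with pytest.raises(ValidationError):
            ConceptVector(np.full(12, 1.2), np.ones(12, bool),
                          np.zeros(12, bool))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 32 - 1))
    def test_detector_activations_always_in_unit_interval(self, table, seed):
        """Arbitrary finite inputs produce activations in [0, 1]."""
        r = np.random.default_rng(seed)
        th = resolve_thresholds(table, float(r.uniform(24, 44)))
        wave = r.normal(0, r.uniform(0.01, 1.0), AUDIO_RATE * 2)
        res = detect_vocal_concepts(np.clip(wave, -1, 1), 30.0, th)
        for cid in ("C5", "C6", "C7", "C8"):
            assert 0.0 <= res[cid]["activation"] <= 1.0


class TestConceptHeads:
    def test_zero_weights_give_half_activation(self):
        heads = ConceptHeads(np.random.default_rng(0))
        for head in heads.heads:
            head.W.data[:] = 0.0
            head.b.data[:] = 0.0
        matrix, canonical, avail = concept_heads_forward(
            np.zeros(128), np.zeros(128), np.zeros(128), heads)
        np.testing.assert_allclose(matrix.numpy(), 0.5)
        np.testing.assert_allclose(canonical.numpy(), 0.5)

    def test_large_logit_saturates(self):
        heads = ConceptHeads(np.random.default_rng(0))
        for head in heads.heads:
            head.W.data[:] = 0.0
            head.b.data[:] = 20.0
        matrix, _, _ = concept_heads_forward(
            np.zeros(128), np.zeros(128), np.zeros(128), heads)
        assert (matrix.numpy() > 0.999).all()

    def test_canonical_selection_matches_source_rows(self, rng):
        heads = ConceptHeads(rng)
        h = [rng.normal(size=128) for _ in range(3)]
        matrix, canonical, avail = concept_heads_forward(*h, heads)
        m = matrix.numpy()
        expected = [m[0, k] if k < 4 else m[1, k] if k < 8 else m[2, k]
                    for k in range(12)]
        np.testing.assert_allclose(canonical.numpy(), expected)
        assert avail.all()

    def test_absent_source_modality_marks_unavailable(self, rng):
        heads = ConceptHeads(rng)
        _, _, avail = concept_heads_forward(
            np.zeros(128), np.zeros(128), np.zeros(128), heads,
            modality_mask=(True, False, True))
        assert avail[:4].all() and not avail[4:8].any() and avail[8:].all()

    def test_wrong_dimension_is_shape_error(self, rng):
        heads = ConceptHeads(rng)
        with pytest.raises(ShapeError):
            concept_heads_forward(np.zeros(64), np.zeros(128),
                                  np.zeros(128), heads)


def test_zero_noise_detectors_reproduce_ground_truth(clean_dataset):
    """At zero measurement noise the rule-based firing equals the
    generator's clean-signal concept labels exactly."""
    ds = clean_dataset
    assert (ds.fired == ds.gt_fired).all()
    assert (ds.available == ds.gt_available).all()
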
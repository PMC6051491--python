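"""Generators: determinism, planted structure, validation."""

import numpy as np
import pytest

from halopol.errors import LocalizationError, ValidationError
from halopol.flowstretch import localize_bead, to_bases
from halopol.synthetic_data import (
    BindingSimParams,
    RamanSimParams,
    SequenceSimParams,
    TraceSimParams,
    simulate_bead_frames,
    simulate_binding,
    simulate_raman,
    simulate_sequence,
    simulate_traces,
)


class TestTraceGenerator:
    def test_bit_reproducible(self):
        a = simulate_traces(TraceSimParams(n_reaction_traces=2, seed=11))
        b = simulate_traces(TraceSimParams(n_reaction_traces=2, seed=11))
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.extension, tb.extension)
        assert a.truth == b.truth

    def test_noiseless_slope_is_rate_over_calibration(self):
        """With no noise/drift/pauses and zero rate spread, the reaction
        trace climbs at exactly rate/3.76 nm per second."""
        p = TraceSimParams(
            rate_mean=376.0, rate_sd=0.0, noise_sd=0.0, drift_amplitude=0.0,
            pause_probability_per_segment_end=0.0, processivity_mean=1e6,
            n_reaction_traces=1, n_control_traces=0, seed=3,
        )
        sim = simulate_traces(p)
        tr = sim.traces[0]
        ramp = tr.extension[tr.extension < sim.params.template_length / 3.76 - 1e-9]
        slopes = np.diff(ramp) / sim.params.sampling_interval
        np.testing.assert_allclose(slopes, 376.0 / 3.76, rtol=1e-9)

    def test_noiseless_traces_nondecreasing_and_capped(self):
        p = TraceSimParams(noise_sd=0.0, drift_amplitude=0.0, n_reaction_traces=4, seed=5)
        sim = simulate_traces(p)
        for tr in sim.traces:
            if tr.role != "reaction":
                continue
            assert np.all(np.diff(tr.extension) >= -1e-9)
            bases = to_bases(tr).extension
            assert bases.max() <= p.template_length + 1e-6

    def test_segment_length_law_of_large_numbers(self):
        """The censored exponential MLE on ~500 true segment lengths (the
        template-capped final segment of each molecule censored) approaches
        the configured processivity mean; the naive mean of uncapped
        segments would be biased low by the template-crossing condition."""
        p = TraceSimParams(
            processivity_mean=1000.0, noise_sd=0.0, drift_amplitude=0.0,
            n_reaction_traces=75, n_control_traces=0, seed=21,
        )
        sim = simulate_traces(p)
        lengths, n_uncapped = [], 0
        for v in sim.truth["traces"].values():
            for s in v["segments"]:
                lengths.append(s["length"])
                n_uncapped += not s["capped"]
        assert n_uncapped >= 400
        mle = np.sum(lengths) / n_uncapped
        assert abs(mle - 1000.0) / 1000.0 < 0.10

    @pytest.mark.parametrize(
        "field,value",
        [
            ("sampling_interval", 0.0),
            ("calibration", -1.0),
            ("rate_sd", -1.0),
            ("pause_probability_per_segment_end", 1.5),
            ("n_reaction_traces", 0),
        ],
    )
    def test_validation_names_field(self, field, value):
        params = TraceSimParams(**{field: value})
        with pytest.raises(ValidationError) as exc:
            params.validate()
        assert exc.value.field == field

    def test_truth_sidecar_has_indices_and_seconds(self, br3_sim):
        any_trace = next(iter(br3_sim.truth["traces"].values()))
        seg = any_trace["segments"][0]
        assert {"start_s", "end_s", "start_index", "end_index", "rate", "length"} <= set(seg)


class TestBeadFrames:
    def test_noiseless_frame_localizes_exactly(self):
        frames = simulate_bead_frames([(12.3, 45.6)], psf_sd=2.0, amplitude=1000.0)
        x, y = localize_bead(frames[0])
        assert abs(x - 12.3) < 0.01 and abs(y - 45.6) < 0.01

    def test_zero_amplitude_reports_failure(self):
        frames = simulate_bead_frames([(20.0, 20.0)], psf_sd=2.0, amplitude=0.0, noise_sd=1.0)
        with pytest.raises(LocalizationError):
            localize_bead(frames[0])

    def test_position_outside_frame_rejected(self):
        with pytest.raises(ValidationError):
            simulate_bead_frames([(100.0, 5.0)], frame_size=(64, 64))


class TestRamanGenerator:
    def test_single_band_area_normalised(self):
        # pure Gaussian: integrable to 0.1% on a finite window
        p = RamanSimParams(
            band_centers=(1650.0,), band_widths=(18.0,), band_areas=(42.0,),
            mixing_fractions=(0.0,), wavenumber_grid=np.arange(1400.0, 1900.0, 0.2),
        )
        sim = simulate_raman(p)
        area = np.trapezoid(sim.spectrum.intensity, sim.spectrum.wavenumber)
        assert abs(area - 42.0) / 42.0 < 1e-3
        # half-Lorentzian mix: tails truncated by any finite window, ~1%
        p2 = RamanSimParams(
            band_centers=(1650.0,), band_widths=(18.0,), band_areas=(42.0,),
            mixing_fractions=(0.5,), wavenumber_grid=np.arange(1000.0, 2300.0, 0.2),
        )
        sim2 = simulate_raman(p2)
        area2 = np.trapezoid(sim2.spectrum.intensity, sim2.spectrum.wavenumber)
        assert abs(area2 - 42.0) / 42.0 < 0.01

    def test_grid_must_cover_centers(self):
        p = RamanSimParams(wavenumber_grid=np.arange(1600.0, 1800.0, 0.5))
        with pytest.raises(ValidationError):
            simulate_raman(p)

    def test_truth_bands_emitted(self):
        sim = simulate_raman(RamanSimParams(seed=2))
        assert [b["center"] for b in sim.truth["bands"]] == list(sim.params.band_centers)


class TestBindingGenerator:
    def test_half_saturation_identity(self):
        p = BindingSimParams(kd=50.0, rmax=300.0, concentrations=(25.0, 50.0, 100.0))
        sim = simulate_binding(p)
        i = list(p.concentrations).index(50.0)
        assert sim.series.responses[i] == pytest.approx(150.0)

    def test_saturation_limit(self):
        kd = 15.1
        p = BindingSimParams(kd=kd, rmax=400.0, concentrations=(kd, 1e6 * kd))
        sim = simulate_binding(p)
        assert abs(sim.series.responses[-1] - 400.0) / 400.0 < 1e-4

    def test_concentrations_must_increase(self):
        with pytest.raises(ValidationError):
            simulate_binding(BindingSimParams(concentrations=(100.0, 50.0)))


class TestSequenceGenerator:
    def test_planted_composition_exact(self):
        p = SequenceSimParams(
            length=100, target_acidic_fraction=0.2, target_basic_fraction=0.1,
            disorder_segments=((10, 40),), seed=1,
        )
        sim = simulate_sequence(p)
        seq = sim.record.residues
        assert sum(c in "DE" for c in seq) == 20
        assert sum(c in "RK" for c in seq) == 10

    def test_full_enrichment_puts_all_acidics_in_disorder(self):
        p = SequenceSimParams(
            length=200, target_acidic_fraction=0.15, target_basic_fraction=0.1,
            disorder_segments=((50, 150),), acidic_enrichment_in_disorder=1.0, seed=4,
        )
        sim = simulate_sequence(p)
        for rec in sim.truth["acidic_positions"]:
            assert 50 <= rec["position"] <= 150

    def test_disorder_track_respects_layout(self):
        p = SequenceSimParams(length=50, disorder_segments=((11, 30),), seed=9)
        sim = simulate_sequence(p)
        probs = sim.disorder.probabilities
        assert np.all(probs[10:30] >= 0.5)
        assert np.all(probs[:10] < 0.5) and np.all(probs[30:] < 0.5)

    def test_infeasible_composition_rejected(self):
        with pytest.raises(ValidationError):
            SequenceSimParams(
                target_acidic_fraction=0.7, target_basic_fraction=0.5
            ).validate()
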
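"""Single-molecule chain: localization, drift, units, segmentation, fits."""

import numpy as np
import pytest

from halopol.errors import LocalizationError, UnitError, ValidationError
from halopol.flowstretch import (
    Trace,
    analyze_experiment,
    correct_drift,
    estimate_noise_sd,
    fit_processivity,
    fit_rate_distribution,
    localize_bead,
    segment_trace,
    to_bases,
)
from halopol.synthetic_data import TraceSimParams, simulate_bead_frames, simulate_traces


def make_trace(values, dt=0.5, unit="bases", role="reaction", trace_id="t"):
    values = np.asarray(values, dtype=float)
    return Trace(trace_id, role, np.arange(values.size) * dt, values, unit=unit)


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------


def test_localization_uniform_frame_fails():
    with pytest.raises(LocalizationError):
        localize_bead(np.full((48, 48), 3.0))


def test_localization_rms_error_under_noise():
    """Monte-Carlo against planted truth: 100 frames at 5% pixel noise
    localize to better than 0.2 px RMS."""
    truth = (20.5, 30.25)
    frames = simulate_bead_frames([truth] * 100, psf_sd=2.0, amplitude=1000.0,
                                  noise_sd=50.0, seed=3)
    errs = [np.hypot(*(np.array(localize_bead(f)) - truth)) for f in frames]
    assert np.sqrt(np.mean(np.square(errs))) < 0.2


# ---------------------------------------------------------------------------
# drift correction and calibration
# ---------------------------------------------------------------------------


def test_drift_cancels_exactly_with_exact_controls():
    t = np.arange(0, 60, 0.5)
    drift = 8.0 * np.sin(2 * np.pi * t / 37.0 + 0.3)
    ramp = 2.5 * t
    reaction = make_trace(ramp + drift, unit="nm")
    control = make_trace(5.0 + drift, unit="nm", role="control")
    corrected = correct_drift([reaction], [control])[0]
    # drift removed exactly; the (mean-of-drift) constant offset is preserved
    residual = corrected.extension - ramp
    np.testing.assert_allclose(residual, residual[0], atol=1e-9)
    assert residual[0] == pytest.approx(drift.mean(), abs=1e-9)


def test_zero_centered_controls_leave_reaction_unchanged():
    t = np.arange(0, 30, 0.5)
    reaction = make_trace(3.0 * t, unit="nm")
    control = make_trace(np.full(t.size, 7.0), unit="nm", role="control")
    corrected = correct_drift([reaction], [control])[0]
    np.testing.assert_allclose(corrected.extension, reaction.extension)


def test_drift_correction_errors():
    a = make_trace(np.zeros(20), unit="nm")
    b = Trace("b", "control", np.arange(10) * 0.5, np.zeros(10), unit="nm")
    with pytest.raises(ValidationError):
        correct_drift([a], [])
    with pytest.raises(ValidationError):
        correct_drift([a], [b])


def test_residual_drift_small_with_noisy_controls(rng):
    """Three controls at 2 nm noise remove a 20 nm drift to < 2 nm RMS."""
    t = np.arange(0, 120, 0.5)
    drift = 20.0 * np.sin(2 * np.pi * t / 80.0)
    reaction = make_trace(drift, unit="nm")  # flat molecule + drift
    controls = [
        make_trace(drift + rng.normal(0, 2.0, t.size), unit="nm", role="control")
        for _ in range(3)
    ]
    corrected = correct_drift([reaction], controls)[0]
    residual = corrected.extension - corrected.extension.mean()
    assert np.sqrt(np.mean(residual**2)) < 2.0


def test_to_bases_conversion_and_unit_safety():
    tr = make_trace([0.0, 100.0] * 10, unit="nm")
    conv = to_bases(tr)
    assert conv.unit == "bases"
    assert conv.extension[1] == pytest.approx(376.0)
    assert conv.extension[0] == 0.0
    ident = to_bases(tr, calibration=1.0)
    np.testing.assert_array_equal(ident.extension, tr.extension)
    assert ident.unit == "bases"
    with pytest.raises(UnitError):
        to_bases(conv)


# ---------------------------------------------------------------------------
# noise estimation
# ---------------------------------------------------------------------------


def test_noise_sd_on_white_noise(rng):
    x = rng.normal(0, 2.0, 10_000)
    est = estimate_noise_sd(make_trace(x))
    assert 1.9 < est < 2.1


def test_noise_sd_zero_on_clean_ramp():
    x = np.linspace(0, 500, 300)
    assert estimate_noise_sd(make_trace(x)) < 1e-9


@pytest.mark.parametrize("slope", [0.0, 5.0, 400.0])
def test_noise_sd_slope_invariant(rng, slope):
    t = np.arange(5000) * 0.5
    x = slope * t + rng.normal(0, 2.0, t.size)
    est = estimate_noise_sd(make_trace(x))
    assert abs(est - 2.0) / 2.0 < 0.1


def test_noise_sd_needs_enough_samples():
    with pytest.raises(ValidationError):
        estimate_noise_sd(make_trace(np.zeros(10)))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def test_pause_rule_hand_case(rng):
    """7-point ramp, 8 flat points (fluctuation within +/-0.5, sd=1),
    5-point ramp: exactly one pause covering the flats, two segments."""
    flat = 300.0 + rng.uniform(-0.5, 0.5, 8)
    values = np.concatenate([np.arange(7) * 50.0, flat, 350.0 + np.arange(5) * 50.0])
    res = segment_trace(make_trace(values), noise_sd=1.0)
    assert len(res.pauses) == 1
    p = res.pauses[0]
    assert p.start_index <= 7 and p.end_index >= 15  # covers the flat run
    assert len(res.segments) == 2


def test_monotone_ramp_is_single_segment():
    values = np.arange(40) * 50.0
    res = segment_trace(make_trace(values), noise_sd=1.0)
    assert res.pauses == []
    assert len(res.segments) == 1
    seg = res.segments[0]
    assert (seg.start_index, seg.end_index) == (0, 40)
    assert seg.rate == pytest.approx(100.0)  # 50 bases per 0.5 s


def test_flat_trace_is_single_pause():
    res = segment_trace(make_trace(np.full(30, 123.0)), noise_sd=1.0)
    assert len(res.pauses) == 1
    assert (res.pauses[0].start_index, res.pauses[0].end_index) == (0, 30)
    assert res.segments == []


def test_segment_trace_rejects_bad_inputs():
    tr = make_trace(np.zeros(30))
    with pytest.raises(ValidationError):
        segment_trace(tr, noise_sd=-1.0)
    with pytest.raises(UnitError):
        segment_trace(make_trace(np.zeros(30), unit="nm"), noise_sd=1.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_tiling_invariant(seed):
    """Pauses, segments and discarded intervals are disjoint and cover [0, n)."""
    sim = simulate_traces(TraceSimParams(n_reaction_traces=3, seed=seed))
    traces = correct_drift(
        [t for t in sim.traces if t.role == "reaction"],
        [t for t in sim.traces if t.role == "control"],
    )
    for tr in traces:
        res = segment_trace(to_bases(tr), noise_sd=9.0)
        intervals = (
            [(p.start_index, p.end_index) for p in res.pauses]
            + [(s.start_index, s.end_index) for s in res.segments]
            + [(s, e) for s, e, _ in res.discarded]
        )
        covered = np.zeros(res.n_samples, dtype=int)
        for s, e in intervals:
            covered[s:e] += 1
        assert np.all(covered == 1)


def test_exact_boundary_recovery_on_clean_traces(clean_sim):
    """Zero noise, zero drift: detected pause/segment sample intervals
    equal the generator's ground truth exactly."""
    res = analyze_experiment(clean_sim.traces, noise_sd=0.0)
    for seg_result in res["segmentations"]:
        truth = clean_sim.truth["traces"][seg_result.trace_id]
        true_pauses = sorted(
            (p["start_index"], p["end_index"])
            for p in truth["pauses"]
            if p["start_index"] is not None
        )
        detected = sorted((p.start_index, p.end_index) for p in seg_result.pauses)
        assert detected == true_pauses
        true_segments = sorted(
            (s["start_index"], s["end_index"])
            for s in truth["segments"]
            if s["start_index"] is not None and s["end_index"] - s["start_index"] >= 3
        )
        detected_segments = sorted((s.start_index, s.end_index) for s in seg_result.segments)
        assert detected_segments == true_segments


# ---------------------------------------------------------------------------
# population fits
# ---------------------------------------------------------------------------


def test_rate_fit_trivial_cases():
    est = fit_rate_distribution([100.0, 100.0, 100.0])
    assert (est.mean, est.sd) == (100.0, 0.0)
    assert fit_rate_distribution([90.0, 110.0]).mean == pytest.approx(100.0)
    with pytest.raises(ValidationError):
        fit_rate_distribution([100.0])


def test_rate_fit_recovers_gaussian_mean(rng):
    rates = rng.normal(460.0, 35.0, 83)
    est = fit_rate_distribution(rates)
    assert abs(est.mean - 460.0) < 12.0
    assert est.fit_uncertainty == pytest.approx(est.sd / np.sqrt(83))


def test_processivity_trivial_cases():
    assert fit_processivity([1000.0, 1000.0]).mean == pytest.approx(1000.0)
    assert fit_processivity([1000.0, 3000.0]).mean == pytest.approx(2000.0)
    with pytest.raises(ValidationError):
        fit_processivity([1000.0, -5.0])


def test_processivity_mle_consistency(rng):
    lengths = rng.exponential(2000.0, 500)
    est = fit_processivity(lengths)
    assert abs(est.mean - 2000.0) / 2000.0 < 0.10
    assert est.mean == pytest.approx(lengths.mean())


def test_processivity_censoring_changes_denominator_only():
    """Right-censored observations keep their mass in the numerator but do
    not count as completed events."""
    from halopol.flowstretch import ExtensionRise

    rises = [
        ExtensionRise(0, 10, 1500.0, 0.0, 1500.0),
        ExtensionRise(12, 20, 2500.0, 1500.0, 4000.0),
        ExtensionRise(25, 30, 3249.0, 4000.0, 7249.0),  # reaches the template end
    ]
    plain = fit_processivity(rises)
    censored = fit_processivity(rises, censor_at=7249.0)
    assert plain.mean == pytest.approx(7249.0 / 3)
    assert censored.mean == pytest.approx(7249.0 / 2)
    assert censored.n_censored == 1


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------


def test_pipeline_recovers_simulation_parameters():
    """With the pause threshold well below the per-sample synthesis step,
    the full chain recovers rate and processivity within 10% (large-n run
    so population sampling noise does not dominate)."""
    params = TraceSimParams(n_reaction_traces=100, seed=42)
    sim = simulate_traces(params)
    res = analyze_experiment(sim.traces, censor_at=params.template_length)
    assert abs(res["rate"].mean - params.rate_mean) / params.rate_mean < 0.10
    assert abs(res["processivity"].mean - params.processivity_mean) / params.processivity_mean < 0.10
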
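"""Seeded generators for every input class the analysis modules consume.

Each generator emulates one instrument's output with the statistical
structure the downstream estimators assume, and returns the ground truth
alongside the data so any estimator can be scored without reaching back
into generator internals:

* :func:`simulate_traces` — flow-stretching bead trajectories: alternating
  synthesis ramps (exponential lengths, Gaussian rates) and pause plateaus
  (shifted-exponential durations), shared low-frequency drift, white noise,
  plus no-synthesis control traces.
* :func:`simulate_bead_frames` — camera frames with a 2-D Gaussian bead
  spot and pixel noise, for localization benchmarks.
* :func:`simulate_raman` — multi-band pseudo-Voigt spectra on a linear
  baseline.
* :func:`simulate_binding` — equilibrium Langmuir (1:1 steady-state) SPR
  response series.
* :func:`simulate_sequence` — amino-acid sequences with planted charge
  composition, disorder layout, and acidic enrichment inside disordered
  segments.

All generators are bit-reproducible given (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .flowstretch import Trace
from .lineshapes import gaussian_2d, pseudo_voigt
from .raman import Band, Spectrum
from .seqprofile import DisorderTrack, DomainAnnotation, SequenceRecord
from .spr import BindingSeries

__all__ = [
    "TraceSimParams",
    "RamanSimParams",
    "BindingSimParams",
    "SequenceSimParams",
    "TraceSimulation",
    "RamanSimulation",
    "BindingSimulation",
    "SequenceSimulation",
    "simulate_traces",
    "simulate_bead_frames",
    "simulate_raman",
    "simulate_binding",
    "simulate_sequence",
    "BR3_TRACE_PARAMS",
    "PFU_TRACE_PARAMS",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ACIDIC = "DE"
_BASIC = "RK"
_NEUTRAL = "".join(a for a in _AMINO_ACIDS if a not in _ACIDIC + _BASIC)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class TraceSimParams:
    """Flow-stretching trajectory simulation conditions.

    Defaults are the BR3 Pol single-molecule conditions: 460 +/- 35 bases/s
    rates, 2.0 kb mean processivity, a ~7.2 kb template, 0.5 s sampling and
    the 3.76 b/nm calibration. Pause durations are a shifted exponential:
    ``pause_duration_min`` (default 3 s, the operational minimum for a
    detectable pause at 0.5 s sampling) plus an exponential tail so the mean
    equals ``pause_duration_mean``.
    """

    rate_mean: float = 460.0  # bases/s
    rate_sd: float = 35.0  # bases/s
    processivity_mean: float = 2000.0  # bases
    pause_duration_mean: float = 5.0  # s
    pause_duration_min: float = 3.0  # s
    pause_probability_per_segment_end: float = 1.0
    sampling_interval: float = 0.5  # s
    noise_sd: float = 2.0  # nm
    drift_amplitude: float = 10.0  # nm
    template_length: float = 7249.0  # bases
    calibration: float = 3.76  # bases/nm
    n_reaction_traces: int = 25
    n_control_traces: int = 3
    tail_duration: float = 5.0  # s of terminal plateau after template exhaustion
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval", "must be > 0")
        if self.calibration <= 0:
            raise ValidationError("calibration", "must be > 0")
        for name in ("rate_sd", "noise_sd", "drift_amplitude"):
            if getattr(self, name) < 0:
                raise ValidationError(name, "must be >= 0")
        if self.rate_mean <= 0:
            raise ValidationError("rate_mean", "must be > 0")
        if self.processivity_mean <= 0:
            raise ValidationError("processivity_mean", "must be > 0")
        if not 0 <= self.pause_probability_per_segment_end <= 1:
            raise ValidationError("pause_probability_per_segment_end", "must be in [0, 1]")
        if self.pause_duration_min < 0 or self.pause_duration_mean < self.pause_duration_min:
            raise ValidationError(
                "pause_duration_mean", "must be >= pause_duration_min (and both >= 0)"
            )
        if self.template_length <= 0:
            raise ValidationError("template_length", "must be > 0")
        if self.n_reaction_traces < 1:
            raise ValidationError("n_reaction_traces", "must be >= 1")
        if self.n_control_traces < 0:
            raise ValidationError("n_control_traces", "must be >= 0")


#: Single-molecule conditions for BR3 Pol (250 mM KCl optimum).
BR3_TRACE_PARAMS = TraceSimParams()

#: Single-molecule conditions for Pfu Pol (0 mM KCl optimum): slower rate,
#: shorter processivity, fewer molecules.
PFU_TRACE_PARAMS = TraceSimParams(
    rate_mean=305.0, rate_sd=40.0, processivity_mean=1300.0, n_reaction_traces=13
)


@dataclass
class RamanSimParams:
    """Multi-band spectrum conditions.

    Defaults are the amide/side-chain region of a soluble protein: six bands
    at ~1550 (Trp indole), 1580 (Ala+Gly), 1610 (Tyr/Trp/Phe), 1650
    (alpha-helix), 1670 (random coil) and 1680 cm^-1 (beta-sheet), with
    structural areas in a 50/30/20 helix/coil/sheet ratio.
    """

    band_centers: Sequence[float] = (1550.0, 1580.0, 1610.0, 1650.0, 1670.0, 1680.0)
    band_widths: Sequence[float] = (12.0, 12.0, 14.0, 18.0, 18.0, 14.0)  # FWHM, cm^-1
    band_areas: Sequence[float] = (8.0, 6.0, 10.0, 50.0, 30.0, 20.0)  # a.u.
    mixing_fractions: Sequence[float] = (0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
    baseline_slope: float = 0.0  # a.u. per cm^-1
    baseline_intercept: float = 0.0  # a.u.
    noise_sd: float = 0.0  # a.u.
    wavenumber_grid: Sequence[float] | None = None  # default 1450..1850 step 0.5
    seed: int = 0

    def grid(self) -> np.ndarray:
        if self.wavenumber_grid is None:
            return np.arange(1450.0, 1850.0 + 0.25, 0.5)
        return np.asarray(self.wavenumber_grid, dtype=float)

    def validate(self) -> None:
        centers = np.asarray(self.band_centers, dtype=float)
        if centers.size < 1 or np.any(np.diff(centers) <= 0):
            raise ValidationError("band_centers", "must be non-empty and strictly increasing")
        for name in ("band_widths", "band_areas", "mixing_fractions"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size != centers.size:
                raise ValidationError(name, "must match band_centers in length")
        if np.any(np.asarray(self.band_widths, dtype=float) <= 0):
            raise ValidationError("band_widths", "must be > 0")
        if np.any(np.asarray(self.band_areas, dtype=float) < 0):
            raise ValidationError("band_areas", "must be >= 0")
        mix = np.asarray(self.mixing_fractions, dtype=float)
        if np.any((mix < 0) | (mix > 1)):
            raise ValidationError("mixing_fractions", "must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd", "must be >= 0")
        grid = self.grid()
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("wavenumber_grid", "must be strictly increasing")
        if grid.min() > centers.min() or grid.max() < centers.max():
            raise ValidationError("wavenumber_grid", "must cover all band centers")


@dataclass
class BindingSimParams:
    """Equilibrium SPR series conditions: the 10-600 nM analyte ladder.

    ``noise_sd`` is additive RU noise; ``noise_relative`` multiplies each
    response by (1 + eps) with eps ~ N(0, noise_relative), matching
    percent-of-signal instrument noise.
    """

    kd: float = 15.1  # nM
    rmax: float = 400.0  # RU
    concentrations: Sequence[float] = (10.0, 20.0, 50.0, 100.0, 200.0, 400.0, 600.0)  # nM
    noise_sd: float = 0.0  # RU
    noise_relative: float = 0.0  # fraction of signal
    seed: int = 0

    def validate(self) -> None:
        if self.kd <= 0:
            raise ValidationError("kd", "must be > 0")
        if self.rmax <= 0:
            raise ValidationError("rmax", "must be > 0")
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 1 or np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValidationError("concentrations", "must be positive and strictly increasing")
        if self.noise_sd < 0 or self.noise_relative < 0:
            raise ValidationError("noise_sd", "noise terms must be >= 0")


@dataclass
class SequenceSimParams:
    """Planted-composition protein sequence conditions.

    Defaults emulate a halophilic family-B polymerase: 818 residues, an
    acidic excess (17% D+E vs 11% R+K), ~30% of the chain in disordered
    segments, and acidic residues preferentially placed there.
    """

    length: int = 818
    target_acidic_fraction: float = 0.17
    target_basic_fraction: float = 0.11
    disorder_segments: Sequence[tuple[int, int]] = ((40, 120), (380, 470), (740, 818))
    acidic_enrichment_in_disorder: float = 0.5
    domain_layout: Sequence[tuple[str, int, int]] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.length < 1:
            raise ValidationError("length", "must be >= 1")
        if not 0 <= self.target_acidic_fraction <= 1 or not 0 <= self.target_basic_fraction <= 1:
            raise ValidationError("target_acidic_fraction", "fractions must be in [0, 1]")
        if self.target_acidic_fraction + self.target_basic_fraction > 1:
            raise ValidationError(
                "target_acidic_fraction", "acidic + basic target fractions exceed 1"
            )
        for start, end in self.disorder_segments:
            if not (1 <= start <= end <= self.length):
                raise ValidationError("disorder_segments", f"interval ({start}, {end}) outside sequence")
        if not 0 <= self.acidic_enrichment_in_disorder <= 1:
            raise ValidationError("acidic_enrichment_in_disorder", "must be in [0, 1]")
        prev_end = 0
        for name, start, end in self.domain_layout:
            if not (1 <= start <= end <= self.length):
                raise ValidationError("domain_layout", f"domain {name!r} outside sequence")
            if start <= prev_end:
                raise ValidationError("domain_layout", "domains must be ordered and non-overlapping")
            prev_end = end


# ---------------------------------------------------------------------------
# Result containers (data + ground truth)
# ---------------------------------------------------------------------------


@dataclass
class TraceSimulation:
    traces: list[Trace]
    truth: dict
    params: TraceSimParams


@dataclass
class RamanSimulation:
    spectrum: Spectrum
    bands: list[Band]
    truth: dict
    params: RamanSimParams


@dataclass
class BindingSimulation:
    series: BindingSeries
    truth: dict
    params: BindingSimParams


@dataclass
class SequenceSimulation:
    record: SequenceRecord
    disorder: DisorderTrack
    domains: list[DomainAnnotation]
    truth: dict
    params: SequenceSimParams


# ---------------------------------------------------------------------------
# Flow-stretching trajectories
# ---------------------------------------------------------------------------


def _draw_events(params: TraceSimParams, rng: np.random.Generator) -> list[dict]:
    """One molecule's alternating synthesis/pause schedule in continuous time."""
    events = []
    t = 0.0
    level = 0.0  # cumulative synthesized bases
    while level < params.template_length:
        rate = 0.0
        while rate <= 0:
            rate = rng.normal(params.rate_mean, params.rate_sd) if params.rate_sd > 0 else params.rate_mean
        length = rng.exponential(params.processivity_mean)
        capped = level + length >= params.template_length
        if capped:
            length = params.template_length - level
        duration = length / rate
        events.append(
            {
                "kind": "segment",
                "start_s": t,
                "end_s": t + duration,
                "rate": rate,
                "length": length,
                "capped": capped,
            }
        )
        t += duration
        level += length
        if capped:
            break
        if rng.random() < params.pause_probability_per_segment_end:
            scale = params.pause_duration_mean - params.pause_duration_min
            d = params.pause_duration_min + (rng.exponential(scale) if scale > 0 else 0.0)
            events.append({"kind": "pause", "start_s": t, "end_s": t + d})
            t += d
    return events


def _eval_piecewise(events: list[dict], t: np.ndarray) -> np.ndarray:
    """Cumulative synthesized bases at each sample time."""
    out = np.zeros_like(t)
    level = 0.0
    for ev in events:
        a, b = ev["start_s"], ev["end_s"]
        if ev["kind"] == "segment":
            inside = (t >= a) & (t < b)
            out[inside] = level + ev["rate"] * (t[inside] - a)
            level += ev["length"]
        out[t >= b] = level
    return out


def simulate_traces(params: TraceSimParams | None = None, seed: int | None = None) -> TraceSimulation:
    """Simulate reaction and control bead trajectories with ground truth.

    Reaction traces alternate synthesis ramps (length ~ Exp(processivity),
    slope a fresh Normal(rate_mean, rate_sd) draw, expressed in nm via
    1/calibration) with pause plateaus; cumulative synthesis is capped at
    the template length and a short terminal plateau is appended. All traces
    of the experiment share one smooth drift waveform (sum of 3 sinusoids)
    and carry independent white noise; controls have drift + noise only.

    Truth maps trace ids to segment/pause boundaries in both seconds and
    sample indices, per-segment true rates and lengths, and a ``capped``
    flag for the template-end-truncated segment.
    """
    params = params if params is not None else TraceSimParams()
    if seed is not None:
        params = TraceSimParams(**{**params.__dict__, "seed": seed})
    params.validate()
    rng = np.random.default_rng(params.seed)
    dt = params.sampling_interval

    schedules = [_draw_events(params, rng) for _ in range(params.n_reaction_traces)]
    total = max(ev[-1]["end_s"] for ev in schedules) + params.tail_duration
    time = np.arange(0.0, total, dt)

    # shared drift: smooth sum of 3 sinusoids, total amplitude <= drift_amplitude
    amp = params.drift_amplitude / 3.0 * rng.uniform(0.5, 1.0, size=3)
    period = rng.uniform(30.0, 120.0, size=3)
    phase = rng.uniform(0.0, 2 * np.pi, size=3)
    drift = np.sum(
        [a * np.sin(2 * np.pi * time / p + ph) for a, p, ph in zip(amp, period, phase)], axis=0
    )

    traces: list[Trace] = []
    truth: dict = {"traces": {}}
    for i, events in enumerate(schedules):
        tid = f"reaction_{i:03d}"
        bases = _eval_piecewise(events, time)
        noise = rng.normal(0.0, params.noise_sd, size=time.size) if params.noise_sd > 0 else 0.0
        ext_nm = bases / params.calibration + drift + noise
        traces.append(Trace(trace_id=tid, role="reaction", time=time, extension=ext_nm))
        seg_truth, pause_truth = [], []
        for ev in events:
            idx = np.flatnonzero((time >= ev["start_s"]) & (time < ev["end_s"]))
            rec = {
                "start_s": ev["start_s"],
                "end_s": ev["end_s"],
                "start_index": int(idx[0]) if idx.size else None,
                "end_index": int(idx[-1]) + 1 if idx.size else None,
            }
            if ev["kind"] == "segment":
                rec.update(rate=ev["rate"], length=ev["length"], capped=ev["capped"])
                seg_truth.append(rec)
            else:
                pause_truth.append(rec)
        # terminal plateau after template exhaustion behaves as a pause
        end_s = events[-1]["end_s"]
        idx = np.flatnonzero(time >= end_s)
        if idx.size:
            pause_truth.append(
                {
                    "start_s": end_s,
                    "end_s": float(time[-1] + dt),
                    "start_index": int(idx[0]),
                    "end_index": int(time.size),
                    "terminal": True,
                }
            )
        truth["traces"][tid] = {"segments": seg_truth, "pauses": pause_truth}

    for i in range(params.n_control_traces):
        tid = f"control_{i:03d}"
        offset = rng.uniform(0.0, 20.0)
        noise = rng.normal(0.0, params.noise_sd, size=time.size) if params.noise_sd > 0 else 0.0
        traces.append(
            Trace(trace_id=tid, role="control", time=time, extension=offset + drift + noise)
        )

    truth["rate_mean"] = params.rate_mean
    truth["processivity_mean"] = params.processivity_mean
    return TraceSimulation(traces=traces, truth=truth, params=params)


def simulate_bead_frames(
    true_positions: Sequence[tuple[float, float]],
    psf_sd: float = 2.0,
    amplitude: float = 1000.0,
    noise_sd: float = 0.0,
    frame_size: tuple[int, int] = (64, 64),
    seed: int = 0,
) -> np.ndarray:
    """Stack of camera frames, one 2-D Gaussian bead spot per frame.

    Returns an (n_frames, height, width) float array. Positions are (x, y)
    in pixels and must lie inside the frame.
    """
    if psf_sd <= 0:
        raise ValidationError("psf_sd", "must be > 0")
    ny, nx = frame_size
    rng = np.random.default_rng(seed)
    frames = []
    for x0, y0 in true_positions:
        if not (0 <= x0 < nx and 0 <= y0 < ny):
            raise ValidationError("true_positions", f"position ({x0}, {y0}) outside the frame")
        frame = gaussian_2d((ny, nx), x0, y0, psf_sd, amplitude)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames.append(frame)
    return np.stack(frames)


# ---------------------------------------------------------------------------
# Raman spectra
# ---------------------------------------------------------------------------


def simulate_raman(params: RamanSimParams | None = None, seed: int | None = None) -> RamanSimulation:
    """Spectrum = linear baseline + sum of pseudo-Voigt bands + white noise."""
    params = params if params is not None else RamanSimParams()
    if seed is not None:
        params = RamanSimParams(**{**params.__dict__, "seed": seed})
    params.validate()
    rng = np.random.default_rng(params.seed)
    grid = params.grid()
    intensity = params.baseline_intercept + params.baseline_slope * grid
    bands = []
    for c, w, a, m in zip(
        params.band_centers, params.band_widths, params.band_areas, params.mixing_fractions
    ):
        intensity = intensity + pseudo_voigt(grid, c, w, a, m)
        bands.append(Band(center=c, width=w, area=a, mixing=m))
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=grid.size)
    truth = {
        "bands": [
            {"center": b.center, "fwhm": b.width, "area": b.area, "mixing": b.mixing}
            for b in bands
        ],
        "baseline": {"slope": params.baseline_slope, "intercept": params.baseline_intercept},
    }
    return RamanSimulation(
        spectrum=Spectrum(wavenumber=grid, intensity=intensity),
        bands=bands,
        truth=truth,
        params=params,
    )


# ---------------------------------------------------------------------------
# SPR binding series
# ---------------------------------------------------------------------------


def simulate_binding(params: BindingSimParams | None = None, seed: int | None = None) -> BindingSimulation:
    """Equilibrium responses R(C) = Rmax*C/(Kd + C) with optional noise."""
    params = params if params is not None else BindingSimParams()
    if seed is not None:
        params = BindingSimParams(**{**params.__dict__, "seed": seed})
    params.validate()
    rng = np.random.default_rng(params.seed)
    conc = np.asarray(params.concentrations, dtype=float)
    response = params.rmax * conc / (params.kd + conc)
    if params.noise_relative > 0:
        response = response * (1.0 + rng.normal(0.0, params.noise_relative, size=conc.size))
    if params.noise_sd > 0:
        response = response + rng.normal(0.0, params.noise_sd, size=conc.size)
    series = BindingSeries(concentrations=conc, responses=response, label="synthetic")
    return BindingSimulation(
        series=series, truth={"kd_nM": params.kd, "rmax_RU": params.rmax}, params=params
    )


# ---------------------------------------------------------------------------
# Protein sequences with planted composition
# ---------------------------------------------------------------------------


def simulate_sequence(params: SequenceSimParams | None = None, seed: int | None = None) -> SequenceSimulation:
    """Sequence with planted charge composition and disorder layout.

    Acidic residue count is round(target * length); a fraction
    ``acidic_enrichment_in_disorder`` of them is placed (uniformly) inside
    the disordered segments, the rest outside, with D/E labels assigned in
    stratified halves so Asp and Glu individually realize the enrichment.
    Basic residues fill uniformly chosen remaining positions; all other
    positions draw uniformly from the 16 non-charged amino acids. The
    disorder track is >= 0.5 inside the segments and < 0.5 outside.
    """
    params = params if params is not None else SequenceSimParams()
    if seed is not None:
        params = SequenceSimParams(**{**params.__dict__, "seed": seed})
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.length

    in_disorder = np.zeros(n, dtype=bool)
    for start, end in params.disorder_segments:
        in_disorder[start - 1 : end] = True
    disorder_pos = np.flatnonzero(in_disorder)
    order_pos = np.flatnonzero(~in_disorder)

    n_acidic = int(round(params.target_acidic_fraction * n))
    n_basic = int(round(params.target_basic_fraction * n))
    n_acid_dis = min(int(round(params.acidic_enrichment_in_disorder * n_acidic)), disorder_pos.size)
    n_acid_ord = min(n_acidic - n_acid_dis, order_pos.size)

    acid_dis = rng.choice(disorder_pos, size=n_acid_dis, replace=False)
    acid_ord = rng.choice(order_pos, size=n_acid_ord, replace=False)

    # stratified D/E labels: half of each stratum is Asp, half Glu
    tags = np.empty(0, dtype="<U1")
    acid_positions = np.concatenate([acid_dis, acid_ord])
    labels = []
    for stratum in (acid_dis, acid_ord):
        half = stratum.size // 2
        lab = np.array(["D"] * half + ["E"] * (stratum.size - half))
        rng.shuffle(lab)
        labels.append(lab)
    tags = np.concatenate(labels) if labels else tags

    residues = np.empty(n, dtype="<U1")
    residues[:] = ""
    residues[acid_positions] = tags
    remaining = np.flatnonzero(residues == "")
    basic_positions = rng.choice(remaining, size=min(n_basic, remaining.size), replace=False)
    residues[basic_positions] = rng.choice(list(_BASIC), size=basic_positions.size)
    remaining = np.flatnonzero(residues == "")
    residues[remaining] = rng.choice(list(_NEUTRAL), size=remaining.size)

    probs = np.where(
        in_disorder, rng.uniform(0.6, 0.95, size=n), rng.uniform(0.05, 0.4, size=n)
    )
    record = SequenceRecord(id=f"synthetic_halophile_{params.seed}", residues="".join(residues))
    track = DisorderTrack(probabilities=probs)
    domains = [DomainAnnotation(name=d[0], start=d[1], end=d[2]) for d in params.domain_layout]
    truth = {
        "n_acidic": int(acid_positions.size),
        "n_basic": int(basic_positions.size),
        "acidic_positions": [
            {"position": int(p) + 1, "tag": str(t)} for p, t in zip(acid_positions, tags)
        ],
        "acidic_in_disorder_fraction": float(n_acid_dis / acid_positions.size)
        if acid_positions.size
        else None,
    }
    return SequenceSimulation(record=record, disorder=track, domains=domains, truth=truth, params=params)
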
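"""Single-molecule flow-stretching replication kinetics.

A polymerase extending a primer on a flow-stretched, bead-tethered ssDNA
template converts ssDNA to dsDNA and lengthens the tether. The bead position
signal (nm, sampled on a uniform grid) is therefore a piecewise record of
synthesis phases (DNA lengthening at the single-enzyme rate) separated by
pauses (no synthesis, e.g. polymerase exchange). This module implements the
full analysis chain:

1. :func:`localize_bead` — sub-pixel bead centroid from a 2-D Gaussian fit;
2. :func:`correct_drift` — subtract the shared flow drift measured on
   tethered but unreplicated control molecules;
3. :func:`to_bases` — convert nm of lengthening to synthesized nucleotides
   with the ssDNA/dsDNA calibration factor (3.76 b/nm at ~3 pN);
4. :func:`segment_trace` — pause detection with the 6-point / 3-sigma rule
   and tiling of each trace into pauses and synthesis segments;
5. :func:`fit_rate_distribution` / :func:`fit_processivity` — population
   estimates: Gaussian mean/sd of per-segment rates, exponential mean of
   segment lengths (optionally right-censored at the template end).

:func:`analyze_experiment` chains steps 2-5 for a set of reaction and
control traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, optimize

from .errors import LocalizationError, UnitError, ValidationError

__all__ = [
    "Trace",
    "SynthesisSegment",
    "ExtensionRise",
    "PauseEvent",
    "SegmentationResult",
    "RateEstimate",
    "ProcessivityEstimate",
    "localize_bead",
    "correct_drift",
    "to_bases",
    "estimate_noise_sd",
    "segment_trace",
    "fit_rate_distribution",
    "fit_processivity",
    "analyze_experiment",
    "DEFAULT_CALIBRATION",
]

#: ssDNA->dsDNA length conversion at the ~3 pN stretching force, bases per nm.
DEFAULT_CALIBRATION = 3.76


@dataclass
class Trace:
    """One bead-extension time series (reaction or control molecule).

    ``time`` must be a uniform, strictly increasing grid; ``unit`` tracks
    whether ``extension`` is in nm (raw) or bases (after calibration).
    """

    trace_id: str
    role: str  # "reaction" | "control"
    time: np.ndarray
    extension: np.ndarray
    unit: str = "nm"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.role not in ("reaction", "control"):
            raise ValidationError("role", f"must be 'reaction' or 'control', got {self.role!r}")
        if self.unit not in ("nm", "bases"):
            raise ValidationError("unit", f"must be 'nm' or 'bases', got {self.unit!r}")
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValidationError("time", "need a 1-D grid with at least 2 samples")
        if self.extension.shape != self.time.shape:
            raise ValidationError("extension", "length must match time grid")
        if not np.all(np.isfinite(self.extension)):
            raise ValidationError("extension", "values must be finite")
        steps = np.diff(self.time)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValidationError("time", "grid must be strictly increasing with constant step")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return self.time.size


@dataclass
class SynthesisSegment:
    """One DNA-lengthening phase: half-open sample interval [start, end).

    ``rate`` is the least-squares slope over the segment's samples (bases/s)
    and ``length`` the extension change across the phase (bases), measured
    plateau-to-plateau where flanking pauses exist (see ``segment_trace``).
    ``start_level``/``end_level`` are the extension levels the length was
    measured between; ``end_level`` lets a caller censor segments truncated
    by the template end.
    """

    start_index: int
    end_index: int
    rate: float
    length: float
    start_level: float = np.nan
    end_level: float = np.nan
    trace_id: str = ""


@dataclass
class ExtensionRise:
    """One synthesis event measured as the level step between the flanking
    pause plateaus (or trace ends). Unlike :class:`SynthesisSegment` this
    may span fewer than 3 samples — even zero, when the burst completed
    within one sampling interval — so it carries no slope."""

    start_index: int
    end_index: int
    length: float
    start_level: float
    end_level: float
    trace_id: str = ""


@dataclass
class PauseEvent:
    """A no-synthesis interval: >= ``min_pause_points`` samples whose total
    amplitude range stays below ``k_sd`` times the noise sd."""

    start_index: int
    end_index: int
    duration: float
    trace_id: str = ""


@dataclass
class SegmentationResult:
    """Pauses, rises and synthesis segments tiling one trace.

    ``rises`` is the length sample (every significant synthesis event);
    ``segments`` the subset with >= 3 samples that supports a slope (the
    rate sample). ``discarded`` holds the remaining gap intervals as
    (start, end, reason) tuples, so pauses + segments + discarded exactly
    tile [0, n) (short rises appear both in ``rises`` and, as intervals, in
    ``discarded``).
    """

    trace_id: str
    n_samples: int
    segments: list[SynthesisSegment] = field(default_factory=list)
    rises: list[ExtensionRise] = field(default_factory=list)
    pauses: list[PauseEvent] = field(default_factory=list)
    discarded: list[tuple[int, int, str]] = field(default_factory=list)
    noise_sd: float = np.nan


@dataclass
class RateEstimate:
    """Gaussian fit (MLE = sample mean/sd) of the per-segment rate sample."""

    mean: float
    sd: float
    n_segments: int
    fit_uncertainty: float


@dataclass
class ProcessivityEstimate:
    """Exponential mean of the segment-length sample (right-censorable MLE)."""

    mean: float
    fit_uncertainty: float
    n_segments: int
    n_censored: int = 0


# ---------------------------------------------------------------------------
# Bead localization
# ---------------------------------------------------------------------------


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def localize_bead(frame: np.ndarray) -> tuple[float, float]:
    """Sub-pixel bead centroid from a least-squares 2-D Gaussian fit.

    Free parameters: center (x, y), width sd, amplitude and flat offset.
    Returns (x, y) in pixel coordinates (x indexes columns).

    Raises
    ------
    LocalizationError
        If no spot rises above the frame's noise floor or the fit does not
        converge.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValidationError("frame", "expected a 2-D pixel array")
    ny, nx = frame.shape
    background = float(np.median(frame))
    noise = _robust_sd(frame - background)
    amp0 = float(frame.max() - background)
    # 5x the robust pixel noise: the maximum of ~4k noise pixels alone
    # reaches ~4 sigma, so 3 sigma would accept empty frames
    if amp0 <= 5.0 * noise or amp0 <= 0:
        raise LocalizationError("no spot above the noise floor")

    # initial centroid from the brightest pixel of a lightly smoothed frame
    # (robust to pixel noise, unlike whole-frame intensity moments)
    smoothed = ndimage.gaussian_filter(frame, sigma=1.5)
    y0, x0 = np.unravel_index(int(np.argmax(smoothed)), frame.shape)
    yy, xx = np.mgrid[0:ny, 0:nx]

    def residual(p):
        x, y, sd, amp, off = p
        model = off + amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sd**2))
        return (model - frame).ravel()

    p0 = [float(x0), float(y0), 2.0, amp0, background]
    fit = optimize.least_squares(
        residual,
        p0,
        bounds=([-1, -1, 0.5, 0.0, -np.inf], [nx, ny, max(nx, ny), np.inf, np.inf]),
    )
    if not fit.success:
        raise LocalizationError("2-D Gaussian fit did not converge")
    x, y, sd, amp, off = fit.x
    resid_sd = _robust_sd(fit.fun)
    if amp <= 5.0 * resid_sd:
        raise LocalizationError("fitted amplitude is below the residual noise floor")
    return float(x), float(y)


# ---------------------------------------------------------------------------
# Drift correction and calibration
# ---------------------------------------------------------------------------


def correct_drift(reaction: Sequence[Trace], controls: Sequence[Trace]) -> list[Trace]:
    """Subtract the shared flow drift measured on control molecules.

    Each control is first centered on its own mean, so subtracting the
    pointwise mean of the centered controls removes the common drift
    waveform without shifting the reaction traces' offsets.
    """
    reaction = list(reaction)
    controls = list(controls)
    if not controls:
        raise ValidationError("controls", "at least one control trace is required")
    grid = reaction[0].time if reaction else controls[0].time
    for t in [*reaction, *controls]:
        if t.time.shape != grid.shape or not np.allclose(t.time, grid, rtol=1e-9, atol=1e-9):
            raise ValidationError("time", f"trace {t.trace_id!r} is not on the common time grid")
    centered = np.stack([c.extension - c.extension.mean() for c in controls])
    drift = centered.mean(axis=0)
    return [replace(t, extension=t.extension - drift) for t in reaction]


def to_bases(trace: Trace, calibration: float = DEFAULT_CALIBRATION) -> Trace:
    """Convert a nm trace to synthesized bases with the b/nm calibration."""
    if calibration <= 0:
        raise ValidationError("calibration", "must be > 0")
    if trace.unit != "nm":
        raise UnitError(f"trace {trace.trace_id!r} is already in bases")
    return replace(trace, extension=trace.extension * calibration, unit="bases")


def estimate_noise_sd(trace: Trace | np.ndarray) -> float:
    """Robust per-trace noise sd from first differences.

    The MAD-scaled sd of the differenced signal, divided by sqrt(2), is
    insensitive to a constant slope (differencing turns it into a constant,
    removed by the median) and to rare jumps (down-weighted by the MAD).
    """
    x = trace.extension if isinstance(trace, Trace) else np.asarray(trace, dtype=float)
    if x.size < 20:
        raise ValidationError("trace", "need at least 20 samples to estimate noise")
    d = np.diff(x)
    return _robust_sd(d) / np.sqrt(2.0)


# ---------------------------------------------------------------------------
# Segmentation: the 6-point / 3-sigma pause rule
# ---------------------------------------------------------------------------


def _window_stat(windows: np.ndarray, stat: str) -> np.ndarray:
    if stat == "max_dev":
        return np.abs(windows - windows.mean(axis=1, keepdims=True)).max(axis=1)
    if stat == "range":
        return windows.max(axis=1) - windows.min(axis=1)
    raise ValidationError("stat", f"unknown window statistic {stat!r}")


def _pause_mask(x: np.ndarray, min_points: int, threshold: float, stat: str) -> np.ndarray:
    """Mark every sample covered by some window of ``min_points`` consecutive
    samples whose amplitude-fluctuation statistic is <= ``threshold``."""
    n = x.size
    mask = np.zeros(n, dtype=bool)
    if n < min_points:
        return mask
    windows = np.lib.stride_tricks.sliding_window_view(x, min_points)
    starts = np.flatnonzero(_window_stat(windows, stat) <= threshold)
    if starts.size:
        delta = np.zeros(n + 1, dtype=int)
        np.add.at(delta, starts, 1)
        np.add.at(delta, starts + min_points, -1)
        mask = np.cumsum(delta[:-1]) > 0
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def _split_run(
    x: np.ndarray, s: int, e: int, threshold: float, stat: str, min_points: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split a candidate pause run until each piece satisfies the fluctuation
    bound. Returns (kept pauses, dropped fragments shorter than
    ``min_points``).

    A contiguous marked run can straddle a synthesis step shorter than the
    sampling interval (two plateaus back to back); splitting at the largest
    interior jump separates the plateaus. Dropped fragments are plateau-like
    samples that no longer qualify as a pause; any gap containing them has
    an unreliable slope.
    """
    seg = x[s:e]
    if _window_stat(seg[None, :], stat)[0] <= threshold:
        return ([(s, e)], []) if e - s >= min_points else ([], [(s, e)])
    if e - s < 2:
        return [], [(s, e)]
    cut = s + 1 + int(np.argmax(np.abs(np.diff(seg))))
    kept, dropped = [], []
    for a, b in ((s, cut), (cut, e)):
        if b - a >= min_points:
            k, d = _split_run(x, a, b, threshold, stat, min_points)
            kept.extend(k)
            dropped.extend(d)
        elif b > a:
            dropped.append((a, b))
    return kept, dropped


def segment_trace(
    trace: Trace,
    noise_sd: float | None = None,
    min_pause_points: int = 6,
    k_sd: float = 3.0,
    stat: str = "max_dev",
) -> SegmentationResult:
    """Tile a drift-corrected trace (in bases) into pauses and rises.

    A pause is a maximal run of samples covered by windows of
    ``min_pause_points`` consecutive samples whose amplitude fluctuation —
    by default the maximum deviation from the window mean (``stat="range"``
    uses the total range instead) — stays within ``k_sd`` times the noise
    sd ("no change in the DNA length"). Candidate runs that straddle a
    level step larger than the threshold (a sub-sampling-interval synthesis
    burst between two plateaus) are split at the largest interior jump.

    Between consecutive pauses (and at the trace ends) the extension rise
    is measured between the mean plateau levels of the flanking pauses,
    which is insensitive to boundary samples caught mid-step; at trace ends
    the first/last sample stands in for the missing plateau. Rises above
    ``k_sd * noise_sd`` are synthesis events and enter the length sample
    (``rises``); those spanning >= 3 samples additionally get a
    least-squares slope and become ``segments`` (the rate sample). Gaps
    with no significant lengthening are recorded under ``discarded``.
    """
    if trace.unit != "bases":
        raise UnitError("segment_trace requires a trace converted to bases")
    if noise_sd is None:
        noise_sd = estimate_noise_sd(trace)
    if noise_sd < 0 or not np.isfinite(noise_sd):
        raise ValidationError("noise_sd", "must be a finite value >= 0")

    x = trace.extension
    n = x.size
    # tiny absolute epsilon so an exactly flat plateau is not rejected by
    # float rounding when noise_sd == 0 (threshold 0)
    threshold = k_sd * noise_sd + 1e-9 * max(1.0, float(np.max(np.abs(x))))
    mask = _pause_mask(x, min_pause_points, threshold, stat)
    pause_runs: list[tuple[int, int]] = []
    fragments: list[tuple[int, int]] = []
    for s, e in _runs(mask):
        kept, dropped = _split_run(x, s, e, threshold, stat, min_pause_points)
        pause_runs.extend(kept)
        fragments.extend(dropped)
    pause_runs.sort()

    result = SegmentationResult(trace_id=trace.trace_id, n_samples=n, noise_sd=noise_sd)
    dt = trace.dt
    for s, e in pause_runs:
        result.pauses.append(
            PauseEvent(start_index=s, end_index=e, duration=(e - s) * dt, trace_id=trace.trace_id)
        )
    levels = [float(x[s:e].mean()) for s, e in pause_runs]

    # gaps between consecutive pauses and at the trace ends (possibly empty)
    if not pause_runs:
        gaps = [(0, n, float(x[0]), float(x[n - 1]))]
    else:
        gaps = []
        first_s, _ = pause_runs[0]
        if first_s > 0:
            gaps.append((0, first_s, float(x[0]), levels[0]))
        for i in range(len(pause_runs) - 1):
            gaps.append((pause_runs[i][1], pause_runs[i + 1][0], levels[i], levels[i + 1]))
        last_e = pause_runs[-1][1]
        if last_e < n:
            gaps.append((last_e, n, levels[-1], float(x[n - 1])))

    for s, e, lv0, lv1 in gaps:
        length = lv1 - lv0
        if length <= threshold or length <= 0:
            if e > s:
                result.discarded.append((s, e, "no significant lengthening"))
            continue
        rise = ExtensionRise(
            start_index=s,
            end_index=e,
            length=length,
            start_level=lv0,
            end_level=lv1,
            trace_id=trace.trace_id,
        )
        result.rises.append(rise)
        has_fragment = any(fs < e and fe > s for fs, fe in fragments)
        if has_fragment:
            # plateau-like samples leaked into this gap; the slope would be
            # diluted by them, but the plateau-to-plateau rise is still valid
            result.discarded.append((s, e, "contains unresolved plateau fragment"))
        elif e - s >= 3:
            slope = float(np.polyfit(trace.time[s:e], x[s:e], 1)[0])
            result.segments.append(
                SynthesisSegment(
                    start_index=s,
                    end_index=e,
                    rate=slope,
                    length=length,
                    start_level=lv0,
                    end_level=lv1,
                    trace_id=trace.trace_id,
                )
            )
        else:
            result.discarded.append((s, e, "too short for a slope (length kept in rises)"))
    return result


# ---------------------------------------------------------------------------
# Population fits
# ---------------------------------------------------------------------------


def _as_array(values: Iterable, attr: str) -> np.ndarray:
    out = [getattr(v, attr) if hasattr(v, attr) else float(v) for v in values]
    return np.asarray(out, dtype=float)


def fit_rate_distribution(segments: Iterable[SynthesisSegment | float]) -> RateEstimate:
    """Gaussian fit of the per-segment rate sample.

    The maximum-likelihood Gaussian has the sample mean and (population) sd;
    the fit uncertainty on the mean is sd/sqrt(n).
    """
    rates = _as_array(segments, "rate")
    if rates.size < 2:
        raise ValidationError("segments", "need at least 2 segments to fit a rate distribution")
    mean = float(rates.mean())
    sd = float(rates.std(ddof=0))
    return RateEstimate(
        mean=mean, sd=sd, n_segments=rates.size, fit_uncertainty=sd / np.sqrt(rates.size)
    )


def fit_processivity(
    segments: Iterable[SynthesisSegment | float],
    censor_at: float | None = None,
    censor_margin: float = 50.0,
    truncation: float = 0.0,
) -> ProcessivityEstimate:
    """Exponential mean of segment lengths (single-exponential decay fit).

    Without censoring the MLE is the sample mean. With ``censor_at`` set to
    the template length (bases), segments whose ``end_level`` reaches within
    ``censor_margin`` of the template end are treated as right-censored —
    they contribute their observed length to the likelihood but not an
    observed event — giving the standard censored-exponential MLE
    sum(lengths) / n_uncensored.

    ``truncation`` is the minimum detectable segment length (the pipeline's
    rise filter, k_sd * noise_sd): detected lengths are then left-truncated
    draws, and by memorylessness each observed length is truncation +
    Exp(mean), so the MLE subtracts ``truncation`` per observation.
    """
    segs = list(segments)
    lengths = _as_array(segs, "length")
    if lengths.size < 2:
        raise ValidationError("segments", "need at least 2 segments to fit processivity")
    if np.any(lengths <= 0):
        raise ValidationError("segments", "segment lengths must be positive")
    if truncation < 0 or np.any(lengths < truncation):
        raise ValidationError("truncation", "must be >= 0 and below every observed length")
    if censor_at is None:
        censored = np.zeros(lengths.size, dtype=bool)
    else:
        ends = _as_array(segs, "end_level")
        censored = np.isfinite(ends) & (ends >= censor_at - censor_margin)
    n_obs = int((~censored).sum())
    if n_obs == 0:
        raise ValidationError("segments", "all segments are censored; cannot estimate the mean")
    mean = float((lengths - truncation).sum() / n_obs)
    return ProcessivityEstimate(
        mean=mean,
        fit_uncertainty=mean / np.sqrt(n_obs),
        n_segments=lengths.size,
        n_censored=int(censored.sum()),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def analyze_experiment(
    traces: Sequence[Trace],
    calibration: float = DEFAULT_CALIBRATION,
    min_pause_points: int = 6,
    k_sd: float = 3.0,
    noise_sd: float | None = None,
    censor_at: float | None = None,
) -> dict:
    """Run the full chain on a mixed set of reaction and control traces.

    Drift-corrects the reactions with the controls, converts to bases,
    segments every reaction trace and pools the segments into rate and
    processivity estimates. Unless ``noise_sd`` (bases) is given, the pause
    threshold uses the control traces' differenced-MAD noise estimate,
    inflated by sqrt(1 + 1/n_controls) for the variance added by subtracting
    the mean control, and scaled by the calibration.
    """
    reaction = [t for t in traces if t.role == "reaction"]
    controls = [t for t in traces if t.role == "control"]
    if not reaction:
        raise ValidationError("traces", "no reaction traces provided")
    corrected = correct_drift(reaction, controls)
    in_bases = [to_bases(t, calibration) for t in corrected]
    if noise_sd is None:
        per_control = [estimate_noise_sd(c) for c in controls]
        noise_sd = (
            float(np.mean(per_control)) * np.sqrt(1.0 + 1.0 / len(controls)) * calibration
        )
    segmentations = [
        segment_trace(t, noise_sd=noise_sd, min_pause_points=min_pause_points, k_sd=k_sd)
        for t in in_bases
    ]
    all_segments = [s for r in segmentations for s in r.segments]
    all_rises = [s for r in segmentations for s in r.rises]
    rate = fit_rate_distribution(all_segments)
    processivity = fit_processivity(all_rises, censor_at=censor_at, truncation=k_sd * noise_sd)
    return {
        "segmentations": segmentations,
        "rate": rate,
        "processivity": processivity,
        "noise_sd_bases": noise_sd,
        "n_segments": len(all_segments),
        "n_rises": len(all_rises),
    }
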
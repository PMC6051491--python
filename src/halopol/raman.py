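"""Raman band decomposition for protein secondary structure and Tyr state.

Two spectral windows carry the structural information used here:

* 1500-1800 cm^-1 — six pseudo-Voigt components at ~1550 (Trp indole), 1580
  (Ala+Gly), 1610 (Tyr/Trp/Phe), 1650 (alpha-helix), 1670 (random coil) and
  1680 cm^-1 (beta-sheet). The three structural band areas, normalised to
  their sum, give helix/coil/sheet percentages.
* 800-880 cm^-1 — the tyrosine Fermi doublet. The integrated-area ratio
  I850/I830 reports the hydrogen-bonding state of the phenolic OH:
  ~0.9-1.5 for a solvent-exposed Tyr, ~0.7-1.0 for a buried Tyr
  hydrogen-bonded to carboxylates.

Fits are nonlinear least squares (lmfit) of a linear baseline plus
pseudo-Voigt components — each a Lorentzian/Gaussian mix sharing center and
FWHM — with multi-start restarts against local minima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np
from lmfit.models import LinearModel, PseudoVoigtModel

from .errors import FitConvergenceError, UndefinedRatioError, ValidationError
from .lineshapes import pseudo_voigt

__all__ = [
    "Spectrum",
    "Band",
    "SecondaryStructure",
    "TyrDoublet",
    "fit_bands",
    "secondary_structure",
    "tyr_doublet",
    "mean_spectrum",
    "AMIDE_BAND_CENTERS",
    "BAND_ASSIGNMENTS",
]

#: Canonical six-band template for the 1500-1800 cm^-1 window.
AMIDE_BAND_CENTERS = (1550.0, 1580.0, 1610.0, 1650.0, 1670.0, 1680.0)
BAND_ASSIGNMENTS = (
    "Trp-indole",
    "Ala+Gly",
    "Tyr/Trp/Phe",
    "alpha-helix",
    "random-coil",
    "beta-sheet",
)
_STRUCTURAL = ("alpha-helix", "random-coil", "beta-sheet")


@dataclass
class Spectrum:
    """Raman intensity vs. wavenumber on a strictly increasing grid."""

    wavenumber: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.ndim != 1 or self.wavenumber.size < 3:
            raise ValidationError("wavenumber", "need a 1-D grid with >= 3 points")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValidationError("wavenumber", "grid must be strictly increasing")
        if self.intensity.shape != self.wavenumber.shape:
            raise ValidationError("intensity", "length must match the wavenumber grid")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensity", "values must be finite")

    def window(self, lo: float, hi: float) -> "Spectrum":
        sel = (self.wavenumber >= lo) & (self.wavenumber <= hi)
        return Spectrum(self.wavenumber[sel], self.intensity[sel])

    def covers(self, lo: float, hi: float, tol: float = 1.0) -> bool:
        return self.wavenumber.min() <= lo + tol and self.wavenumber.max() >= hi - tol


@dataclass
class Band:
    """One pseudo-Voigt component: ``mixing`` is the Lorentzian weight and
    ``width`` the FWHM shared by both component shapes."""

    center: float
    width: float
    area: float
    mixing: float
    assignment: str = ""
    area_stderr: float = np.nan

    def __post_init__(self):
        if self.width <= 0:
            raise ValidationError("width", "must be > 0")
        if self.area < 0:
            raise ValidationError("area", "must be >= 0")
        if not 0 <= self.mixing <= 1:
            raise ValidationError("mixing", "must be in [0, 1]")


@dataclass
class SecondaryStructure:
    alpha_pct: float
    coil_pct: float
    beta_pct: float
    alpha_unc: float = np.nan
    coil_unc: float = np.nan
    beta_unc: float = np.nan


@dataclass
class TyrDoublet:
    i850: float
    i830: float
    ratio: float
    classification: str


def _multistart_fit(model, params, x, y, n_restarts: int, jitter):
    """Run lmfit from the template and jittered restarts; best chisqr wins."""
    rng = np.random.default_rng(12345)
    best = None
    for k in range(n_restarts):
        p = params if k == 0 else jitter(params.copy(), rng)
        try:
            res = model.fit(y, p, x=x)
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise FitConvergenceError(
            "band fit failed to converge in all restarts",
            diagnostics={"n_restarts": n_restarts, "n_points": x.size},
        )
    return best


def fit_bands(
    spectrum: Spectrum,
    template: Sequence[Band] | None = None,
    region: tuple[float, float] = (1500.0, 1800.0),
    n_restarts: int = 5,
    share_mixing: bool = True,
    center_restraint: float = 0.5,
) -> tuple[list[Band], float]:
    """Decompose the 1500-1800 cm^-1 window into six pseudo-Voigt bands.

    ``template`` supplies initial guesses (default: the canonical six-band
    layout with areas estimated from the integrated intensity). Centers are
    bounded within +/-10 cm^-1 of the template, FWHM within [5, 60] cm^-1,
    mixing in [0, 1], areas >= 0; a linear baseline is co-fitted. Five
    jittered restarts guard against local minima.

    Two numerical choices stabilise the notoriously ill-conditioned
    decomposition of the overlapping 1650/1670/1680 bands (10 cm^-1 apart
    at FWHM ~15-20 cm^-1):

    * one Gauss/Lorentz fraction shared by all components
      (``share_mixing``), the usual constraint in amide deconvolution —
      per-band free fractions let neighbours trade tail mass;
    * a quadratic restraint pulling each center to its template position
      with scale ``center_restraint`` (cm^-1), weighted by the estimated
      spectral noise. With free centers the Cramer-Rao floor on the
      structural area fractions is several percentage points at ~1% noise;
      the restraint removes that degeneracy while still allowing genuine
      shifts of a few cm^-1 (and is inactive on noiseless data).

    Returns the converged bands sorted by center (labelled with the
    canonical assignments) and the data-residual 2-norm.
    """
    lo, hi = region
    if not spectrum.covers(lo, hi):
        raise ValidationError("spectrum", f"grid must cover {lo:.0f}-{hi:.0f} cm^-1")
    win = spectrum.window(lo, hi)
    x, y = win.wavenumber, win.intensity

    if template is None:
        total = float(np.trapezoid(np.clip(y - y.min(), 0, None), x))
        template = [
            Band(center=c, width=18.0, area=max(total / 6.0, 1e-6), mixing=0.5)
            for c in AMIDE_BAND_CENTERS
        ]
    if len(template) != 6:
        raise ValidationError("template", "exactly 6 template bands are required")

    # high-frequency noise estimate from second differences (slope-free)
    noise = 1.4826 * float(np.median(np.abs(np.diff(y, 2)))) / np.sqrt(6.0)
    penalty_w = noise / center_restraint

    params = lmfit.Parameters()
    slope = (y[-1] - y[0]) / (x[-1] - x[0])
    params.add("bl_slope", value=slope)
    params.add("bl_intercept", value=float(y.min() - slope * x[0]))
    for i, b in enumerate(template):
        params.add(f"p{i}_center", value=b.center, min=b.center - 10.0, max=b.center + 10.0)
        params.add(f"p{i}_fwhm", value=b.width, min=5.0, max=60.0)
        params.add(f"p{i}_amplitude", value=b.area, min=0.0)
        if share_mixing and i > 0:
            params.add(f"p{i}_fraction", expr="p0_fraction")
        else:
            params.add(f"p{i}_fraction", value=b.mixing, min=0.0, max=1.0)

    centers0 = np.array([b.center for b in template])

    def _eval(p) -> np.ndarray:
        out = p["bl_slope"] * x + p["bl_intercept"]
        for i in range(6):
            out = out + pseudo_voigt(
                x, p[f"p{i}_center"].value, p[f"p{i}_fwhm"].value,
                p[f"p{i}_amplitude"].value, p[f"p{i}_fraction"].value,
            )
        return out

    def objective(p):
        data_resid = _eval(p) - y
        center_pen = penalty_w * (
            np.array([p[f"p{i}_center"].value for i in range(6)]) - centers0
        )
        return np.concatenate([data_resid, center_pen])

    rng = np.random.default_rng(12345)
    best = None
    for k in range(n_restarts):
        p = params.copy()
        if k > 0:
            for i in range(6):
                p[f"p{i}_amplitude"].set(value=p[f"p{i}_amplitude"].value * rng.uniform(0.7, 1.3))
                p[f"p{i}_fwhm"].set(
                    value=float(np.clip(p[f"p{i}_fwhm"].value * rng.uniform(0.8, 1.25), 5.1, 59.9))
                )
        try:
            res = lmfit.minimize(objective, p, method="leastsq")
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise FitConvergenceError(
            "band fit failed to converge in all restarts",
            diagnostics={"n_restarts": n_restarts, "n_points": x.size},
        )

    bands = []
    for i in range(6):
        stderr = best.params[f"p{i}_amplitude"].stderr
        bands.append(
            Band(
                center=float(best.params[f"p{i}_center"].value),
                width=float(best.params[f"p{i}_fwhm"].value),
                area=float(best.params[f"p{i}_amplitude"].value),
                mixing=float(best.params[f"p{i}_fraction"].value),
                area_stderr=float(stderr) if stderr is not None else np.nan,
            )
        )
    bands.sort(key=lambda b: b.center)
    for b, label in zip(bands, BAND_ASSIGNMENTS):
        b.assignment = label
    data_resid = _eval(best.params) - y
    return bands, float(np.linalg.norm(data_resid))


def secondary_structure(bands: Sequence[Band]) -> SecondaryStructure:
    """Helix/coil/sheet percentages from the three structural band areas.

    Each percentage is that band's area over the sum of the three
    structural areas (side-chain bands excluded from the normalisation).
    Uncertainties propagate the per-band area standard errors where the fit
    provided them.
    """
    by_label = {b.assignment: b for b in bands}
    missing = [lab for lab in _STRUCTURAL if lab not in by_label]
    if missing:
        raise ValidationError("bands", f"missing structural assignments: {missing}")
    areas = np.array([by_label[lab].area for lab in _STRUCTURAL])
    errs = np.array([by_label[lab].area_stderr for lab in _STRUCTURAL])
    total = areas.sum()
    if total <= 0:
        raise ValidationError("bands", "structural band areas sum to zero")
    pct = areas / total * 100.0
    if np.all(np.isfinite(errs)):
        # d(a_i/S)/da_j -> first-order propagation, ignoring covariances
        unc = np.empty(3)
        for i in range(3):
            grads = np.array([-areas[i] / total**2] * 3)
            grads[i] += 1.0 / total
            unc[i] = np.sqrt(np.sum((grads * errs) ** 2)) * 100.0
    else:
        unc = np.full(3, np.nan)
    return SecondaryStructure(
        alpha_pct=float(pct[0]),
        coil_pct=float(pct[1]),
        beta_pct=float(pct[2]),
        alpha_unc=float(unc[0]),
        coil_unc=float(unc[1]),
        beta_unc=float(unc[2]),
    )


def tyr_doublet(
    spectrum: Spectrum, region: tuple[float, float] = (800.0, 880.0), n_restarts: int = 5
) -> TyrDoublet:
    """Integrated-area ratio I850/I830 of the tyrosine Fermi doublet.

    Two pseudo-Voigt peaks (centers bounded 830+/-8 and 850+/-8 cm^-1) and a
    linear baseline are fitted over 800-880 cm^-1. Classification: ratio in
    (1.0, 1.5] -> "exposed" (solvent H-bonded OH), [0.7, 0.9) -> "buried"
    (H-bonded to Asp/Glu), [0.9, 1.0] where the literature ranges overlap ->
    "ambiguous", as is anything outside [0.7, 1.5].
    """
    lo, hi = region
    if not spectrum.covers(lo, hi):
        raise ValidationError("spectrum", f"grid must cover {lo:.0f}-{hi:.0f} cm^-1")
    win = spectrum.window(lo, hi)
    x, y = win.wavenumber, win.intensity

    model = LinearModel(prefix="bl_") + PseudoVoigtModel(prefix="a_") + PseudoVoigtModel(prefix="b_")
    params = model.make_params()
    total = float(np.trapezoid(np.clip(y - y.min(), 0, None), x))
    params["bl_slope"].set(value=(y[-1] - y[0]) / (x[-1] - x[0]))
    params["bl_intercept"].set(value=float(y.min()))
    for prefix, center in (("a_", 830.0), ("b_", 850.0)):
        params[f"{prefix}center"].set(value=center, min=center - 8.0, max=center + 8.0)
        params[f"{prefix}sigma"].set(value=5.0, min=1.5, max=25.0)
        params[f"{prefix}fraction"].set(value=0.5, min=0.0, max=1.0)
        params[f"{prefix}amplitude"].set(value=max(total / 2.0, 1e-9), min=0.0)

    def jitter(p, rng):
        for prefix in ("a_", "b_"):
            p[f"{prefix}amplitude"].set(value=p[f"{prefix}amplitude"].value * rng.uniform(0.6, 1.4))
            p[f"{prefix}sigma"].set(value=float(np.clip(p[f"{prefix}sigma"].value * rng.uniform(0.7, 1.4), 1.6, 24.9)))
        return p

    res = _multistart_fit(model, params, x, y, n_restarts, jitter)
    i830 = float(res.params["a_amplitude"].value)
    i850 = float(res.params["b_amplitude"].value)
    if i830 <= 1e-9 * max(i850, 1.0):
        raise UndefinedRatioError("830 cm^-1 band area is ~0; I850/I830 undefined")
    ratio = i850 / i830
    if 1.0 < ratio <= 1.5:
        classification = "exposed"
    elif 0.7 <= ratio < 0.9:
        classification = "buried"
    else:
        # 0.9-1.0 is where the exposed and buried literature ranges overlap;
        # anything outside 0.7-1.5 is also not classifiable
        classification = "ambiguous"
    return TyrDoublet(i850=i850, i830=i830, ratio=ratio, classification=classification)


def mean_spectrum(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra sharing one grid."""
    if not spectra:
        raise ValidationError("spectra", "need at least one spectrum")
    grid = spectra[0].wavenumber
    for s in spectra[1:]:
        if s.wavenumber.shape != grid.shape or not np.allclose(s.wavenumber, grid):
            raise ValidationError("spectra", "replicates must share one wavenumber grid")
    return Spectrum(grid, np.mean([s.intensity for s in spectra], axis=0))
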
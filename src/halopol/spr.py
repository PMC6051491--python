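"""Steady-state SPR affinity estimation.

The equilibrium response of a 1:1 interaction follows the Langmuir isotherm
R(C) = Rmax * C / (Kd + C); fitting the maximum response reached at each
analyte concentration yields the equilibrium dissociation constant Kd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ValidationError

__all__ = ["BindingSeries", "AffinityEstimate", "subtract_reference", "steady_state_fit"]

#: Default upper bound on Rmax (RU); immobilization levels are chosen so the
#: maximum protein response stays below this.
DEFAULT_RMAX_BOUND = 500.0


@dataclass
class BindingSeries:
    """Equilibrium responses (RU) vs. analyte concentration (nM)."""

    concentrations: np.ndarray
    responses: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.ndim != 1 or self.concentrations.size < 1:
            raise ValidationError("concentrations", "need a non-empty 1-D array")
        if self.responses.shape != self.concentrations.shape:
            raise ValidationError("responses", "length must match concentrations")
        if np.any(self.concentrations <= 0):
            raise ValidationError("concentrations", "must be positive")
        if not np.all(np.isfinite(self.responses)):
            raise ValidationError("responses", "values must be finite")


@dataclass
class AffinityEstimate:
    kd: float  # nM
    rmax: float  # RU
    kd_uncertainty: float  # nM, from the fit covariance
    converged: bool
    diagnostics: str = ""


def subtract_reference(raw: BindingSeries, reference: BindingSeries) -> BindingSeries:
    """Pointwise reference-cell subtraction (bulk shift / nonspecific signal)."""
    if raw.concentrations.shape != reference.concentrations.shape or not np.allclose(
        raw.concentrations, reference.concentrations
    ):
        raise ValidationError("reference", "concentration ladders do not match")
    return BindingSeries(
        concentrations=raw.concentrations,
        responses=raw.responses - reference.responses,
        label=raw.label,
    )


def _langmuir(c, rmax, kd):
    return rmax * c / (kd + c)


def steady_state_fit(
    series: BindingSeries,
    rmax_bound: float = DEFAULT_RMAX_BOUND,
    relative_weights: bool = False,
) -> AffinityEstimate:
    """Least-squares Langmuir fit of an equilibrium series.

    Unweighted by default; ``relative_weights`` weights residuals by 1/R for
    percent-of-signal noise. The fit is flagged non-converged when the Kd
    estimate exceeds 10x the top concentration (the series does not
    approach saturation, so Kd is not identified).
    """
    c = series.concentrations
    r = series.responses
    if np.unique(c).size < 4:
        raise ValidationError("series", "need >= 4 distinct concentrations")
    top = float(c.max())
    rmax0 = min(float(r.max()) * 1.2 if r.max() > 0 else 1.0, rmax_bound * 0.98)
    half = rmax0 / 2.0
    above = c[r >= half]
    kd0 = float(above.min()) if above.size else top
    sigma = np.clip(np.abs(r), 1e-6, None) if relative_weights else None
    try:
        popt, pcov = optimize.curve_fit(
            _langmuir,
            c,
            r,
            p0=[rmax0, kd0],
            sigma=sigma,
            bounds=([0.0, 1e-12], [rmax_bound, np.inf]),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except RuntimeError as exc:
        return AffinityEstimate(
            kd=np.nan, rmax=np.nan, kd_uncertainty=np.nan, converged=False, diagnostics=str(exc)
        )
    rmax, kd = float(popt[0]), float(popt[1])
    kd_unc = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    if kd > 10.0 * top * (1.0 + 1e-9):  # slack so Kd == 10*Cmax exactly still converges
        return AffinityEstimate(
            kd=kd,
            rmax=rmax,
            kd_uncertainty=kd_unc,
            converged=False,
            diagnostics=f"non-saturating data: Kd estimate {kd:.3g} nM exceeds 10x the top concentration {top:.3g} nM",
        )
    return AffinityEstimate(kd=kd, rmax=rmax, kd_uncertainty=kd_unc, converged=True)
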
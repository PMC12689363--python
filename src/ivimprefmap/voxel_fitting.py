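"""Per-voxel parameter estimation.

Two estimators operate on a single voxel's signal-vs-b decay:

``fit_adc``
    Mono-exponential nonlinear least squares on the linear signal scale,
    restricted to b >= b_min.  With b_min = 0 this yields ADC_b0; with
    b_min = 150 s/mm² (perfusion-suppressed) it yields ADC_b150.

``fit_ivim_segmented``
    The segmented bi-exponential fit.  For each candidate cut-off b*:
    a log-linear fit on b >= b* estimates the tissue diffusivity D and
    extrapolated intercept A; the perfusion fraction follows as
    f = 1 - A/S(0) (clamped to [0, 0.999], negatives to 0); with S0
    pinned to the measured S(0) and (f, D) held fixed, a bounded
    one-dimensional least squares over all b estimates the
    pseudo-diffusion coefficient D*.  The cut-off whose full bi-exponential
    has the lowest sum of squared residuals over ALL b-values wins, ties
    going to the lower cut-off.

Sums of squared residuals for model comparison are always evaluated over
the full b-value set on the linear signal scale so both models see
identical data.  Voxels with nonpositive signal anywhere in the fitted
subset are flagged invalid rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .dwi_io import AcquisitionScheme, DwiVolume, RoiMask
from .signal_models import FREE_WATER_D, UNIT_SCALE, AdcParams, IvimParams

__all__ = [
    "FitConfig",
    "AdcFit",
    "IvimFit",
    "ParameterMaps",
    "fit_adc",
    "fit_ivim_segmented",
    "fit_volume",
]


@dataclass(frozen=True)
class FitConfig:
    """Fitting knobs shared by all voxels.

    cutoff_candidates : candidate segmented-fit cut-offs b*, s/mm².
    dstar_bounds      : search interval for D*, µm²/ms.
    d_bounds          : clamp interval for D, µm²/ms.
    adc150_threshold  : minimum b for the perfusion-suppressed ADC fit.
    ssr_floor_rel     : relative per-point noise proxy used to floor SSR
                        before the AICc logarithm (see model_selection).
    count_noise_param : if True, add 1 to each model's parameter count k.
    """

    cutoff_candidates: tuple = (100.0, 150.0, 300.0)
    dstar_bounds: tuple = (3.0, 100.0)
    d_bounds: tuple = (1e-3, FREE_WATER_D)
    adc150_threshold: float = 150.0
    ssr_floor_rel: float = 1e-6
    count_noise_param: bool = False

    def __post_init__(self):
        lo, hi = self.dstar_bounds
        if not (0 < lo < hi):
            raise ValueError("dstar_bounds must be positive and ordered")
        lo, hi = self.d_bounds
        if not (0 < lo < hi):
            raise ValueError("d_bounds must be positive and ordered")
        if not self.cutoff_candidates:
            raise ValueError("at least one cutoff candidate required")

    def validate_for_scheme(self, scheme: AcquisitionScheme) -> None:
        b = scheme.b
        for c in self.cutoff_candidates:
            if (b >= c).sum() < 3 or (b < c).sum() < 3:
                raise ValueError(
                    f"cutoff {c} leaves fewer than 3 points on one side of "
                    f"the scheme {scheme.bvalues}"
                )


@dataclass
class AdcFit:
    """Mono-exponential fit result for one voxel."""

    params: Optional[AdcParams]
    ssr: float
    n_points: int
    b_min: float
    valid: bool = True
    n_params: int = 2


@dataclass
class IvimFit:
    """Segmented bi-exponential fit result for one voxel."""

    params: Optional[IvimParams]
    ssr: float
    cutoff: float
    per_cutoff_ssr: dict = field(default_factory=dict)
    valid: bool = True
    f_clamped: bool = False
    n_params: int = 4


def _adc_model(b, s0, adc):
    return s0 * np.exp(-b * adc * UNIT_SCALE)


def fit_adc(decay, scheme: AcquisitionScheme, b_min: float = 0.0) -> AdcFit:
    """Nonlinear mono-exponential least squares on b >= b_min.

    Initialised from the closed-form log-linear solution; SSR is computed
    over the fitted subset.  Returns an invalid (flagged) fit if fewer
    than 3 usable points remain or any selected signal is nonpositive.
    """
    decay = np.asarray(decay, dtype=float)
    b = scheme.b
    sel = b >= b_min
    bs, ys = b[sel], decay[sel]
    if len(bs) < 3 or np.any(ys <= 0) or not np.all(np.isfinite(ys)):
        return AdcFit(None, np.nan, int(len(bs)), b_min, valid=False)
    # log-linear start: ln S = ln S0 - b * ADC * 1e-3
    slope, intercept = np.polyfit(bs, np.log(ys), 1)
    adc0 = max(-slope / UNIT_SCALE, 0.0)
    s00 = float(np.exp(intercept))
    try:
        popt, _ = curve_fit(
            _adc_model,
            bs,
            ys,
            p0=[s00, adc0],
            bounds=([1e-12, 0.0], [np.inf, np.inf]),
            maxfev=500,
        )
    except RuntimeError:
        popt = [s00, adc0]
    s0_hat, adc_hat = float(popt[0]), float(popt[1])
    ssr = float(np.sum((ys - _adc_model(bs, s0_hat, adc_hat)) ** 2))
    return AdcFit(AdcParams(s0_hat, adc_hat), ssr, int(len(bs)), b_min)


def _biexp(b, s0, f, d, dstar):
    return s0 * (f * np.exp(-b * dstar * UNIT_SCALE)
                 + (1.0 - f) * np.exp(-b * d * UNIT_SCALE))


def fit_ivim_segmented(
    decay, scheme: AcquisitionScheme, config: FitConfig = FitConfig()
) -> IvimFit:
    """Segmented IVIM fit with cut-off sweep and SSR-based selection."""
    decay = np.asarray(decay, dtype=float)
    b = scheme.b
    s0_meas = float(decay[0]) if b[0] == 0 else float(decay[np.argmin(b)])
    if (
        s0_meas <= 0
        or np.any(decay <= 0)
        or not np.all(np.isfinite(decay))
    ):
        return IvimFit(None, np.nan, np.nan, valid=False)

    best = None
    per_cutoff_ssr: dict = {}
    any_clamped = False
    d_lo, d_hi = config.d_bounds
    for cutoff in sorted(config.cutoff_candidates):
        sel = b >= cutoff
        if sel.sum() < 3:
            continue
        bs, ys = b[sel], decay[sel]
        slope, intercept = np.polyfit(bs, np.log(ys), 1)
        d_hat = float(np.clip(-slope / UNIT_SCALE, d_lo, d_hi))
        a_hat = float(np.exp(intercept))
        f_hat = 1.0 - a_hat / s0_meas
        clamped = f_hat < 0 or f_hat > 0.999
        f_hat = float(np.clip(f_hat, 0.0, 0.999))
        # 1-D bounded least squares over D*, everything else pinned
        ds_lo = max(config.dstar_bounds[0], d_hat * (1.0 + 1e-6))
        ds_hi = config.dstar_bounds[1]
        if f_hat > 0 and ds_lo < ds_hi:
            res = minimize_scalar(
                lambda ds: float(
                    np.sum((decay - _biexp(b, s0_meas, f_hat, d_hat, ds)) ** 2)
                ),
                bounds=(ds_lo, ds_hi),
                method="bounded",
            )
            dstar_hat = float(res.x)
        else:
            dstar_hat = ds_hi  # unused: fast compartment absent
        ssr = float(
            np.sum((decay - _biexp(b, s0_meas, f_hat, d_hat, dstar_hat)) ** 2)
        )
        per_cutoff_ssr[float(cutoff)] = ssr
        # strict < keeps the lower cutoff on ties (candidates ascend)
        if best is None or ssr < best[0]:
            best = (ssr, float(cutoff), f_hat, d_hat, dstar_hat, clamped)
            any_clamped = clamped

    if best is None:
        return IvimFit(None, np.nan, np.nan, valid=False)
    ssr, cutoff, f_hat, d_hat, dstar_hat, _ = best
    params = IvimParams(S0=s0_meas, f=f_hat, D=d_hat, Dstar=dstar_hat)
    return IvimFit(
        params, ssr, cutoff, per_cutoff_ssr, f_clamped=any_clamped
    )


@dataclass
class ParameterMaps:
    """Voxel-wise parameter maps plus the bookkeeping model_selection needs.

    All arrays share the DWI grid shape.  ``validity`` is 1 where both the
    ADC_b0 and segmented IVIM fits succeeded, else 0; parameter values in
    invalid voxels are NaN.
    """

    D: np.ndarray
    f: np.ndarray
    Dstar: np.ndarray
    ADC_b0: np.ndarray
    ADC_b150: np.ndarray
    S0: np.ndarray
    ssr_adc: np.ndarray
    ssr_ivim: np.ndarray
    validity: np.ndarray
    n_b: int
    config: FitConfig
    n_clamped_f: int = 0

    @property
    def grid_shape(self):
        return self.D.shape

    def as_dict(self):
        return {
            "D": self.D,
            "f": self.f,
            "Dstar": self.Dstar,
            "ADC_b0": self.ADC_b0,
            "ADC_b150": self.ADC_b150,
            "validity": self.validity,
        }


def fit_volume(
    dwi: DwiVolume,
    config: FitConfig = FitConfig(),
    mask: Optional[RoiMask] = None,
) -> ParameterMaps:
    """Fit ADC_b0, ADC_b150 and the segmented IVIM model at every (in-mask)
    voxel of a 4D volume, returning dense parameter maps.

    Out-of-mask voxels are left invalid (code 0, NaN parameters).
    """
    config.validate_for_scheme(dwi.scheme)
    shape = dwi.grid_shape
    nan = lambda: np.full(shape, np.nan)
    maps = ParameterMaps(
        D=nan(), f=nan(), Dstar=nan(), ADC_b0=nan(), ADC_b150=nan(),
        S0=nan(), ssr_adc=nan(), ssr_ivim=nan(),
        validity=np.zeros(shape, dtype=np.int16),
        n_b=len(dwi.scheme), config=config,
    )
    if mask is not None:
        in_mask = mask.labels > 0
    else:
        in_mask = np.ones(shape, dtype=bool)
    n_clamped = 0
    for idx in np.argwhere(in_mask):
        i, j, k = idx
        decay = dwi.signal[i, j, k, :]
        adc0 = fit_adc(decay, dwi.scheme, b_min=0.0)
        adc150 = fit_adc(decay, dwi.scheme, b_min=config.adc150_threshold)
        ivim = fit_ivim_segmented(decay, dwi.scheme, config)
        if not (adc0.valid and ivim.valid):
            continue
        maps.validity[i, j, k] = 1
        maps.D[i, j, k] = ivim.params.D
        maps.f[i, j, k] = ivim.params.f
        maps.Dstar[i, j, k] = ivim.params.Dstar
        maps.S0[i, j, k] = ivim.params.S0
        maps.ADC_b0[i, j, k] = adc0.params.ADC
        if adc150.valid:
            maps.ADC_b150[i, j, k] = adc150.params.ADC
        maps.ssr_adc[i, j, k] = adc0.ssr
        maps.ssr_ivim[i, j, k] = ivim.ssr
        if ivim.f_clamped:
            n_clamped += 1
    maps.n_clamped_f = n_clamped
    return maps
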
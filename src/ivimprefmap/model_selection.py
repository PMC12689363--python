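"""Corrected Akaike information criterion (AICc) per voxel, model
preference maps, and the p_IVIM biomarker.

For a least-squares fit with Gaussian errors,

    AICc = n ln(SSR / n) + 2k + 2k(k + 1) / (n - k - 1)

where n is the number of data points (b-values), k the number of
estimated parameters (2 for the mono-exponential, 4 for the segmented
bi-exponential; an optional convention adds one for the noise variance)
and SSR the sum of squared residuals evaluated over the same n points
for both models.  The model with the strictly lower AICc is preferred;
an exact tie goes to the simpler (ADC) model.

p_IVIM is the fraction of valid voxels in a region where the IVIM model
is preferred — invalid voxels are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

import numpy as np

from .dwi_io import DwiVolume, RoiMask
from .voxel_fitting import AdcFit, FitConfig, IvimFit, ParameterMaps

__all__ = [
    "PreferenceCode",
    "ModelComparison",
    "PreferenceMap",
    "aicc",
    "compare_voxel",
    "build_preference_map",
    "p_ivim",
]


class PreferenceCode(IntEnum):
    INVALID = 0
    ADC = 1
    IVIM = 2


@dataclass(frozen=True)
class ModelComparison:
    aicc_adc: float
    aicc_ivim: float
    preferred: PreferenceCode

    @property
    def delta(self) -> float:
        return self.aicc_adc - self.aicc_ivim


def aicc(ssr: float, n: int, k: int, ssr_floor: float = 0.0) -> float:
    """Corrected Akaike information criterion for a least-squares fit.

    ``ssr_floor`` (same units as ssr) is applied before the logarithm so
    that noiseless/perfect fits yield a finite value rather than -inf.
    Raises when n <= k + 1, where the small-sample correction term is
    undefined.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    if ssr < 0:
        raise ValueError(f"ssr must be >= 0, got {ssr}")
    ssr = max(float(ssr), float(ssr_floor))
    if ssr <= 0:
        raise ValueError("ssr is zero and no positive floor was given")
    return n * np.log(ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def compare_voxel(
    adc_fit: AdcFit,
    ivim_fit: IvimFit,
    n: int,
    config: FitConfig = FitConfig(),
) -> Optional[ModelComparison]:
    """AICc comparison of the full-b ADC fit against the segmented IVIM fit.

    Both SSRs must have been computed over the same ``n`` b-values.  The
    SSR floor is n * (ssr_floor_rel * S0)², a per-point relative noise
    proxy; when both models floor, the tie rule prefers ADC (parsimony).
    Returns None (preference code 0) when either fit is invalid.
    """
    if not (adc_fit.valid and ivim_fit.valid):
        return None
    if adc_fit.b_min != 0:
        raise ValueError("model comparison requires the ADC_b0 fit (b_min=0)")
    s0 = ivim_fit.params.S0
    floor = n * (config.ssr_floor_rel * s0) ** 2
    extra = 1 if config.count_noise_param else 0
    a_adc = aicc(adc_fit.ssr, n, adc_fit.n_params + extra, floor)
    a_ivim = aicc(ivim_fit.ssr, n, ivim_fit.n_params + extra, floor)
    preferred = (
        PreferenceCode.IVIM if a_ivim < a_adc else PreferenceCode.ADC
    )
    return ModelComparison(a_adc, a_ivim, preferred)


@dataclass
class PreferenceMap:
    """3D map of per-voxel model preference codes (0/1/2)."""

    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if not np.isin(self.codes, [0, 1, 2]).all():
            raise ValueError("preference codes must be in {0, 1, 2}")

    @property
    def n_valid(self) -> int:
        return int((self.codes != 0).sum())


def build_preference_map(
    maps: ParameterMaps, mask: Optional[RoiMask] = None
) -> PreferenceMap:
    """Voxel-wise AICc preference from fitted parameter maps.

    Works array-wise on the SSR maps produced by ``fit_volume``; invalid
    voxels (and out-of-mask voxels, if a mask is given) get code 0.
    """
    cfg = maps.config
    n = maps.n_b
    k_adc = 2 + (1 if cfg.count_noise_param else 0)
    k_ivim = 4 + (1 if cfg.count_noise_param else 0)
    valid = maps.validity > 0
    if mask is not None:
        valid = valid & (mask.labels > 0)
    codes = np.zeros(maps.grid_shape, dtype=np.int16)
    if valid.any():
        floor = n * (cfg.ssr_floor_rel * maps.S0[valid]) ** 2
        ssr_a = np.maximum(maps.ssr_adc[valid], floor)
        ssr_i = np.maximum(maps.ssr_ivim[valid], floor)
        pen_adc = 2 * k_adc + 2 * k_adc * (k_adc + 1) / (n - k_adc - 1)
        pen_ivim = 2 * k_ivim + 2 * k_ivim * (k_ivim + 1) / (n - k_ivim - 1)
        a_adc = n * np.log(ssr_a / n) + pen_adc
        a_ivim = n * np.log(ssr_i / n) + pen_ivim
        codes[valid] = np.where(
            a_ivim < a_adc, PreferenceCode.IVIM, PreferenceCode.ADC
        )
    return PreferenceMap(codes)


def p_ivim(pref: PreferenceMap, roi: RoiMask, label: int) -> float:
    """Fraction of valid ROI voxels where IVIM is preferred.

    Invalid voxels (code 0) are excluded from the denominator.  Returns
    NaN when the ROI contains no valid voxel (undefined, not 0).
    """
    sel = roi.indices(label)
    codes = pref.codes[sel]
    n_valid = int((codes != 0).sum())
    if n_valid == 0:
        return float("nan")
    return float((codes == PreferenceCode.IVIM).sum() / n_valid)
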
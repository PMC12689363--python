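"""Closed-form forward models for diffusion-weighted signal decay.

Two models are supported:

* the mono-exponential (ADC) model ``S(b) = S0 * exp(-b * ADC * 1e-3)``
* the bi-exponential intra-voxel incoherent motion (IVIM) model
  ``S(b) = S0 * (f * exp(-b * D* * 1e-3) + (1 - f) * exp(-b * D * 1e-3))``

Unit convention: b-values are given in s/mm² and all diffusivities
(D, D*, ADC) in µm²/ms, so every exponent carries a factor of 1e-3
(1 µm²/ms = 1e-3 mm²/s).  This matches how diffusivities are reported
in the clinical literature (e.g. healthy cervix D ≈ 1.3 µm²/ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IvimParams",
    "AdcParams",
    "ivim_signal",
    "adc_signal",
    "UNIT_SCALE",
    "FREE_WATER_D",
]

#: conversion factor from b[s/mm²] · coef[µm²/ms] to a dimensionless exponent
UNIT_SCALE = 1e-3

#: default ceiling on tissue diffusivity, µm²/ms (free water at body temperature)
FREE_WATER_D = 4.0


@dataclass(frozen=True)
class IvimParams:
    """Bi-exponential IVIM parameters.

    Attributes
    ----------
    S0 : float
        Signal amplitude at b = 0, arbitrary units.  Must be > 0.
    f : float
        Perfusion signal fraction, dimensionless, in [0, 1).
    D : float
        Tissue diffusion coefficient, µm²/ms.  Must be > 0 and below the
        free-water ceiling.
    Dstar : float
        Pseudo-diffusion coefficient of the fast (perfusion) compartment,
        µm²/ms.  Must exceed D whenever f > 0; with f = 0 the fast
        compartment is absent and Dstar is unconstrained (unused).
    """

    S0: float
    f: float
    D: float
    Dstar: float

    def validate(self, d_max: float = FREE_WATER_D) -> None:
        if not self.S0 > 0:
            raise ValueError(f"S0 must be > 0, got {self.S0}")
        if not (0.0 <= self.f < 1.0):
            raise ValueError(f"f must be in [0, 1), got {self.f}")
        if not (0.0 < self.D <= d_max):
            raise ValueError(f"D must be in (0, {d_max}] µm²/ms, got {self.D}")
        if self.f > 0 and not self.Dstar > self.D:
            raise ValueError(
                f"Dstar ({self.Dstar}) must exceed D ({self.D}) when f > 0"
            )


@dataclass(frozen=True)
class AdcParams:
    """Mono-exponential parameters: amplitude S0 (> 0) and ADC (µm²/ms, ≥ 0)."""

    S0: float
    ADC: float

    def validate(self) -> None:
        if not self.S0 > 0:
            raise ValueError(f"S0 must be > 0, got {self.S0}")
        if self.ADC < 0:
            raise ValueError(f"ADC must be >= 0, got {self.ADC}")


def ivim_signal(params: IvimParams, b, *, validate: bool = True) -> np.ndarray:
    """Evaluate the bi-exponential IVIM decay at b-values ``b`` (s/mm²).

    Returns an array of the same shape as ``b`` (or a scalar array for
    scalar input); positive and non-increasing in b, with S(0) = S0.
    """
    if validate:
        params.validate()
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    fast = params.f * np.exp(-b * params.Dstar * UNIT_SCALE)
    slow = (1.0 - params.f) * np.exp(-b * params.D * UNIT_SCALE)
    return params.S0 * (fast + slow)


def adc_signal(params: AdcParams, b, *, validate: bool = True) -> np.ndarray:
    """Evaluate the mono-exponential decay at b-values ``b`` (s/mm²)."""
    if validate:
        params.validate()
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return params.S0 * np.exp(-b * params.ADC * UNIT_SCALE)
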
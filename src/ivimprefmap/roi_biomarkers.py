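"""ROI-level summary biomarkers.

Per region of interest: medians of D, f, D*, ADC_b0 and ADC_b150 over all
valid voxels; the same medians restricted to the IVIM-favoured voxel
subset (and, for diffusivities, to the ADC-favoured subset); p_IVIM; the
perfusion-bias statistic delta-ADC (the median of voxel-wise
ADC_b0 - ADC_b150 differences, NOT the difference of medians); and ROI
volume in cm³.  Summaries are assembled into long-format BiomarkerTable
records for the statistics stage.

A single validity definition is shared with model_selection: voxels with
preference code 0 contribute to no median and to no p_IVIM denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dwi_io import BiomarkerTable, RoiMask
from .model_selection import PreferenceCode, PreferenceMap, p_ivim
from .voxel_fitting import ParameterMaps

__all__ = ["RoiSummary", "summarize_roi", "build_biomarker_table",
           "BIOMARKER_NAMES"]

#: biomarker_name values emitted into tables (units: diffusivities µm²/ms,
#: f and p_IVIM dimensionless, volume cm³)
BIOMARKER_NAMES = ("D", "f", "p_IVIM", "ADC_b0", "ADC_b150", "delta_ADC",
                   "volume")


def _median(values: np.ndarray) -> float:
    """Median over finite entries; NaN (flagged) when none contribute."""
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    return float(np.median(values))


@dataclass
class RoiSummary:
    """Whole-ROI and preference-conditioned biomarker summary."""

    roi_name: str
    n_voxels: int
    n_valid: int
    volume_cm3: float
    p_ivim: float
    median_D: float
    median_f: float
    median_Dstar: float
    median_ADC_b0: float
    median_ADC_b150: float
    median_delta_adc: float
    # medians restricted to IVIM-favoured voxels
    ivim_subset: dict = field(default_factory=dict)
    # diffusivity medians restricted to ADC-favoured voxels
    adc_subset: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.n_valid == 0

    def to_dict(self) -> dict:
        out = {
            "roi_name": self.roi_name,
            "n_voxels": self.n_voxels,
            "n_valid": self.n_valid,
            "volume_cm3": self.volume_cm3,
            "p_IVIM": self.p_ivim,
            "median_D": self.median_D,
            "median_f": self.median_f,
            "median_Dstar": self.median_Dstar,
            "median_ADC_b0": self.median_ADC_b0,
            "median_ADC_b150": self.median_ADC_b150,
            "median_delta_ADC": self.median_delta_adc,
            "ivim_subset": dict(self.ivim_subset),
            "adc_subset": dict(self.adc_subset),
        }
        return out


def summarize_roi(
    maps: ParameterMaps,
    pref: PreferenceMap,
    roi: RoiMask,
    label: int,
    voxel_volume_mm3: float = 1.0,
    roi_name: Optional[str] = None,
) -> RoiSummary:
    """Summarise one labelled region of the parameter maps.

    Medians run over valid voxels only (even counts: mean of the two
    central order statistics, numpy's convention).  delta-ADC is computed
    voxel-wise then median-reduced.  An empty or all-invalid ROI yields a
    flagged summary (NaN medians) rather than fabricated numbers.
    """
    if maps.grid_shape != roi.labels.shape:
        raise ValueError("maps and mask are on different grids")
    sel = roi.indices(label)
    n_voxels = int(sel.sum())
    name = roi_name or roi.label_names.get(label, str(label))
    valid = sel & (pref.codes != 0)
    delta = maps.ADC_b0 - maps.ADC_b150

    summary = RoiSummary(
        roi_name=name,
        n_voxels=n_voxels,
        n_valid=int(valid.sum()),
        volume_cm3=n_voxels * voxel_volume_mm3 / 1000.0,
        p_ivim=p_ivim(pref, roi, label),
        median_D=_median(maps.D[valid]),
        median_f=_median(maps.f[valid]),
        median_Dstar=_median(maps.Dstar[valid]),
        median_ADC_b0=_median(maps.ADC_b0[valid]),
        median_ADC_b150=_median(maps.ADC_b150[valid]),
        median_delta_adc=_median(delta[valid]),
    )
    ivim_sel = sel & (pref.codes == PreferenceCode.IVIM)
    summary.ivim_subset = {
        "n": int(ivim_sel.sum()),
        "median_D": _median(maps.D[ivim_sel]),
        "median_f": _median(maps.f[ivim_sel]),
        "median_Dstar": _median(maps.Dstar[ivim_sel]),
    }
    adc_sel = sel & (pref.codes == PreferenceCode.ADC)
    summary.adc_subset = {
        "n": int(adc_sel.sum()),
        "median_ADC_b0": _median(maps.ADC_b0[adc_sel]),
        "median_ADC_b150": _median(maps.ADC_b150[adc_sel]),
        "median_D": _median(maps.D[adc_sel]),
    }
    return summary


def build_biomarker_table(
    summaries: Sequence[tuple],
) -> BiomarkerTable:
    """Assemble (subject_id, group, session, RoiSummary) tuples into a
    long-format BiomarkerTable.

    Each non-empty summary contributes one record per biomarker in
    ``BIOMARKER_NAMES``; flagged (empty-ROI) summaries contribute nothing.
    Key collisions raise via the BiomarkerTable constructor.
    """
    records = []
    for subject_id, group, session, summary in summaries:
        if summary.empty:
            continue
        values = {
            "D": summary.median_D,
            "f": summary.median_f,
            "p_IVIM": summary.p_ivim,
            "ADC_b0": summary.median_ADC_b0,
            "ADC_b150": summary.median_ADC_b150,
            "delta_ADC": summary.median_delta_adc,
            "volume": summary.volume_cm3,
        }
        for biomarker in BIOMARKER_NAMES:
            records.append(
                {
                    "subject_id": str(subject_id),
                    "group": group,
                    "session": str(session),
                    "roi_name": summary.roi_name,
                    "biomarker_name": biomarker,
                    "value": values[biomarker],
                }
            )
    return BiomarkerTable.from_records(records)
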
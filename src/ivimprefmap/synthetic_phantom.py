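"""Digital diffusion-weighted phantoms with known ground truth.

Phantoms emulate a 10-b-value pelvic DW-MRI acquisition (b = 0, 20, 40,
60, 80, 100, 150, 300, 500, 800 s/mm²): each voxel belongs to a tissue
class with true (S0, f, D, D*), the noiseless signal follows the
bi-exponential IVIM forward model, and magnitude noise is added as
Gaussian or Rician at a prescribed SNR at b = 0.  Cohort-level
generators emulate the two study designs: test-retest sessions with
between-session parameter jitter, and a three-visit longitudinal series
with a treatment-induced D increase and tumour shrinkage.

All randomness flows from a single master seed via numpy SeedSequence
spawning, so every subject/session/visit stream is independently
reproducible.

Class presets: the ``pelvis_toy`` normal-tissue class uses healthy-cervix
central values (f = 0.19, D = 1.3 µm²/ms, D* = 30 µm²/ms); the fluid
class is mono-exponential free water (f = 0, D = 3.0); the tumour class
(f = 0.10, D = 1.0, D* = 20) is a plausible configurable stand-in, not a
measured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .dwi_io import PAPER_BVALUES, AcquisitionScheme, DwiVolume, RoiMask
from .signal_models import IvimParams, ivim_signal

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "GroundTruth",
    "DEFAULT_SCHEME",
    "NORMAL_TISSUE",
    "FLUID",
    "TUMOUR",
    "make_geometry",
    "two_region_spec",
    "pelvis_toy_spec",
    "generate_phantom",
    "make_test_retest",
    "make_longitudinal",
]

DEFAULT_SCHEME = AcquisitionScheme(PAPER_BVALUES, n_averages=4)

#: default signal-to-noise ratio at b = 0 (4-average pelvic EPI scale)
DEFAULT_SNR_B0 = 50.0


@dataclass(frozen=True)
class TissueClass:
    """A named tissue with true IVIM parameters bound to a geometry label."""

    name: str
    params: IvimParams
    region: int

    def __post_init__(self):
        self.params.validate()
        if self.region <= 0:
            raise ValueError("region label must be a positive integer")


NORMAL_TISSUE = TissueClass("normal_tissue",
                            IvimParams(S0=1.0, f=0.19, D=1.3, Dstar=30.0), 2)
FLUID = TissueClass("fluid", IvimParams(S0=1.0, f=0.0, D=3.0, Dstar=30.0), 1)
TUMOUR = TissueClass("tumour",
                     IvimParams(S0=1.0, f=0.10, D=1.0, Dstar=20.0), 3)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom realisation."""

    geometry: np.ndarray
    classes: tuple
    scheme: AcquisitionScheme = DEFAULT_SCHEME
    snr_b0: float = DEFAULT_SNR_B0
    noise_model: str = "rician"
    seed: int = 0
    voxel_size: tuple = (2.9, 2.9, 6.0)

    def __post_init__(self):
        object.__setattr__(self, "geometry",
                           np.asarray(self.geometry, dtype=np.int32))
        object.__setattr__(self, "classes", tuple(self.classes))
        if self.noise_model not in ("gaussian", "rician", "none"):
            raise ValueError(f"unknown noise model '{self.noise_model}'")
        if self.noise_model != "none" and not self.snr_b0 > 0:
            raise ValueError("snr_b0 must be > 0 when noise is enabled")
        by_region = {c.region for c in self.classes}
        present = {int(v) for v in np.unique(self.geometry) if v != 0}
        orphan = present - by_region
        if orphan:
            raise ValueError(f"geometry labels without a tissue class: {orphan}")

    def class_for(self, label: int) -> TissueClass:
        for c in self.classes:
            if c.region == label:
                return c
        raise KeyError(label)


@dataclass
class GroundTruth:
    """Per-voxel true parameter maps consistent with the generated signal."""

    S0: np.ndarray
    f: np.ndarray
    D: np.ndarray
    Dstar: np.ndarray
    labels: np.ndarray


def make_geometry(preset: str, shape=(8, 8, 2)) -> np.ndarray:
    """Label volume for a named preset.

    ``two_region``: labels 1 and 2 split the grid along x.
    ``pelvis_toy``: thirds along x — fluid (1), normal tissue (2),
    tumour (3).
    """
    geom = np.zeros(shape, dtype=np.int32)
    nx = shape[0]
    if preset == "two_region":
        geom[: nx // 2] = 1
        geom[nx // 2:] = 2
    elif preset == "pelvis_toy":
        geom[: nx // 3] = 1
        geom[nx // 3: 2 * nx // 3] = 2
        geom[2 * nx // 3:] = 3
    else:
        raise ValueError(f"unknown geometry preset '{preset}'")
    return geom


def two_region_spec(shape=(8, 8, 2), *, snr_b0=DEFAULT_SNR_B0,
                    noise_model="rician", seed=0) -> PhantomSpec:
    """Fluid + perfused-normal-tissue phantom (preference-map testbed)."""
    return PhantomSpec(make_geometry("two_region", shape),
                       (FLUID, NORMAL_TISSUE), snr_b0=snr_b0,
                       noise_model=noise_model, seed=seed)


def pelvis_toy_spec(shape=(9, 9, 2), *, snr_b0=DEFAULT_SNR_B0,
                    noise_model="rician", seed=0) -> PhantomSpec:
    """Three-class fluid/normal/tumour phantom."""
    return PhantomSpec(make_geometry("pelvis_toy", shape),
                       (FLUID, NORMAL_TISSUE, TUMOUR), snr_b0=snr_b0,
                       noise_model=noise_model, seed=seed)


def generate_phantom(spec: PhantomSpec):
    """Generate one 4D phantom: (DwiVolume, RoiMask, GroundTruth).

    Noiseless signal follows the IVIM forward model per class.  Noise:
    ``gaussian`` adds Normal(0, sigma); ``rician`` takes the magnitude of
    (S + n1, n2) with independent Normal(0, sigma) channels; sigma =
    S0_ref / snr_b0 with S0_ref the largest class S0.  Deterministic
    given ``spec.seed``.
    """
    geom = spec.geometry
    b = spec.scheme.b
    nb = len(b)
    shape = geom.shape
    signal = np.zeros(shape + (nb,), dtype=float)
    truth = GroundTruth(
        S0=np.zeros(shape), f=np.zeros(shape), D=np.zeros(shape),
        Dstar=np.zeros(shape), labels=geom.copy(),
    )
    names = {}
    for label in sorted(int(v) for v in np.unique(geom) if v != 0):
        cls = spec.class_for(label)
        names[label] = cls.name
        sel = geom == label
        signal[sel] = ivim_signal(cls.params, b)
        truth.S0[sel] = cls.params.S0
        truth.f[sel] = cls.params.f
        truth.D[sel] = cls.params.D
        truth.Dstar[sel] = cls.params.Dstar

    if spec.noise_model != "none":
        rng = np.random.default_rng(spec.seed)
        s0_ref = max(c.params.S0 for c in spec.classes)
        sigma = s0_ref / spec.snr_b0
        if spec.noise_model == "gaussian":
            signal = signal + rng.normal(0.0, sigma, signal.shape)
        else:  # rician: magnitude of a complex Gaussian-perturbed signal
            re = signal + rng.normal(0.0, sigma, signal.shape)
            im = rng.normal(0.0, sigma, signal.shape)
            signal = np.hypot(re, im)

    vol = DwiVolume(signal=signal, scheme=spec.scheme,
                    voxel_size=spec.voxel_size)
    mask = RoiMask(labels=geom.copy(), label_names=names)
    return vol, mask, truth


def _jitter_params(p: IvimParams, rng, cv: float) -> IvimParams:
    """Multiplicative between-session jitter on f, D and D*."""
    if cv == 0:
        return p
    f = p.f * (1.0 + rng.normal(0.0, cv)) if p.f > 0 else 0.0
    d = p.D * (1.0 + rng.normal(0.0, cv))
    ds = p.Dstar * (1.0 + rng.normal(0.0, cv))
    f = float(np.clip(f, 0.0, 0.999))
    d = float(np.clip(d, 1e-3, 4.0))
    ds = float(max(ds, d * 1.5))
    return IvimParams(S0=p.S0, f=f, D=d, Dstar=ds)


def _derived_seed(ss: np.random.SeedSequence, *keys) -> int:
    child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=tuple(keys))
    return int(child.generate_state(1)[0] % (2**31))


def make_test_retest(
    spec: PhantomSpec,
    n_subjects: int,
    between_session_cv: float,
    n_sessions: int = 2,
):
    """Repeatability cohort: per subject and session, true tissue
    parameters are jittered multiplicatively (truth × (1 + N(0, cv)))
    and a phantom generated with a deterministically derived seed.

    Returns a list of dicts with keys subject_id, session, volume, mask,
    truth, spec.
    """
    if between_session_cv < 0:
        raise ValueError("between_session_cv must be >= 0")
    master = np.random.SeedSequence(spec.seed)
    out = []
    for subj in range(n_subjects):
        for sess in range(n_sessions):
            seed = _derived_seed(master, subj, sess)
            rng = np.random.default_rng(
                _derived_seed(master, subj, sess, 999)
            )
            classes = tuple(
                replace(c, params=_jitter_params(c.params, rng,
                                                 between_session_cv))
                for c in spec.classes
            )
            sess_spec = replace(spec, classes=classes, seed=seed)
            vol, mask, truth = generate_phantom(sess_spec)
            out.append({
                "subject_id": f"sub{subj:03d}",
                "session": f"ses{sess + 1}",
                "volume": vol,
                "mask": mask,
                "truth": truth,
                "spec": sess_spec,
            })
    return out


def make_longitudinal(
    spec: PhantomSpec,
    n_subjects: int,
    d_multipliers: Sequence[float] = (1.0, 1.15, 1.15),
    erosion_steps: Sequence[int] = (0, 1, 2),
    tumour_label: int = 3,
    timepoints: Sequence[str] = ("baseline", "week3", "week5"),
    between_subject_cv: float = 0.0,
):
    """Longitudinal cohort: three visits per subject with the tumour D
    scaled per timepoint and the tumour label eroded to shrink volume.

    Raises if erosion empties the tumour region.  Returns a list of
    per-visit dicts (subject_id, session, volume, mask, truth, spec).
    """
    if len(d_multipliers) != len(timepoints) or len(erosion_steps) != len(timepoints):
        raise ValueError("need one D multiplier and erosion step per timepoint")
    if any(m <= 0 for m in d_multipliers):
        raise ValueError("D multipliers must be > 0")
    master = np.random.SeedSequence(spec.seed)
    out = []
    for subj in range(n_subjects):
        rng = np.random.default_rng(_derived_seed(master, subj, 777))
        base_classes = tuple(
            replace(c, params=_jitter_params(c.params, rng,
                                             between_subject_cv))
            for c in spec.classes
        )
        for tp, (label_tp, mult, erode) in enumerate(
            zip(timepoints, d_multipliers, erosion_steps)
        ):
            classes = []
            for c in base_classes:
                if c.region == tumour_label:
                    p = c.params
                    d_new = float(np.clip(p.D * mult, 1e-3, 4.0))
                    classes.append(replace(
                        c, params=IvimParams(p.S0, p.f, d_new,
                                             max(p.Dstar, d_new * 1.5))))
                else:
                    classes.append(c)
            geom = spec.geometry.copy()
            if erode > 0:
                tum = geom == tumour_label
                # erode in-plane only: slices are thick (6 mm) relative to
                # in-plane resolution, so shrinkage is modelled per slice
                tum_eroded = ndimage.binary_erosion(
                    tum, structure=np.ones((3, 3, 1), dtype=bool),
                    iterations=erode)
                if not tum_eroded.any():
                    raise ValueError(
                        f"erosion by {erode} empties the tumour region"
                    )
                geom[tum & ~tum_eroded] = 0
            visit_spec = replace(
                spec, geometry=geom, classes=tuple(classes),
                seed=_derived_seed(master, subj, tp),
            )
            vol, mask, truth = generate_phantom(visit_spec)
            out.append({
                "subject_id": f"pat{subj:03d}",
                "session": label_tp,
                "volume": vol,
                "mask": mask,
                "truth": truth,
                "spec": visit_spec,
            })
    return out
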
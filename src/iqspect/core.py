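"""Shared domain types for the quantitative SPECT / CBF pipeline.

Conventions used throughout the package:

* images are 2-D multi-slice, stored ``(n_slices, ny, nx)`` with voxel
  spacing in mm; voxel values carry an explicit unit tag (``counts``,
  ``Bq/mL``, ``mL/min/100g`` or ``%``),
* sinograms are stored ``(n_frames, n_views, n_bins)`` with views spread
  uniformly over 360 degrees (opposed views are required by the
  geometric-mean reconstruction),
* flows ``f`` are expressed in mL/min per mL of tissue; reported CBF is
  ``100 * f / rho`` in mL/min/100 g with blood/brain density
  ``rho = 1.06 g/mL``,
* times are minutes from the first tracer injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ImageVolume",
    "Geometry",
    "ProjectionSet",
    "InputFunction",
    "AcquisitionSchedule",
    "ScatterParams",
    "InstitutionProfile",
    "KineticConstants",
    "CalibrationFactors",
    "MuMap",
    "LookupTable",
    "PhantomSpec",
    "ResolutionEstimate",
    "MU_BRAIN_RECON",
    "FWHM_TO_SIGMA",
]

#: uniform attenuation coefficient assumed by the reconstruction (cm^-1),
#: an average over brain and skull for the 159 keV photopeak of 123I.
MU_BRAIN_RECON = 0.160

#: FWHM = sigma * sqrt(8 ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ImageVolume:
    """Voxel grid with spacing and a declared physical unit."""

    data: np.ndarray  # (n_slices, ny, nx)
    spacing_mm: tuple[float, float, float]  # (slice, y, x)
    unit: str = "arbitrary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("ImageVolume requires a (slices, ny, nx) array")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def pixel_mm(self) -> float:
        return float(self.spacing_mm[-1])

    def like(self, data: np.ndarray, unit: str | None = None) -> "ImageVolume":
        return ImageVolume(np.asarray(data, float), self.spacing_mm,
                          self.unit if unit is None else unit)


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry (views over the full circle)."""

    n_views: int
    n_bins: int
    bin_mm: float
    full_circle: bool = True

    def __post_init__(self) -> None:
        if self.n_views < 2 or self.n_bins < 2:
            raise ValueError("degenerate geometry")
        if self.full_circle and self.n_views % 2:
            raise ValueError("full-circle geometry needs an even view count "
                             "so every view has an opposed partner")

    @property
    def angles_deg(self) -> np.ndarray:
        span = 360.0 if self.full_circle else 180.0
        return np.arange(self.n_views) * span / self.n_views


@dataclass
class ProjectionSet:
    """Dynamic sinogram stack: frames x slices x views x radial bins."""

    data: np.ndarray  # (n_frames, n_slices, n_views, n_bins)
    geometry: Geometry
    frame_starts_min: np.ndarray
    frame_durations_min: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:       # single frame, single slice
            self.data = self.data[None, None]
        elif self.data.ndim == 3:     # single frame, multi-slice
            self.data = self.data[None]
        self.frame_starts_min = np.atleast_1d(np.asarray(self.frame_starts_min, float))
        self.frame_durations_min = np.atleast_1d(np.asarray(self.frame_durations_min, float))
        if self.data.shape[0] != len(self.frame_starts_min):
            raise ValueError("frame bookkeeping does not match sinogram stack")
        if self.data.shape[2:] != (self.geometry.n_views, self.geometry.n_bins):
            raise ValueError("sinogram shape does not match geometry")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    def summed(self, t0: float | None = None, t1: float | None = None) -> "ProjectionSet":
        """Counts summed over all frames fully inside the window [t0, t1]."""
        s, d = self.frame_starts_min, self.frame_durations_min
        if t0 is None:
            t0 = float(s.min())
        if t1 is None:
            t1 = float((s + d).max())
        sel = (s >= t0 - 1e-9) & (s + d <= t1 + 1e-9)
        if not sel.any():
            raise ValueError(f"no frames inside window [{t0}, {t1}] min")
        return ProjectionSet(self.data[sel].sum(axis=0, keepdims=True),
                             self.geometry,
                             np.array([s[sel].min()]),
                             np.array([d[sel].sum()]))


@dataclass
class InputFunction:
    """Whole-blood tracer concentration versus time for one injection.

    Times are minutes from that injection; values are Bq/mL and are zero
    for t < 0 by contract.
    """

    times_min: np.ndarray
    values_bqml: np.ndarray
    dose_mbq: float

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, float)
        self.values_bqml = np.asarray(self.values_bqml, float)
        if self.times_min.shape != self.values_bqml.shape:
            raise ValueError("time grid and values differ in length")
        if np.any(self.values_bqml < -1e-12):
            raise ValueError("negative blood concentration")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        out = np.interp(t, self.times_min, self.values_bqml, left=0.0, right=0.0)
        return np.where(t < 0.0, 0.0, out)

    def scaled(self, factor: float) -> "InputFunction":
        return InputFunction(self.times_min, self.values_bqml * factor, self.dose_mbq)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Dual-injection protocol timing: two 28-min dynamic scans of
    7 x 4-min frames, injections at 0 and 30 min, vasodilator at 20 min,
    calibration blood sample at 10 min."""

    inj1_min: float = 0.0
    inj2_min: float = 30.0
    acz_min: float = 20.0
    sample_min: float = 10.0
    n_frames_per_scan: int = 7
    frame_min: float = 4.0
    dose1_mbq: float = 140.0
    dose2_mbq: float = 140.0

    def frame_starts(self) -> np.ndarray:
        s1 = self.inj1_min + np.arange(self.n_frames_per_scan) * self.frame_min
        s2 = self.inj2_min + np.arange(self.n_frames_per_scan) * self.frame_min
        return np.concatenate([s1, s2])

    def frame_durations(self) -> np.ndarray:
        return np.full(2 * self.n_frames_per_scan, self.frame_min)

    @property
    def scan1_end(self) -> float:
        return self.inj1_min + self.n_frames_per_scan * self.frame_min

    @property
    def scan2_end(self) -> float:
        return self.inj2_min + self.n_frames_per_scan * self.frame_min

    def validate(self) -> None:
        if self.scan1_end > self.inj2_min + 1e-9:
            raise ValueError("first scan overlaps second injection")
        if not (self.inj1_min <= self.sample_min < self.scan1_end):
            raise ValueError("blood sample outside the first scan")


@dataclass(frozen=True)
class ScatterParams:
    """Transmission-dependent scatter fraction SF(t) = 1 - 1/(A - B t^beta)
    plus a near-uniform septal-penetration offset (fraction of mean counts).
    The scatter kernel is a unit-area symmetric mono-exponential."""

    a: float = 2.0
    b: float = 1.0
    beta: float = 0.5
    kernel_decay_mm: float = 20.0
    penetration_offset_fraction: float = 0.03

    def validate(self) -> None:
        t = np.linspace(0.0, 1.0, 201)
        denom = self.a - self.b * t ** self.beta
        if np.any(denom < 1.0 - 1e-9):
            raise ValueError("scatter fraction leaves [0, 1): require "
                             "A - B t^beta >= 1 on [0, 1]")

    def fraction(self, transmission: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(transmission, float), 0.0, 1.0)
        denom = self.a - self.b * t ** self.beta
        return np.clip(1.0 - 1.0 / np.maximum(denom, 1.0), 0.0, None)


@dataclass(frozen=True)
class InstitutionProfile:
    """Per-institution acquisition profile: overall reconstructed
    resolution, Becquerel calibration factor (BCF), well-counter
    cross-calibration factor (CCF), doses and scatter behaviour."""

    name: str
    fwhm_mm: float              # spatial resolution of reconstructed images
    bcf: float                  # Bq/mL per reconstructed count-rate unit
    ccf: float                  # well-counter sensitivity relative to SPECT
    imp_dose_mbq: float
    acz_dose_mg_kg: float
    n_subjects: int = 10
    scatter: ScatterParams = field(default_factory=ScatterParams)

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0 or self.bcf <= 0 or self.ccf <= 0:
            raise ValueError("FWHM, BCF and CCF must be positive")


@dataclass(frozen=True)
class KineticConstants:
    """Tracer constants: distribution volume Vd (mL/mL) and blood/brain
    density rho (g/mL); CBF[mL/min/100 g] = 100 * f / rho."""

    vd: float = 35.0
    rho: float = 1.06

    def __post_init__(self) -> None:
        if self.vd <= 0 or self.rho <= 0:
            raise ValueError("Vd and rho must be positive")

    def flow_to_cbf(self, f):
        return 100.0 * np.asarray(f, float) / self.rho

    def cbf_to_flow(self, cbf):
        return np.asarray(cbf, float) * self.rho / 100.0


@dataclass(frozen=True)
class CalibrationFactors:
    bcf: float
    ccf: float

    def __post_init__(self) -> None:
        if self.bcf <= 0 or self.ccf <= 0:
            raise ValueError("calibration factors must be positive")


@dataclass
class MuMap:
    """Attenuation map: MU_BRAIN_RECON inside the head mask, 0 outside."""

    values: np.ndarray  # cm^-1, (n_slices, ny, nx)
    mask: np.ndarray    # bool
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        if self.values.ndim == 2:
            self.values = self.values[None]
            self.mask = self.mask[None]


@dataclass
class LookupTable:
    """Monotone map from flow to expected window-mean tissue activity.

    ``activities`` must be strictly increasing with flow; ``scale`` is the
    multiplicative factor applied to the activity axis (the quantity the
    global-CBF anchoring step adjusts).
    """

    flows: np.ndarray          # mL/min/mL, ascending
    activities: np.ndarray     # Bq/mL, strictly increasing
    window: tuple[float, float]
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.flows = np.asarray(self.flows, float)
        self.activities = np.asarray(self.activities, float)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        d = np.diff(self.activities)
        if np.any(d <= 0):
            raise ValueError("look-up table is not strictly increasing in flow")

    @property
    def scaled_activities(self) -> np.ndarray:
        return self.activities * self.scale

    def rescaled(self, scale: float) -> "LookupTable":
        return LookupTable(self.flows, self.activities, self.window, scale)


@dataclass
class PhantomSpec:
    """Digital phantom: a labelled structure map with per-structure tissue
    compartment, attenuation, flows, and (for static phantoms) activity."""

    labels: np.ndarray                       # int structure ids, (slices, ny, nx)
    structures: Mapping[str, int]            # name -> label id
    compartment_of: Mapping[str, str]        # name -> gray/white/skull/scalp/background
    spacing_mm: tuple[float, float, float]
    mu_cm: Mapping[str, float] = field(default_factory=dict)
    f_rest: Mapping[str, float] = field(default_factory=dict)   # mL/min/mL
    f_acz: Mapping[str, float] = field(default_factory=dict)
    activity_bqml: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim == 2:
            self.labels = self.labels[None]
        if any(v < 0 for v in self.f_rest.values()) or any(v < 0 for v in self.f_acz.values()):
            raise ValueError("flows must be non-negative")
        if any(v < 0 for v in self.mu_cm.values()):
            raise ValueError("attenuation must be non-negative")

    # -- masks ---------------------------------------------------------
    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.structures[name]

    def compartment_mask(self, compartment: str) -> np.ndarray:
        out = np.zeros(self.labels.shape, bool)
        for name, comp in self.compartment_of.items():
            if comp == compartment and name in self.structures:
                out |= self.mask(name)
        return out

    @property
    def gm_mask(self) -> np.ndarray:
        return self.compartment_mask("gray")

    @property
    def wm_mask(self) -> np.ndarray:
        return self.compartment_mask("white")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.gm_mask | self.wm_mask

    @property
    def head_mask(self) -> np.ndarray:
        return self.labels > 0

    # -- per-voxel maps ------------------------------------------------
    def _paint(self, per_structure: Mapping[str, float]) -> np.ndarray:
        out = np.zeros(self.labels.shape, float)
        for name, value in per_structure.items():
            if name in self.structures:
                out[self.mask(name)] = value
        return out

    def mu_map_true(self) -> ImageVolume:
        return ImageVolume(self._paint(self.mu_cm), self.spacing_mm, unit="cm^-1")

    def flow_map(self, condition: str = "rest") -> ImageVolume:
        per = self.f_rest if condition == "rest" else self.f_acz
        return ImageVolume(self._paint(per), self.spacing_mm, unit="mL/min/mL")

    def activity_map(self) -> ImageVolume:
        return ImageVolume(self._paint(self.activity_bqml), self.spacing_mm, unit="Bq/mL")

    def with_flow_scale(self, rest_factor: float, acz_factor: float | None = None) -> "PhantomSpec":
        """Multiplicative global flow perturbation (inter-subject variability)."""
        if acz_factor is None:
            acz_factor = rest_factor
        return replace(
            self,
            f_rest={k: v * rest_factor for k, v in self.f_rest.items()},
            f_acz={k: v * acz_factor for k, v in self.f_acz.items()},
        )


@dataclass(frozen=True)
class ResolutionEstimate:
    fwhm_mm: float
    residual: float
    freq_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("FWHM must be non-negative")
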
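"""Dual-table autoradiographic CBF estimation (DTARG).

From two 28-min dynamic scans with tracer injections at 0 and 30 min and
a vasodilator challenge at 20 min, CBF is estimated by table look-up:

1. the population-standard input function is calibrated against a single
   10-min whole-blood sample (counted in a well counter cross-calibrated
   to the SPECT images by CCF),
2. a look-up table maps flow to the expected window-mean tissue activity
   predicted by the one-tissue compartment model with distribution
   volume Vd = 35.0 mL/mL,
3. global gray-matter CBF is anchored on the 24-28 min frame (the window
   least sensitive to input-shape variation), and the full-study (0-28)
   table is rescaled so pixelwise CBF is consistent with that anchor,
4. the tissue background at the second injection is predicted from the
   rest-CBF image by continuing the compartment model to 58 min, and
5. a second look-up applied to the background-subtracted 30-58 min data
   yields the challenge CBF; the percent increase is the cerebrovascular
   reactivity (CVR).

CBF is reported in mL/min/100 g using the blood/brain density
rho = 1.06 g/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (FWHM_TO_SIGMA, ImageVolume, InputFunction, KineticConstants,
                   LookupTable)
from .phantoms import DTARG_FILTER_FWHM_MM, window_mean_tac

__all__ = [
    "calibrate_input_function",
    "build_lookup_table",
    "invert_lookup",
    "estimate_global_cbf",
    "scale_lookup_table",
    "compute_rest_cbf",
    "predict_background",
    "compute_acz_cbf",
    "compute_cvr",
    "detect_gm_mask",
    "core_mask",
    "DtargResult",
]

FLOW_MAX = 1.2      # mL/min/mL; covers > 120 mL/min/100 g
FLOW_STEP = 0.001

# tables depend only on (input curve, Vd, window, flow grid); within a
# cohort every subject shares the calibrated input, so memoize.
_TABLE_CACHE: dict = {}


def _input_key(input_fn: InputFunction) -> str:
    import hashlib
    h = hashlib.sha1()
    h.update(input_fn.times_min.tobytes())
    h.update(input_fn.values_bqml.tobytes())
    return h.hexdigest()


def calibrate_input_function(standard: InputFunction, well_sample: float,
                             ccf: float, t_sample_min: float = 10.0) -> InputFunction:
    """Scale the population curve so it passes through the measured
    whole-blood point: scale = (well_sample / CCF) / standard(t_sample)."""
    ref = float(standard(np.array([t_sample_min]))[0])
    if ref <= 0:
        raise ValueError("standard input function vanishes at the sample time")
    if ccf <= 0:
        raise ValueError("CCF must be positive")
    return standard.scaled((well_sample / ccf) / ref)


def build_lookup_table(input_fn: InputFunction, constants: KineticConstants,
                       window: tuple[float, float],
                       flow_max: float = FLOW_MAX,
                       flow_step: float = FLOW_STEP) -> LookupTable:
    """Expected window-mean tissue activity for each flow on the grid
    0..flow_max (strictly monotone by construction, verified at build)."""
    key = (_input_key(input_fn), constants.vd, window, flow_max, flow_step)
    if key in _TABLE_CACHE:
        return _TABLE_CACHE[key].rescaled(1.0)
    flows = np.arange(0.0, flow_max + flow_step / 2, flow_step)
    acts = window_mean_tac(flows, constants.vd, input_fn, window)
    table = LookupTable(flows=flows, activities=acts, window=window)
    _TABLE_CACHE[key] = table
    return table.rescaled(1.0)


def invert_lookup(table: LookupTable, activity, constants: KineticConstants):
    """Flow from window-mean activity by inverse interpolation.

    Returns ``(cbf, clipped)``: CBF in mL/min/100 g and a boolean mask of
    values above the table maximum (clamped to the top flow).
    """
    activity = np.asarray(activity, float)
    if np.any(activity < 0):
        raise ValueError("negative tissue activity")
    acts = table.scaled_activities
    f = np.interp(activity, acts, table.flows)
    clipped = activity > acts[-1]
    return constants.flow_to_cbf(f), clipped


def estimate_global_cbf(frame_24_28: ImageVolume, gm_mask: np.ndarray,
                        table_24_28: LookupTable,
                        constants: KineticConstants) -> float:
    """Global gray-matter CBF from the 24-28 min frame: the look-up
    inverse of the GM-mean activity."""
    gm_mask = np.asarray(gm_mask, bool)
    if not gm_mask.any():
        raise ValueError("empty gray-matter mask")
    mean_act = float(frame_24_28.data[gm_mask].mean())
    cbf, _ = invert_lookup(table_24_28, np.array([max(mean_act, 0.0)]), constants)
    return float(cbf[0])


def scale_lookup_table(table: LookupTable, image_0_28: ImageVolume,
                       gm_mask: np.ndarray, target_global_cbf: float,
                       constants: KineticConstants,
                       bracket: tuple[float, float] = (0.2, 5.0),
                       tol: float = 1e-4) -> LookupTable:
    """Rescale the table's activity axis so the GM-mean of pixelwise
    inverted CBF matches the global anchor (bisection on the scale)."""
    if target_global_cbf <= 0:
        raise ValueError("target global CBF must be positive")
    gm_mask = np.asarray(gm_mask, bool)
    acts = image_0_28.data[gm_mask]

    def gm_cbf(scale: float) -> float:
        cbf, _ = invert_lookup(table.rescaled(scale * table.scale), acts, constants)
        return float(cbf.mean())

    lo, hi = bracket
    # gm_cbf is decreasing in the scale
    if (gm_cbf(lo) - target_global_cbf) < 0 or (gm_cbf(hi) - target_global_cbf) > 0:
        raise ValueError(
            f"no scale in [{lo}, {hi}] reaches global CBF {target_global_cbf:.1f} "
            f"(range [{gm_cbf(hi):.1f}, {gm_cbf(lo):.1f}])")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gm_cbf(mid) > target_global_cbf:
            lo = mid
        else:
            hi = mid
    s = 0.5 * (lo + hi)
    return table.rescaled(s * table.scale)


def detect_gm_mask(image_0_28: ImageVolume, head_mask: np.ndarray,
                   fraction: float = 0.6) -> np.ndarray:
    """Blind gray-matter mask: voxels above ``fraction`` of the robust
    maximum of the 0-28 min image, inside the head."""
    head_mask = np.asarray(head_mask, bool)
    ref = np.percentile(image_0_28.data[head_mask], 99) if head_mask.any() else 0.0
    if ref <= 0:
        raise ValueError("no activity inside the head mask")
    return (image_0_28.data > fraction * ref) & head_mask


def core_mask(mask: np.ndarray, spacing_mm: float, erosion_mm: float = 7.5) -> np.ndarray:
    """Erode a region in-plane so sampling avoids tissue boundaries
    (resolution-scale erosion, the ROI-placement convention)."""
    mask = np.asarray(mask, bool)
    it = max(0, int(round(erosion_mm / spacing_mm)))
    if it == 0:
        return mask.copy()
    out = np.zeros_like(mask)
    for s in range(mask.shape[0]):
        out[s] = ndimage.binary_erosion(mask[s], iterations=it)
    # never erode a region away entirely
    return out if out.any() else mask.copy()


def _smooth(image: ImageVolume, fwhm_mm: float) -> ImageVolume:
    if fwhm_mm <= 0:
        return image
    sigma = fwhm_mm * FWHM_TO_SIGMA / image.pixel_mm
    data = np.stack([ndimage.gaussian_filter(image.data[s], sigma)
                     for s in range(image.n_slices)])
    return image.like(data)


@dataclass
class DtargResult:
    """CBF image plus the provenance of the table scaling."""

    cbf: ImageVolume
    global_cbf: float
    scale: float
    table: LookupTable
    clipped_fraction: float = 0.0
    extras: dict = field(default_factory=dict)


def compute_rest_cbf(mean_0_28: ImageVolume, frame_24_28: ImageVolume,
                     input_fn: InputFunction, constants: KineticConstants,
                     gm_mask: np.ndarray, head_mask: np.ndarray,
                     smoothing_fwhm_mm: float = DTARG_FILTER_FWHM_MM) -> DtargResult:
    """Rest CBF: global anchor on the (unsmoothed) 24-28 min frame, table
    rescaling, pixelwise look-up on the smoothed 0-28 min mean image,
    extra-cranial voxels set to zero."""
    head_mask = np.asarray(head_mask, bool)
    table_anchor = build_lookup_table(input_fn, constants, (24.0, 28.0))
    global_cbf = estimate_global_cbf(frame_24_28, gm_mask, table_anchor, constants)

    table = build_lookup_table(input_fn, constants, (0.0, 28.0))
    sm = _smooth(mean_0_28, smoothing_fwhm_mm)
    scaled = scale_lookup_table(table, sm, gm_mask, global_cbf, constants)
    cbf, clipped = invert_lookup(scaled, np.clip(sm.data, 0, None), constants)
    cbf[~head_mask] = 0.0
    return DtargResult(cbf=mean_0_28.like(cbf, unit="mL/min/100g"),
                       global_cbf=global_cbf, scale=scaled.scale, table=scaled,
                       clipped_fraction=float(clipped[head_mask].mean()))


def predict_background(rest_cbf: ImageVolume, input_first: InputFunction,
                       constants: KineticConstants,
                       window: tuple[float, float] = (30.0, 58.0),
                       scale: float = 1.0) -> ImageVolume:
    """Tissue activity from the first injection during the second scan,
    predicted per voxel by continuing the compartment model with the
    rest-phase flow; ``scale`` carries the rest table's calibration."""
    key = ("bg", _input_key(input_first), constants.vd, window)
    if key in _TABLE_CACHE:
        flows, acts = _TABLE_CACHE[key]
    else:
        flows = np.arange(0.0, FLOW_MAX + FLOW_STEP / 2, FLOW_STEP)
        acts = window_mean_tac(flows, constants.vd, input_first, window)
        _TABLE_CACHE[key] = (flows, acts)
    f_map = constants.cbf_to_flow(np.clip(rest_cbf.data, 0, None))
    bg = np.interp(f_map, flows, acts * scale)
    return rest_cbf.like(bg, unit="Bq/mL")


def compute_acz_cbf(mean_30_58: ImageVolume, background: ImageVolume,
                    input_second: InputFunction, constants: KineticConstants,
                    head_mask: np.ndarray, scale: float = 1.0,
                    smoothing_fwhm_mm: float = DTARG_FILTER_FWHM_MM) -> DtargResult:
    """Challenge CBF: look-up of the background-subtracted second-scan
    window mean, using a table for the second injection's input on its
    own clock (window 0-28 after injection), sharing the rest scale."""
    if background.data.shape != mean_30_58.data.shape:
        raise ValueError("background and second-scan grids differ")
    head_mask = np.asarray(head_mask, bool)
    table = build_lookup_table(input_second, constants, (0.0, 28.0)).rescaled(scale)
    sm = _smooth(mean_30_58, smoothing_fwhm_mm)
    diff = np.clip(sm.data - background.data, 0.0, None)
    cbf, clipped = invert_lookup(table, diff, constants)
    cbf[~head_mask] = 0.0
    return DtargResult(cbf=mean_30_58.like(cbf, unit="mL/min/100g"),
                       global_cbf=float("nan"), scale=scale, table=table,
                       clipped_fraction=float(clipped[head_mask].mean()))


def compute_cvr(rest: ImageVolume, acz: ImageVolume) -> ImageVolume:
    """Percent CBF increase after the challenge: 100 (acz - rest)/rest,
    zero where rest CBF is zero."""
    if rest.data.shape != acz.data.shape:
        raise ValueError("rest and challenge grids differ")
    out = np.zeros_like(rest.data)
    np.divide(100.0 * (acz.data - rest.data), rest.data, out=out,
              where=rest.data > 0)
    return rest.like(out, unit="%")
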
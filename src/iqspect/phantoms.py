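"""Digital phantoms, tracer kinetics and dynamic projection simulation.

The brain phantom is a stylised 2-D multi-slice head: a convoluted
cortical gray-matter band, deep gray nuclei (basal ganglia, thalamus), a
white-matter core, an infratentorial slice (cerebellum, vermis, pons),
and skull/scalp rings with realistic head contour.  Gray matter is
modelled at territory scale (bands of ~20-25 mm) rather than at cortical
thickness: brain SPECT at 10-17 mm resolution quantifies territory-level
flow, and the phantom is built so that ROI means remain interpretable at
that resolution.

The simulator produces dual-injection dynamic sinograms: per-structure
one-tissue-compartment time-activity curves, frame integration, system
blurring, attenuated forward projection through the *true* heterogeneous
attenuation (skull denser than brain), transmission-dependent scatter,
a uniform septal-penetration offset, and Poisson counting noise whose
level is set by the institution's sensitivity (1/BCF).
"""

from __future__ import annotations

import hashlib

import numpy as np
from scipy import ndimage

from .core import (FWHM_TO_SIGMA, AcquisitionSchedule, Geometry, ImageVolume,
                   InputFunction, InstitutionProfile, KineticConstants,
                   PhantomSpec, ProjectionSet)
from .projector import project_slices, transmission_sinogram

__all__ = [
    "make_brain_phantom",
    "make_cylinder_phantom",
    "standard_input_function",
    "tissue_tac",
    "tissue_tac_batch",
    "simulate_dual_injection_study",
    "simulate_static_scan",
    "simulate_blood_sample",
    "intrinsic_blur_fwhm",
    "POST_FILTER_FWHM_MM",
    "DTARG_FILTER_FWHM_MM",
    "COUNT_SENSITIVITY",
]

#: post-reconstruction Gaussian filter (mm FWHM) of the quantitative
#: reconstruction; institution resolutions in Table-style profiles are
#: resolutions of the *reconstructed* images, i.e. they include this.
POST_FILTER_FWHM_MM = 7.0

#: additional smoothing applied by the CBF calculation itself (mm FWHM).
DTARG_FILTER_FWHM_MM = 7.0

#: detector sensitivity scale: expected counts per (Bq/mL * mm * min) are
#: COUNT_SENSITIVITY / BCF.  Chosen so a 28-min rest scan of the brain
#: phantom at the least sensitive profile collects a clinically typical
#: ~4e5 counts per slice.
COUNT_SENSITIVITY = 0.14

# attenuation coefficients (cm^-1) at the 159 keV photopeak used for the
# *true* phantom; reconstruction assumes the uniform brain+skull average.
_MU_TRUE = {"brain": 0.150, "skull": 0.250, "scalp": 0.150, "water": 0.160}

_GM_STRUCTURES = ("cortex", "basal_ganglia_l", "basal_ganglia_r",
                  "thalamus_l", "thalamus_r", "cerebellum", "vermis", "pons")
_WM_STRUCTURES = ("white_matter", "white_matter_cb")


def _grid_coords(n: int, spacing: float):
    c = (n - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    x = (jj - c) * spacing          # +x to the left of the subject
    y = (c - ii) * spacing          # +y anterior
    return x, y, np.hypot(x, y)


def make_brain_phantom(grid_size: int = 96, spacing_mm: float = 2.5,
                       seed: int = 0, n_slices: int = 3,
                       gm_cbf: float = 35.7, wm_cbf: float = 25.8,
                       gm_cbf_acz: float = 51.7, wm_cbf_acz: float = 34.3,
                       constants: KineticConstants = KineticConstants()) -> PhantomSpec:
    """Multi-slice digital head phantom.

    Default flows reproduce population-mean gray/white CBF at rest and
    after the vasodilator challenge (35.7/25.8 and 51.7/34.3 mL/min/100 g).
    The convolution phase of the cortical band is drawn from ``seed`` so
    different subjects are not voxel-identical, while the same seed always
    yields the same phantom.
    """
    if grid_size < 32:
        raise ValueError("grid must be at least 32 x 32")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    # head geometry (mm)
    scalp_r, skull_r, brain_r = 86.0, 82.0, 75.0
    if grid_size * spacing_mm < 2 * scalp_r + 4 * spacing_mm:
        raise ValueError("grid too small to contain the head phantom; "
                         "increase grid_size or spacing_mm")
    if n_slices < 1:
        raise ValueError("need at least one slice")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)

    x, y, r = _grid_coords(grid_size, spacing_mm)
    theta = np.arctan2(x, y)  # angle from the anterior axis

    names = ["background", "scalp", "skull", "white_matter", "cortex",
             "basal_ganglia_l", "basal_ganglia_r", "thalamus_l", "thalamus_r",
             "white_matter_cb", "cerebellum", "vermis", "pons"]
    ids = {name: i for i, name in enumerate(names)}

    labels = np.zeros((n_slices, grid_size, grid_size), dtype=np.int16)
    n_cerebral = max(1, n_slices - 1) if n_slices > 1 else 1

    head = r < scalp_r
    skull = r < skull_r
    brain = r < brain_r

    def _rings(slc):
        slc[head] = ids["scalp"]
        slc[skull] = ids["skull"]

    for s in range(n_cerebral):
        slc = labels[s]
        _rings(slc)
        inner = 52.0 + 5.0 * np.sin(6 * theta + phase + 0.7 * s)
        slc[brain & (r < inner)] = ids["white_matter"]
        slc[brain & (r >= inner)] = ids["cortex"]
        for side, sx in (("l", 1.0), ("r", -1.0)):
            bg = ((x - sx * 24.0) / 13.0) ** 2 + ((y - 8.0) / 9.0) ** 2 <= 1.0
            th = ((x - sx * 11.0) / 9.0) ** 2 + ((y + 14.0) / 7.0) ** 2 <= 1.0
            slc[bg] = ids[f"basal_ganglia_{side}"]
            slc[th] = ids[f"thalamus_{side}"]

    if n_slices > 1:
        slc = labels[-1]  # infratentorial slice
        _rings(slc)
        slc[brain] = ids["white_matter_cb"]
        cereb = brain & (y < -5.0) & (r >= 35.0) & (r <= 72.0)
        slc[cereb] = ids["cerebellum"]
        vermis = brain & (np.abs(x) <= 11.0) & (y <= -25.0)
        slc[vermis] = ids["vermis"]
        pons = (x / 13.0) ** 2 + ((y - 12.0) / 10.0) ** 2 <= 1.0
        slc[pons] = ids["pons"]

    present = set(np.unique(labels).tolist())
    for required in ("cortex", "white_matter", "skull", "scalp"):
        if ids[required] not in present:
            raise ValueError(f"grid too small: structure '{required}' is empty")

    compartment = {"background": "background", "scalp": "scalp", "skull": "skull"}
    compartment.update({n: "white" for n in _WM_STRUCTURES})
    compartment.update({n: "gray" for n in _GM_STRUCTURES})

    f_gm = float(constants.cbf_to_flow(gm_cbf))
    f_wm = float(constants.cbf_to_flow(wm_cbf))
    f_gm_a = float(constants.cbf_to_flow(gm_cbf_acz))
    f_wm_a = float(constants.cbf_to_flow(wm_cbf_acz))
    f_rest = {n: f_gm for n in _GM_STRUCTURES}
    f_rest.update({n: f_wm for n in _WM_STRUCTURES})
    f_acz = {n: f_gm_a for n in _GM_STRUCTURES}
    f_acz.update({n: f_wm_a for n in _WM_STRUCTURES})

    mu = {n: _MU_TRUE["brain"] for n in _GM_STRUCTURES + _WM_STRUCTURES}
    mu["skull"] = _MU_TRUE["skull"]
    mu["scalp"] = _MU_TRUE["scalp"]

    return PhantomSpec(labels=labels, structures=ids, compartment_of=compartment,
                       spacing_mm=(spacing_mm, spacing_mm, spacing_mm),
                       mu_cm=mu, f_rest=f_rest, f_acz=f_acz)


def make_cylinder_phantom(diameter_mm: float = 160.0, activity_bqml: float = 50_000.0,
                          shape: str = "disc", grid_size: int = 96,
                          spacing_mm: float = 2.5, n_slices: int = 1) -> PhantomSpec:
    """Calibration phantom: uniform cylinder slice, centred line, or point.

    ``disc`` is a water-filled uniform cylinder of the given inner
    diameter; ``line``/``point`` are a single hot voxel at the centre of
    every slice (a line source along the axis), without surrounding water.
    """
    if shape not in ("disc", "line", "point"):
        raise ValueError(f"unknown phantom shape {shape!r}")
    if activity_bqml < 0:
        raise ValueError("activity must be non-negative")
    if shape == "disc" and diameter_mm > grid_size * spacing_mm - 4 * spacing_mm:
        raise ValueError("cylinder does not fit the grid")
    x, y, r = _grid_coords(grid_size, spacing_mm)
    labels = np.zeros((n_slices, grid_size, grid_size), dtype=np.int16)
    ids = {"background": 0, "source": 1}
    if shape == "disc":
        labels[:, r <= diameter_mm / 2.0] = 1
        if activity_bqml == 0 and not (labels == 1).any():
            raise ValueError("empty cylinder mask")
    else:
        c = grid_size // 2
        labels[:, c, c] = 1
        if shape == "point":
            labels[1:, c, c] = 0  # single voxel only
            labels[0, c, c] = 1
    return PhantomSpec(labels=labels,
                       structures=ids,
                       compartment_of={"background": "background", "source": "gray"},
                       spacing_mm=(spacing_mm, spacing_mm, spacing_mm),
                       mu_cm={"source": _MU_TRUE["water"] if shape == "disc" else 0.0},
                       activity_bqml={"source": float(activity_bqml)})


# ---------------------------------------------------------------------------
# input function and kinetics
# ---------------------------------------------------------------------------

# population-standard whole-blood curve: gamma-variate first pass plus a
# slowly clearing recirculation tail.  The shape is a synthetic stand-in
# for the (unpublished) population curve; it is identical for every
# simulated subject and scales linearly with injected dose.
_IF_PEAK_MIN = 1.5
_IF_TAIL_RISE_MIN = 2.0
_IF_TAIL_FAST_MIN = 25.0
_IF_TAIL_SLOW_MIN = 300.0
_IF_TAIL_FAST_W = 0.55
_IF_FIRSTPASS_AMPL = 2.2
_IF_BQML_PER_MBQ_AT_10MIN = 50.0


def _input_shape(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, float)
    tt = np.clip(t, 0.0, None)
    g = (tt / _IF_PEAK_MIN) ** 2 * np.exp(2.0 * (1.0 - tt / _IF_PEAK_MIN))
    tail = (1.0 - np.exp(-tt / _IF_TAIL_RISE_MIN)) * (
        _IF_TAIL_FAST_W * np.exp(-tt / _IF_TAIL_FAST_MIN)
        + (1.0 - _IF_TAIL_FAST_W) * np.exp(-tt / _IF_TAIL_SLOW_MIN))
    s = _IF_FIRSTPASS_AMPL * g + tail
    return np.where(t < 0.0, 0.0, s)


def standard_input_function(dose_mbq: float,
                            schedule: AcquisitionSchedule | None = None,
                            t_max_min: float = 60.0,
                            dt_min: float = 0.05) -> InputFunction:
    """Population-standard arterial whole-blood curve scaled by dose.

    The curve is normalised so its 10-min value is
    ``_IF_BQML_PER_MBQ_AT_10MIN`` Bq/mL per MBq injected, a typical
    whole-blood level for this tracer, and is strictly positive there.
    """
    if dose_mbq <= 0:
        raise ValueError("dose must be positive")
    t = np.arange(0.0, t_max_min + dt_min / 2, dt_min)
    norm = _IF_BQML_PER_MBQ_AT_10MIN / _input_shape(np.array([10.0]))[0]
    return InputFunction(t, dose_mbq * norm * _input_shape(t), dose_mbq)


def tissue_tac_batch(flows: np.ndarray, vd: float, input_fn: InputFunction,
                     time_grid: np.ndarray, dt_min: float = 1.0 / 60.0) -> np.ndarray:
    """One-tissue-compartment curves for many flows at once.

    Integrates ``dCt/dt = f Ca(t) - (f/Vd) Ct`` with an exponential
    (integrating-factor) update on an internal grid of step ``dt_min``
    (default 1 s); returns shape ``(len(flows), len(time_grid))`` in Bq/mL.
    """
    flows = np.atleast_1d(np.asarray(flows, float))
    if np.any(flows < 0):
        raise ValueError("flow must be non-negative")
    if vd <= 0:
        raise ValueError("Vd must be positive")
    time_grid = np.asarray(time_grid, float)
    t_end = float(time_grid.max()) if time_grid.size else 0.0
    nt = max(2, int(np.ceil(t_end / dt_min)) + 1)
    tg = np.linspace(0.0, t_end, nt)
    dt = tg[1] - tg[0]
    ca = input_fn(tg)
    k = flows / vd
    decay = np.exp(-k * dt)                       # (nf,)
    ct = np.zeros((flows.size, nt))
    half = 0.5 * dt
    for i in range(1, nt):
        ct[:, i] = ct[:, i - 1] * decay + flows * half * (ca[i - 1] * decay + ca[i])
    # internal grid is uniform: interpolate by index arithmetic
    pos = np.clip(time_grid, 0.0, t_end) / dt
    i0 = np.clip(pos.astype(int), 0, nt - 2)
    frac = pos - i0
    out = ct[:, i0] * (1.0 - frac) + ct[:, i0 + 1] * frac
    return np.where(time_grid[None, :] < 0.0, 0.0, out)


def tissue_tac(f: float, vd: float, input_fn: InputFunction,
               time_grid: np.ndarray, dt_min: float = 1.0 / 60.0) -> np.ndarray:
    """One-tissue-compartment tissue curve for a single flow value."""
    return tissue_tac_batch(np.array([f]), vd, input_fn, time_grid, dt_min)[0]


def window_mean_tac(flows: np.ndarray, vd: float, input_fn: InputFunction,
                    window: tuple[float, float], dt_min: float = 1.0 / 60.0) -> np.ndarray:
    """Mean tissue activity over ``window`` for each flow (used by the
    look-up tables and by background prediction)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    nt = max(2, int(np.ceil((t1 - t0) / dt_min)) + 1)
    grid = np.linspace(t0, t1, nt)
    curves = tissue_tac_batch(flows, vd, input_fn, grid, dt_min)
    return np.trapezoid(curves, grid, axis=1) / (t1 - t0)


def _batch_ode(flows_t: np.ndarray, ca: np.ndarray, vd: float, dt: float) -> np.ndarray:
    """Integrating-factor recursion for dCt/dt = f(t) Ca - (f(t)/Vd) Ct with
    per-structure, possibly time-varying, flows ``flows_t`` of shape
    (n_struct, nt)."""
    n_struct, nt = flows_t.shape
    ct = np.zeros((n_struct, nt))
    half = 0.5 * dt
    for i in range(1, nt):
        f = flows_t[:, i]
        decay = np.exp(-f / vd * dt)
        ct[:, i] = ct[:, i - 1] * decay + f * half * (ca[i - 1] * decay + ca[i])
    return ct


def _frame_weights(phantom: PhantomSpec, schedule: AcquisitionSchedule,
                   constants: KineticConstants, input1: InputFunction,
                   input2: InputFunction, acz_onset_min: float | None,
                   dt_min: float = 1.0 / 60.0) -> dict[str, np.ndarray]:
    """Frame-mean tissue activity (Bq/mL) per structure over both scans.

    First-injection tracer follows the rest flow for the whole session
    (the background-subtraction model's assumption); pass a finite
    ``acz_onset_min`` to switch its flow to the challenge value from that
    time on.  Second-injection tracer always uses the challenge flow.
    """
    names = [n for n in phantom.structures
             if phantom.f_rest.get(n, 0.0) > 0 or phantom.f_acz.get(n, 0.0) > 0]
    if not names:
        return {}
    fr = np.array([phantom.f_rest.get(n, 0.0) for n in names])
    fa = np.array([phantom.f_acz.get(n, 0.0) for n in names])

    t_end = schedule.scan2_end
    nt = int(round(t_end / dt_min)) + 1
    tg = np.linspace(0.0, t_end, nt)
    dt = tg[1] - tg[0]

    flows1 = np.repeat(fr[:, None], nt, axis=1)
    if acz_onset_min is not None:
        flows1[:, tg >= acz_onset_min] = fa[:, None]
    c1 = _batch_ode(flows1, input1(tg), constants.vd, dt)

    nt2 = int(round((t_end - schedule.inj2_min) / dt_min)) + 1
    tg2 = np.linspace(0.0, t_end - schedule.inj2_min, nt2)
    c2 = _batch_ode(np.repeat(fa[:, None], nt2, axis=1), input2(tg2),
                    constants.vd, tg2[1] - tg2[0])

    def window_mean(curve, grid, t0, t1):
        lo = np.searchsorted(grid, t0 - 1e-9)
        hi = np.searchsorted(grid, t1 + 1e-9) - 1
        return np.trapezoid(curve[:, lo:hi + 1], grid[lo:hi + 1], axis=1) / (t1 - t0)

    starts = schedule.frame_starts()
    durations = schedule.frame_durations()
    w = np.zeros((len(names), len(starts)))
    for i, (t0, d) in enumerate(zip(starts, durations)):
        w[:, i] = window_mean(c1, tg, t0, t0 + d)
        if t0 + d > schedule.inj2_min + 1e-9:
            a0 = max(t0 - schedule.inj2_min, 0.0)
            a1 = t0 + d - schedule.inj2_min
            w[:, i] += (a1 - a0) / d * window_mean(c2, tg2, a0, a1)
    return {n: w[k] for k, n in enumerate(names)}


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------

_PROJ_CACHE: dict = {}


def intrinsic_blur_fwhm(profile_fwhm_mm: float,
                        post_filter_mm: float = POST_FILTER_FWHM_MM) -> float:
    """System blur applied before projection so that the *reconstructed*
    image (which adds the post filter) ends up at the profile's nominal
    resolution: sqrt(max(FWHM^2 - post^2, 0))."""
    return float(np.sqrt(max(profile_fwhm_mm ** 2 - post_filter_mm ** 2, 0.0)))


def _phantom_key(phantom: PhantomSpec, blur_mm: float, geometry: Geometry) -> tuple:
    h = hashlib.sha1()
    h.update(phantom.labels.tobytes())
    h.update(repr(sorted(phantom.mu_cm.items())).encode())
    return (h.hexdigest(), phantom.spacing_mm, round(blur_mm, 6), geometry)


def _structure_projections(phantom: PhantomSpec, blur_mm: float,
                           geometry: Geometry):
    """Attenuated projections of each (blurred) structure mask, plus the
    true-attenuation transmission sinogram.  Cached: within a cohort the
    same phantom geometry is reused by every subject."""
    key = _phantom_key(phantom, blur_mm, geometry)
    if key in _PROJ_CACHE:
        return _PROJ_CACHE[key]
    spacing = phantom.spacing_mm[-1]
    sigma = blur_mm * FWHM_TO_SIGMA / spacing
    mu_true = phantom.mu_map_true()
    projections = {}
    for name in phantom.structures:
        m = phantom.mask(name).astype(float)
        if not m.any() or name in ("background",):
            continue
        if sigma > 0:
            m = np.stack([ndimage.gaussian_filter(m[s], sigma)
                          for s in range(m.shape[0])])
        img = ImageVolume(m, phantom.spacing_mm)
        projections[name] = project_slices(img, geometry, mu_true)
    trans = transmission_sinogram(mu_true.data, geometry, spacing)
    result = (projections, trans)
    _PROJ_CACHE[key] = result
    return result


def _scatter_fixed_point(primary: np.ndarray, sf: np.ndarray,
                         kernel: np.ndarray, n_iter: int = 14) -> np.ndarray:
    """Observed photopeak counts P solving P = primary + SF * (P (*) g).

    The scatter fraction SF (per view/bin, against *observed* counts)
    contracts the iteration since SF < 1."""
    p = primary.copy()
    for _ in range(n_iter):
        conv = ndimage.convolve1d(p, kernel, axis=-1, mode="constant")
        p = primary + sf * conv
    return p


def scatter_kernel(decay_mm: float, bin_mm: float, half_width_mm: float = 60.0) -> np.ndarray:
    """Unit-area symmetric mono-exponential convolution kernel."""
    half = max(1, int(round(half_width_mm / bin_mm)))
    d = np.arange(-half, half + 1) * bin_mm
    k = np.exp(-np.abs(d) / decay_mm)
    return k / k.sum()


def _expected_sinograms(phantom: PhantomSpec, profile: InstitutionProfile,
                        geometry: Geometry, weights: dict, durations: np.ndarray,
                        scatter: bool, offset: bool):
    """Expected (pre-noise) counts per frame from per-structure frame
    weights (Bq/mL), plus the scatter-free primaries for oracle tests."""
    blur = intrinsic_blur_fwhm(profile.fwhm_mm)
    projections, trans = _structure_projections(phantom, blur, geometry)
    eps = COUNT_SENSITIVITY / profile.bcf
    n_frames = len(durations)
    shape = (n_frames,) + trans.shape
    primary = np.zeros(shape)
    for name, w in weights.items():
        if name not in projections:
            continue
        primary += w[:, None, None, None] * projections[name][None]
    primary *= eps * durations[:, None, None, None]
    observed = primary
    if scatter:
        sf = profile.scatter.fraction(trans)[None]
        kern = scatter_kernel(profile.scatter.kernel_decay_mm, geometry.bin_mm)
        observed = _scatter_fixed_point(primary, sf, kern)
    if offset:
        frac = profile.scatter.penetration_offset_fraction
        mean_counts = observed.mean(axis=(2, 3), keepdims=True)
        observed = observed + frac * mean_counts
    return observed, primary


def simulate_static_scan(phantom: PhantomSpec, profile: InstitutionProfile,
                         duration_min: float, seed: int | None = None,
                         geometry: Geometry | None = None, noise: bool = True,
                         scatter: bool = True, offset: bool = True) -> ProjectionSet:
    """Single-frame scan of a static phantom (calibration experiments and
    the resolution-measurement phantom scan)."""
    if geometry is None:
        geometry = Geometry(60, phantom.labels.shape[-1], phantom.spacing_mm[-1])
    act = phantom.activity_bqml
    if not act:
        raise ValueError("static scan needs a phantom with fixed activities")
    weights = {name: np.array([float(v)]) for name, v in act.items()}
    observed, _ = _expected_sinograms(phantom, profile, geometry, weights,
                                      np.array([duration_min]), scatter, offset)
    data = observed
    if noise:
        rng = np.random.default_rng(seed)
        data = rng.poisson(np.clip(observed, 0, None)).astype(float)
    return ProjectionSet(data[0][None], geometry, np.array([0.0]),
                         np.array([duration_min]))


def simulate_dual_injection_study(phantom: PhantomSpec, profile: InstitutionProfile,
                                  schedule: AcquisitionSchedule, seed: int | None = None,
                                  geometry: Geometry | None = None,
                                  constants: KineticConstants = KineticConstants(),
                                  noise: bool = True, scatter: bool = True,
                                  offset: bool = True,
                                  acz_onset_min: float | None = None,
                                  return_truth: bool = False):
    """Dual-injection dynamic study: two 7-frame sinogram sets plus the
    true well-counter blood sample.

    Kinetics: each structure follows the one-tissue model; activity from
    the first injection continues with the rest-phase flow for the whole
    58-min session (the background-model assumption), while the second
    injection's response uses the challenge flow.  A finite
    ``acz_onset_min`` instead switches the first injection's flow to the
    challenge value from that time on, to probe the assumption.
    """
    schedule.validate()
    if geometry is None:
        geometry = Geometry(60, phantom.labels.shape[-1], phantom.spacing_mm[-1])
    if acz_onset_min is not None and acz_onset_min < schedule.acz_min:
        raise ValueError("challenge flows cannot start before the vasodilator")

    input1 = standard_input_function(schedule.dose1_mbq)
    input2 = standard_input_function(schedule.dose2_mbq)

    starts = schedule.frame_starts()
    durations = schedule.frame_durations()
    weights = _frame_weights(phantom, schedule, constants, input1, input2,
                             acz_onset_min)

    observed, primary = _expected_sinograms(phantom, profile, geometry, weights,
                                            durations, scatter, offset)
    data = observed
    if noise:
        rng = np.random.default_rng(seed)
        data = rng.poisson(np.clip(observed, 0, None)).astype(float)

    n1 = schedule.n_frames_per_scan
    rest = ProjectionSet(data[:n1], geometry, starts[:n1], durations[:n1])
    acz = ProjectionSet(data[n1:], geometry, starts[n1:], durations[n1:])
    sample = simulate_blood_sample(input1, schedule.sample_min, profile.ccf)
    if return_truth:
        truth = {"primary": primary, "observed_mean": observed,
                 "weights": weights, "input1": input1, "input2": input2}
        return rest, acz, sample, truth
    return rest, acz, sample


def simulate_blood_sample(input_fn: InputFunction, t_min: float, ccf: float) -> float:
    """Well-counter reading of the calibration blood sample:
    Ca(t) expressed in well units via the cross-calibration factor."""
    return float(input_fn(np.array([t_min]))[0] * ccf)
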
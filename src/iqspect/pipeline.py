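"""End-to-end study orchestration.

Per subject: simulate the dual-injection acquisition, reconstruct the
summed study windows quantitatively, calibrate the input function from
the blood sample, run the DTARG CBF estimation, and extract ROI means.
Per institution: calibrate BCF/CCF from phantom experiments, measure the
reconstructed resolution against the digital phantom, and run a cohort.
Across institutions: equalize resolution to the worst scanner, rebuild
the ROI tables, and run the inter-institution statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics as kin
from . import recon as rc
from . import resolution as res
from . import stats as st
from .core import (AcquisitionSchedule, CalibrationFactors, Geometry,
                   ImageVolume, InstitutionProfile, KineticConstants,
                   PhantomSpec, ProjectionSet)
from .phantoms import (intrinsic_blur_fwhm, make_brain_phantom,
                       make_cylinder_phantom, simulate_dual_injection_study,
                       simulate_static_scan, standard_input_function)

__all__ = [
    "StudyConfig",
    "calibrate_institution",
    "measure_institution_fwhm",
    "reconstruct_window",
    "run_subject",
    "run_institution_study",
    "run_multicenter_comparison",
    "GM_ANCHOR_EROSION_MM",
]

#: in-plane erosion (mm) of the truth GM mask used for global-CBF
#: anchoring and recovery ROIs: resolution-scale, so sampling stays in
#: territory cores away from tissue boundaries.
GM_ANCHOR_EROSION_MM = 7.5

#: inter-subject variability (coefficients of variation) of global CBF
#: and of the challenge/rest flow ratio; the first matches the ~16%
#: inter-subject CBF spread of healthy adults, the second reproduces a
#: realistic spread of reactivity.
SUBJECT_CV_GLOBAL = 0.16
SUBJECT_CV_REACTIVITY = 0.125

_BRAIN_THRESHOLD = 0.5        # emission-edge fraction (half-maximum rule)
_HEAD_MARGIN_MM = 11.0        # skull+scalp thickness outside the brain edge
_PHANTOM_THRESHOLD = 0.5      # emission-edge fraction for uniform phantoms


@dataclass
class StudyConfig:
    """One multicenter run: institutions, cohort sizes, phantom grid,
    seeds, and the resolution-equalization toggle."""

    profiles: list[InstitutionProfile]
    n_subjects: list[int] | None = None      # default: each profile's enrolment
    grid_size: int = 96
    spacing_mm: float = 2.5
    n_slices: int = 3
    seed: int = 0
    noise: bool = True
    equalize: bool = True
    include_native: bool = True
    #: scan the *same* simulated subjects at every institution (the
    #: matched-cohort null design: differences then reflect the scanners,
    #: not cohort sampling); False draws independent cohorts per
    #: institution, as in the enrolment of a real study.
    matched_cohorts: bool = False
    subject_cv_global: float = SUBJECT_CV_GLOBAL
    subject_cv_reactivity: float = SUBJECT_CV_REACTIVITY
    constants: KineticConstants = field(default_factory=KineticConstants)

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("need at least one institution profile")
        if self.n_subjects is not None and len(self.n_subjects) != len(self.profiles):
            raise ValueError("n_subjects must match the profile list")

    def cohort_sizes(self) -> list[int]:
        if self.n_subjects is not None:
            return list(self.n_subjects)
        return [p.n_subjects for p in self.profiles]


def _geometry(phantom: PhantomSpec, n_views: int = 60) -> Geometry:
    return Geometry(n_views, phantom.labels.shape[-1], phantom.spacing_mm[-1])


def reconstruct_window(proj: ProjectionSet, t0: float, t1: float,
                       mu_map, profile: InstitutionProfile,
                       calib: CalibrationFactors,
                       source_mask=None) -> ImageVolume:
    """Quantitative image (Bq/mL) of the counts summed over [t0, t1]."""
    summed = proj.summed(t0, t1)
    corr = rc.tdcs_scatter_correct(summed, mu_map, proj.geometry, profile.scatter)
    img = rc.osem_reconstruct(corr, mu_map, proj.geometry, source_mask=source_mask)
    img.data *= calib.bcf / float(summed.frame_durations_min[0])
    img.unit = "Bq/mL"
    return img


def calibrate_institution(profile: InstitutionProfile, grid_size: int = 96,
                          spacing_mm: float = 2.5, seed: int = 12345,
                          noise: bool = True,
                          n_repeats: int = 3) -> CalibrationFactors:
    """Phantom calibration experiments: BCF from a known-activity syringe
    and CCF from the uniform 16-cm cylinder counted in the well counter.

    Repeated experiments are averaged (calibration should contribute
    negligible error to the clinical chain; a single noisy run leaves a
    fixed ~1% systematic on everything downstream)."""
    syringe_act = 200_000.0
    cyl_act = 50_000.0
    duration = 60.0   # calibration scans are long/high-count by design

    def chain(phantom, sd):
        proj = simulate_static_scan(phantom, profile, duration, seed=sd,
                                    geometry=_geometry(phantom), noise=noise)
        fbp = rc.reconstruct_uncorrected(proj, proj.geometry)
        mu = rc.estimate_mu_map(fbp, _PHANTOM_THRESHOLD)
        corr = rc.tdcs_scatter_correct(proj, mu, proj.geometry, profile.scatter)
        img = rc.osem_reconstruct(corr, mu, proj.geometry)
        img.data /= duration
        return img

    syr = make_cylinder_phantom(30.0, syringe_act, "disc", grid_size, spacing_mm)
    cyl = make_cylinder_phantom(160.0, cyl_act, "disc", grid_size, spacing_mm)
    core = kin.core_mask(cyl.mask("source"), spacing_mm, 10.0)
    well_value = cyl_act * profile.ccf  # well counter reading of an aliquot
    bcfs, ccfs = [], []
    for rep in range(n_repeats if noise else 1):
        bcf = rc.calibrate_bcf(chain(syr, seed + 2 * rep), syringe_act,
                               syr.mask("source"))
        img = chain(cyl, seed + 2 * rep + 1)
        img.data *= bcf
        bcfs.append(bcf)
        ccfs.append(rc.calibrate_ccf(img, well_value, core))
    return CalibrationFactors(bcf=float(np.mean(bcfs)), ccf=float(np.mean(ccfs)))


def measure_institution_fwhm(profile: InstitutionProfile, phantom: PhantomSpec,
                             calib: CalibrationFactors, seed: int = 54321,
                             noise: bool = True, n_repeats: int = 5) -> float:
    """Resolution experiment: scan the GM-filled digital brain phantom,
    reconstruct as for clinical data, and estimate the FWHM against the
    digital design; repeated acquisitions are averaged and a dedicated
    many-slice phantom is used (more independent cortical-fold spectra),
    since a single noisy 3-slice estimate of a 17-mm system scatters by
    a couple of mm."""
    gm_act = 30_000.0
    resol = make_brain_phantom(phantom.labels.shape[-1], phantom.spacing_mm[-1],
                               seed=7, n_slices=9)
    filled = PhantomSpec(
        labels=resol.labels, structures=resol.structures,
        compartment_of=resol.compartment_of, spacing_mm=resol.spacing_mm,
        mu_cm=resol.mu_cm,
        activity_bqml={n: gm_act for n, c in resol.compartment_of.items()
                       if c == "gray"})
    duration = 28.0
    reference = filled.activity_map()
    imgs = []
    for rep in range(n_repeats if noise else 1):
        proj = simulate_static_scan(filled, profile, duration, seed=seed + rep,
                                    geometry=_geometry(phantom), noise=noise)
        fbp = rc.reconstruct_uncorrected(proj, proj.geometry)
        emission = rc.estimate_mu_map(fbp, _BRAIN_THRESHOLD).mask
        mu = rc.estimate_mu_map(fbp, _BRAIN_THRESHOLD, _HEAD_MARGIN_MM)
        corr = rc.tdcs_scatter_correct(proj, mu, proj.geometry, profile.scatter)
        imgs.append(rc.osem_reconstruct(corr, mu, proj.geometry,
                                        source_mask=emission))
    mean_img = imgs[0].like(np.mean([im.data for im in imgs], axis=0))
    noise_power = None
    if noise and len(imgs) > 1:
        # annular noise power of the *mean* image, measured from the
        # repeat-to-repeat differences
        n_rep = len(imgs)
        acc = None
        for im in imgs:
            _, p_d, _ = res._radial_power(im.data - mean_img.data,
                                          mean_img.pixel_mm)
            acc = p_d if acc is None else acc + p_d
        noise_power = acc / (n_rep * (n_rep - 1))
    return res.estimate_fwhm(mean_img, reference,
                             noise_power=noise_power).fwhm_mm


def run_subject(phantom: PhantomSpec, profile: InstitutionProfile,
                schedule: AcquisitionSchedule, calib: CalibrationFactors,
                seed: int, constants: KineticConstants = KineticConstants(),
                noise: bool = True, equalize_fwhm_mm: float = 0.0,
                gm_mask: np.ndarray | None = None) -> dict:
    """Simulate, reconstruct and quantify one subject.

    Returns rest/challenge CBF and CVR images plus provenance (global
    CBF, table scale, calibration).  ``equalize_fwhm_mm`` is the
    additional resolution-equalization filter applied to the
    reconstructed images before CBF calculation.
    """
    rest, acz, sample = simulate_dual_injection_study(
        phantom, profile, schedule, seed=seed, geometry=_geometry(phantom),
        constants=constants, noise=noise)

    fbp = rc.reconstruct_uncorrected(rest.summed(), rest.geometry)
    emission = rc.estimate_mu_map(fbp, _BRAIN_THRESHOLD).mask
    mu = rc.estimate_mu_map(fbp, _BRAIN_THRESHOLD, _HEAD_MARGIN_MM)

    mean_0_28 = reconstruct_window(rest, schedule.inj1_min, schedule.scan1_end,
                                   mu, profile, calib, emission)
    frame_24_28 = reconstruct_window(rest, schedule.scan1_end - 4.0,
                                     schedule.scan1_end, mu, profile, calib,
                                     emission)
    mean_30_58 = reconstruct_window(acz, schedule.inj2_min, schedule.scan2_end,
                                    mu, profile, calib, emission)
    if equalize_fwhm_mm > 0:
        mean_0_28 = res.equalize_resolution(mean_0_28, equalize_fwhm_mm)
        frame_24_28 = res.equalize_resolution(frame_24_28, equalize_fwhm_mm)
        mean_30_58 = res.equalize_resolution(mean_30_58, equalize_fwhm_mm)

    std1 = standard_input_function(schedule.dose1_mbq)
    input1 = kin.calibrate_input_function(std1, sample, calib.ccf,
                                          schedule.sample_min)
    cal_factor = input1.values_bqml.max() / max(std1.values_bqml.max(), 1e-30)
    input2 = standard_input_function(schedule.dose2_mbq).scaled(cal_factor)

    if gm_mask is None:
        gm_mask = kin.core_mask(phantom.gm_mask, phantom.spacing_mm[-1],
                                GM_ANCHOR_EROSION_MM)
    head_mask = mu.mask

    rest_res = kin.compute_rest_cbf(mean_0_28, frame_24_28, input1, constants,
                                    gm_mask, head_mask)
    background = kin.predict_background(rest_res.cbf, input1, constants,
                                        (schedule.inj2_min, schedule.scan2_end),
                                        scale=rest_res.scale)
    acz_res = kin.compute_acz_cbf(mean_30_58, background, input2, constants,
                                  head_mask, scale=rest_res.scale)
    cvr = kin.compute_cvr(rest_res.cbf, acz_res.cbf)
    return {
        "rest_cbf": rest_res.cbf, "acz_cbf": acz_res.cbf, "cvr": cvr,
        "global_cbf": rest_res.global_cbf, "scale": rest_res.scale,
        "mu_map": mu, "gm_mask": gm_mask, "blood_sample": sample,
        "images": {"mean_0_28": mean_0_28, "frame_24_28": frame_24_28,
                   "mean_30_58": mean_30_58},
        "input1": input1, "input2": input2,
    }


def _subject_rows(result: dict, rois: st.ROISet, institution: str,
                  subject: int) -> list[dict]:
    rows = []
    for cond, key in (("rest", "rest_cbf"), ("acz", "acz_cbf")):
        df = st.roi_means(result[key], rois)
        for _, r in df.iterrows():
            rows.append({"institution": institution, "subject": subject,
                         "region": r.region, "condition": cond,
                         "cbf": r["mean"]})
    return rows


def run_institution_study(profile: InstitutionProfile, n_subjects: int,
                          seed: int, phantom: PhantomSpec | None = None,
                          schedule: AcquisitionSchedule | None = None,
                          calib: CalibrationFactors | None = None,
                          rois: st.ROISet | None = None,
                          constants: KineticConstants = KineticConstants(),
                          noise: bool = True, equalize_fwhm_mm: float = 0.0,
                          subject_cv_global: float = SUBJECT_CV_GLOBAL,
                          subject_cv_reactivity: float = SUBJECT_CV_REACTIVITY,
                          subject_factors: list[tuple[float, float]] | None = None,
                          keep_images: bool = False) -> tuple[pd.DataFrame, list]:
    """Cohort of one institution: per-subject flow variability (log-normal
    on global flow and on the challenge ratio), full per-subject pipeline,
    ROI rows.  Fully reproducible given the seed.

    ``subject_factors`` fixes the per-subject (global, reactivity)
    multipliers instead of drawing them — used by matched-cohort designs
    where the same simulated subjects are scanned on every scanner.
    """
    if phantom is None:
        phantom = make_brain_phantom()
    if schedule is None:
        schedule = AcquisitionSchedule(dose1_mbq=profile.imp_dose_mbq,
                                       dose2_mbq=profile.imp_dose_mbq)
    if calib is None:
        calib = calibrate_institution(profile, phantom.labels.shape[-1],
                                      phantom.spacing_mm[-1], noise=noise)
    if rois is None:
        rois = st.make_roi_template(phantom, erosion_mm=5.0)
    rng = np.random.default_rng(seed)
    sigma_g = np.sqrt(np.log(1 + subject_cv_global ** 2))
    sigma_r = np.sqrt(np.log(1 + subject_cv_reactivity ** 2))
    rows: list[dict] = []
    images = []
    for subj in range(n_subjects):
        if subject_factors is not None:
            u, v = subject_factors[subj]
        else:
            u = float(np.exp(rng.normal(-sigma_g ** 2 / 2, sigma_g))) if subject_cv_global > 0 else 1.0
            v = float(np.exp(rng.normal(-sigma_r ** 2 / 2, sigma_r))) if subject_cv_reactivity > 0 else 1.0
        subject_phantom = phantom.with_flow_scale(u, u * v)
        subj_seed = int(rng.integers(0, 2 ** 31 - 1))
        try:
            result = run_subject(subject_phantom, profile, schedule, calib,
                                 seed=subj_seed, constants=constants,
                                 noise=noise, equalize_fwhm_mm=equalize_fwhm_mm)
        except Exception as exc:  # pragma: no cover - diagnostic context
            raise RuntimeError(
                f"institution {profile.name}, subject {subj}: {exc}") from exc
        rows.extend(_subject_rows(result, rois, profile.name, subj))
        if keep_images:
            images.append(result)
    return pd.DataFrame(rows), images


def run_multicenter_comparison(config: StudyConfig,
                               calibrations: list | None = None,
                               measured_fwhms: list | None = None) -> dict:
    """Full multicenter run.

    Simulates each institution's cohort from a common phantom truth,
    measures each scanner's reconstructed resolution, equalizes all
    cohorts to the worst resolution (largest FWHM), and produces
    Table-style summaries plus pairwise tests (t, Mann-Whitney,
    Steel-Dwass) per region and condition, with and without
    equalization.
    """
    phantom = make_brain_phantom(config.grid_size, config.spacing_mm,
                                 seed=config.seed, n_slices=config.n_slices)
    rois = st.make_roi_template(phantom, erosion_mm=5.0)
    sizes = config.cohort_sizes()

    calibs = calibrations
    if calibs is None:
        calibs = [calibrate_institution(p, config.grid_size, config.spacing_mm,
                                        seed=10_000 + 17 * i, noise=config.noise)
                  for i, p in enumerate(config.profiles)]
    fwhms = measured_fwhms
    if fwhms is None:
        fwhms = [measure_institution_fwhm(p, phantom, c, seed=20_000 + 13 * i,
                                          noise=config.noise)
                 for i, (p, c) in enumerate(zip(config.profiles, calibs))]
    worst = max(fwhms)
    extra = [res.additional_fwhm(worst, f) for f in fwhms]

    out: dict = {"measured_fwhm_mm": dict(zip([p.name for p in config.profiles], fwhms)),
                 "target_fwhm_mm": worst,
                 "additional_fwhm_mm": dict(zip([p.name for p in config.profiles], extra))}

    variants = {"equalized": extra} if config.equalize else {}
    if config.include_native or not variants:
        variants["native"] = [0.0] * len(config.profiles)

    factors = None
    if config.matched_cohorts:
        rng = np.random.default_rng(config.seed + 777)
        sigma_g = np.sqrt(np.log(1 + config.subject_cv_global ** 2))
        sigma_r = np.sqrt(np.log(1 + config.subject_cv_reactivity ** 2))
        factors = [(float(np.exp(rng.normal(-sigma_g ** 2 / 2, sigma_g))),
                    float(np.exp(rng.normal(-sigma_r ** 2 / 2, sigma_r))))
                   for _ in range(max(sizes))]

    for label, extras in variants.items():
        tables = []
        for i, profile in enumerate(config.profiles):
            cohort, _ = run_institution_study(
                profile, sizes[i], seed=config.seed + 1000 * (i + 1),
                phantom=phantom, calib=calibs[i], rois=rois,
                constants=config.constants, noise=config.noise,
                equalize_fwhm_mm=extras[i],
                subject_cv_global=config.subject_cv_global,
                subject_cv_reactivity=config.subject_cv_reactivity,
                subject_factors=None if factors is None else factors[:sizes[i]])
            tables.append(cohort)
        cohort = pd.concat(tables, ignore_index=True)
        out[f"cohort_{label}"] = cohort
        out[f"summary_{label}"] = st.summary_table(cohort)
        if len(config.profiles) >= 3:
            out[f"tests_{label}"] = _institution_tests(cohort, config.profiles)
        elif len(config.profiles) >= 2:
            out[f"tests_{label}"] = _institution_tests(cohort, config.profiles,
                                                       steel=False)
        else:
            out[f"tests_{label}"] = None
            out["notice"] = "single institution: comparison skipped"
    return out


def _institution_tests(cohort: pd.DataFrame, profiles, steel: bool = True,
                       regions: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per region x condition: pairwise t / Mann-Whitney and Steel-Dwass
    adjusted p-values across institutions (bilateral-average regions)."""
    names = [p.name for p in profiles]
    if regions is None:
        regions = tuple(f"{r}_avg" for r in st.BILATERAL_REGIONS) + st.MIDLINE_REGIONS
    rows = []
    for region in regions:
        sub = cohort[cohort.region == region]
        if sub.empty:
            continue
        for cond in ("rest", "acz"):
            groups = [sub[(sub.institution == nm) & (sub.condition == cond)
                          ].sort_values("subject").cbf.to_numpy() for nm in names]
            sd = steel_p = None
            if steel and all(len(g) >= 3 for g in groups) and len(groups) >= 3:
                sd = st.steel_dwass(groups)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    t_stat, t_p, _ = st.group_compare(groups[i], groups[j],
                                                      "unpaired_t")
                    u_stat, u_p, _ = st.group_compare(groups[i], groups[j],
                                                      "mann_whitney")
                    if sd is not None:
                        steel_p = float(sd[(sd.group_i == i) & (sd.group_j == j)
                                           ].p_adjusted.iloc[0])
                    rows.append({"region": region, "condition": cond,
                                 "pair": f"{names[i]}-{names[j]}",
                                 "t_p": t_p, "mann_whitney_p": u_p,
                                 "steel_dwass_p": steel_p})
    return pd.DataFrame(rows)
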
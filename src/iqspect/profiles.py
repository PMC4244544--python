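"""Default institution profiles of the three-scanner study setup.

Spatial resolutions are those of the reconstructed images; BCF converts
reconstructed count rate to Bq/mL (smaller = more sensitive system);
CCF is the well-counter sensitivity relative to the SPECT images.
"""

from __future__ import annotations

from .core import InstitutionProfile, ScatterParams

__all__ = ["INSTITUTION_A", "INSTITUTION_B", "INSTITUTION_C", "default_profiles"]

_SCATTER = ScatterParams()

INSTITUTION_A = InstitutionProfile(
    name="A", fwhm_mm=17.13, bcf=87956.0, ccf=0.799,
    imp_dose_mbq=122.1, acz_dose_mg_kg=17.8, n_subjects=9, scatter=_SCATTER)

INSTITUTION_B = InstitutionProfile(
    name="B", fwhm_mm=11.22, bcf=72281.0, ccf=0.619,
    imp_dose_mbq=142.2, acz_dose_mg_kg=15.0, n_subjects=13, scatter=_SCATTER)

INSTITUTION_C = InstitutionProfile(
    name="C", fwhm_mm=10.26, bcf=112419.0, ccf=0.948,
    imp_dose_mbq=155.9, acz_dose_mg_kg=16.8, n_subjects=10, scatter=_SCATTER)


def default_profiles() -> list[InstitutionProfile]:
    return [INSTITUTION_A, INSTITUTION_B, INSTITUTION_C]
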
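"""Reading and writing the pipeline's on-disk formats.

Images travel as NIfTI with mm spacing in the header; sinograms as NIfTI
(frame, slice, view, bin) with a JSON sidecar carrying view angles and
frame timing; profiles and schedules as YAML; calibration and provenance
as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import (AcquisitionSchedule, Geometry, ImageVolume,
                   InstitutionProfile, ProjectionSet, ScatterParams)

__all__ = [
    "save_image", "load_image",
    "save_projections", "load_projections",
    "save_profile", "load_profile",
    "save_schedule", "load_schedule",
    "save_json", "load_json",
]


def save_image(image: ImageVolume, path: str | Path) -> None:
    # NIfTI axis order (x, y, z) <- our (slice, y, x)
    data = np.transpose(image.data, (2, 1, 0))
    affine = np.diag([image.spacing_mm[2], image.spacing_mm[1],
                      image.spacing_mm[0], 1.0])
    img = nib.Nifti1Image(np.asarray(data, np.float32), affine)
    img.header.set_zooms(tuple(float(s) for s in image.spacing_mm[::-1]))
    img.header["descrip"] = image.unit.encode()[:79]
    nib.save(img, str(path))


def load_image(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.transpose(np.asarray(img.dataobj, float), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    unit = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "arbitrary"
    return ImageVolume(data, (float(zooms[2]), float(zooms[1]), float(zooms[0])),
                       unit=unit)


def save_projections(proj: ProjectionSet, path: str | Path) -> None:
    """NIfTI volume (bin, view, slice, frame) + JSON sidecar."""
    path = Path(path)
    data = np.transpose(proj.data, (3, 2, 1, 0))
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), np.eye(4)), str(path))
    sidecar = {
        "angles_deg": proj.geometry.angles_deg.tolist(),
        "n_views": proj.geometry.n_views,
        "n_bins": proj.geometry.n_bins,
        "bin_mm": proj.geometry.bin_mm,
        "full_circle": proj.geometry.full_circle,
        "frame_starts_min": proj.frame_starts_min.tolist(),
        "frame_durations_min": proj.frame_durations_min.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_projections(path: str | Path) -> ProjectionSet:
    path = Path(path)
    data = np.transpose(np.asarray(nib.load(str(path)).dataobj, float),
                        (3, 2, 1, 0))
    meta = json.loads(path.with_suffix(".json").read_text())
    geo = Geometry(n_views=meta["n_views"], n_bins=meta["n_bins"],
                   bin_mm=meta["bin_mm"], full_circle=meta["full_circle"])
    return ProjectionSet(data, geo, np.array(meta["frame_starts_min"]),
                         np.array(meta["frame_durations_min"]))


def save_profile(profile: InstitutionProfile, path: str | Path) -> None:
    d = dataclasses.asdict(profile)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_profile(path: str | Path) -> InstitutionProfile:
    d = yaml.safe_load(Path(path).read_text())
    scatter = ScatterParams(**d.pop("scatter", {}))
    return InstitutionProfile(scatter=scatter, **d)


def save_schedule(schedule: AcquisitionSchedule, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(schedule),
                                         sort_keys=False))


def load_schedule(path: str | Path) -> AcquisitionSchedule:
    return AcquisitionSchedule(**yaml.safe_load(Path(path).read_text()))


def save_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
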
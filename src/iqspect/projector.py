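"""Attenuated parallel-beam projector shared by the simulator and the
reconstruction.

The projector is rotation-and-sum: for each view the image is resampled
onto a frame rotated so rays run along image rows towards the detector,
then summed over rows.  The resampling is bilinear and is materialised as
a sparse matrix, so ``back_project`` is the exact matrix transpose of the
unattenuated ``forward_project`` (adjoint to machine precision), which
OS-MLEM requires.

Attenuation follows the SPECT convention: each emission voxel is weighted
by ``exp(-integral of mu from that voxel to the detector)``, with a
half-voxel self-attenuation term.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .core import Geometry, ImageVolume, ProjectionSet

__all__ = ["forward_project", "project_slices", "back_project",
           "system_matrix", "transmission_sinogram", "geometry_for_image"]

# per-process cache of rotation operators / system matrices, keyed by
# (grid size, geometry); entries are small and reused constantly.
_CACHE: dict = {}


def geometry_for_image(image: ImageVolume, n_views: int = 60,
                       full_circle: bool = True) -> Geometry:
    n = image.data.shape[-1]
    return Geometry(n_views=n_views, n_bins=n, bin_mm=image.pixel_mm,
                    full_circle=full_circle)


def _check(image: ImageVolume, geometry: Geometry) -> int:
    n = image.data.shape[-1]
    if image.data.shape[-2] != n:
        raise ValueError("projector requires square slices")
    if geometry.n_bins != n:
        raise ValueError("geometry bin count must match the grid size")
    if abs(geometry.bin_mm - image.pixel_mm) > 1e-9:
        raise ValueError("geometry bin width must match the pixel size")
    return n


def _rotation_ops(n: int, angles_deg: tuple[float, ...]):
    """Bilinear gather indices/weights for each view angle.

    Returns per angle ``(idx, w)`` of shape (n*n, 4): output pixel k of the
    rotated frame samples ``sum(img.flat[idx[k]] * w[k])``.  Samples falling
    outside the grid get zero weight (activity is zero off-grid).
    """
    key = ("rot", n, angles_deg)
    if key in _CACHE:
        return _CACHE[key]
    c = (n - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))  # ii rows, jj cols
    x = jj.ravel() - c
    y = ii.ravel() - c
    ops = []
    for ang in angles_deg:
        th = np.deg2rad(ang)
        # rotate the sampling frame by -theta: view at angle theta sums the
        # image resampled on a frame rotated by theta.
        xs = np.cos(th) * x - np.sin(th) * y + c
        ys = np.sin(th) * x + np.cos(th) * y + c
        x0 = np.floor(xs).astype(np.int64)
        y0 = np.floor(ys).astype(np.int64)
        fx = xs - x0
        fy = ys - y0
        idx = np.empty((n * n, 4), np.int64)
        w = np.empty((n * n, 4), float)
        for q, (dy, dx) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            yi = y0 + dy
            xi = x0 + dx
            wq = (fy if dy else 1 - fy) * (fx if dx else 1 - fx)
            valid = (yi >= 0) & (yi < n) & (xi >= 0) & (xi < n)
            wq = np.where(valid, wq, 0.0)
            yi = np.clip(yi, 0, n - 1)
            xi = np.clip(xi, 0, n - 1)
            idx[:, q] = yi * n + xi
            w[:, q] = wq
        ops.append((idx, w))
    _CACHE[key] = ops
    return ops


def _rotate(slc: np.ndarray, op) -> np.ndarray:
    idx, w = op
    n = slc.shape[0]
    return (slc.ravel()[idx] * w).sum(axis=1).reshape(n, n)


def system_matrix(n: int, geometry: Geometry) -> sparse.csr_matrix:
    """Sparse unattenuated system matrix A: (n_views * n_bins) x (n * n).

    Row (v, b) holds the bilinear ray weights (times the step length in mm)
    of bin b at view v; ``A @ image.ravel()`` is the sinogram and ``A.T``
    its exact adjoint.
    """
    key = ("A", n, geometry)
    if key in _CACHE:
        return _CACHE[key]
    angles = tuple(geometry.angles_deg.tolist())
    ops = _rotation_ops(n, angles)
    dl = geometry.bin_mm
    bins = np.tile(np.arange(n), n)  # output pixel k = i*n + j -> bin j
    rows_all, cols_all, vals_all = [], [], []
    for v, (idx, w) in enumerate(ops):
        rows = (v * n + bins)[:, None].repeat(4, axis=1)
        rows_all.append(rows.ravel())
        cols_all.append(idx.ravel())
        vals_all.append((w * dl).ravel())
    A = sparse.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(geometry.n_views * n, n * n),
    ).tocsr()
    A.sum_duplicates()
    _CACHE[key] = A
    return A


def project_slices(image: ImageVolume, geometry: Geometry,
                   mu_map: ImageVolume | None = None) -> np.ndarray:
    """Attenuated (or plain) line integrals of every slice.

    With ``mu_map`` (cm^-1, same grid) each emission voxel is attenuated
    along its path to the detector; without it the result is the plain
    Radon transform.  Returns an array (n_slices, n_views, n_bins) in
    units of activity x mm.
    """
    n = _check(image, geometry)
    if mu_map is not None and mu_map.data.shape != image.data.shape:
        raise ValueError("image and mu-map grids differ")
    dl_mm = geometry.bin_mm
    dl_cm = dl_mm / 10.0
    out = np.empty((image.n_slices, geometry.n_views, n))
    if mu_map is None:
        A = system_matrix(n, geometry)
        for s in range(image.n_slices):
            out[s] = (A @ image.data[s].ravel()).reshape(geometry.n_views, n)
    else:
        ops = _rotation_ops(n, tuple(geometry.angles_deg.tolist()))
        for s in range(image.n_slices):
            act = image.data[s]
            mu = mu_map.data[s]
            for v, op in enumerate(ops):
                ract = _rotate(act, op)
                rmu = _rotate(mu, op)
                # path to the detector (beyond the last row): suffix sum of
                # mu minus half the voxel's own mu.
                suffix = np.cumsum(rmu[::-1], axis=0)[::-1]
                path = (suffix - 0.5 * rmu) * dl_cm
                out[s, v] = (ract * np.exp(-path)).sum(axis=0) * dl_mm
    return out


def forward_project(image: ImageVolume, geometry: Geometry,
                    mu_map: ImageVolume | None = None) -> ProjectionSet:
    """Single-frame :class:`ProjectionSet` of :func:`project_slices`."""
    sino = project_slices(image, geometry, mu_map)
    return ProjectionSet(sino[None], geometry, np.array([0.0]), np.array([1.0]))


def back_project(proj: ProjectionSet | np.ndarray, geometry: Geometry) -> ImageVolume:
    """Exact adjoint of the unattenuated forward projector.

    Accepts a (n_slices, n_views, n_bins) array or a single-frame
    :class:`ProjectionSet`.
    """
    if isinstance(proj, ProjectionSet):
        if proj.n_frames != 1:
            raise ValueError("back_project expects a single frame")
        data = proj.data[0]
    else:
        data = np.asarray(proj, float)
    if data.ndim == 2:
        data = data[None]
    n = geometry.n_bins
    if data.shape[1:] != (geometry.n_views, n):
        raise ValueError("sinogram shape does not match geometry")
    A = system_matrix(n, geometry)
    out = np.empty((data.shape[0], n, n))
    for s in range(data.shape[0]):
        out[s] = (A.T @ data[s].ravel()).reshape(n, n)
    return ImageVolume(out, (1.0, geometry.bin_mm, geometry.bin_mm))


def transmission_sinogram(mu_map: ImageVolume | "np.ndarray", geometry: Geometry,
                          spacing_mm: float | None = None) -> np.ndarray:
    """Full-chord photon transmission exp(-integral mu dl) per (slice, view, bin)."""
    if not isinstance(mu_map, ImageVolume):
        mu_map = ImageVolume(mu_map, (1.0, spacing_mm, spacing_mm), unit="cm^-1")
    lineint = project_slices(mu_map, geometry)  # cm^-1 * mm
    return np.exp(-lineint / 10.0)
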
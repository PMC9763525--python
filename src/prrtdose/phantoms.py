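"""Digital sphere-phantom generator for recovery-coefficient calibration.

Emulates PET/SPECT acquisitions of a six-sphere body phantom: spheres of
known volume filled at a known activity concentration, an optional uniform
background at a fraction eta of the sphere concentration, Gaussian blurring
by the system PSF and scaled-Poisson counting noise. Sphere positions are a
fixed deterministic layout (positions are irrelevant to recovery); spheres
are rasterized with sub-voxel supersampling so voxelized volumes track the
analytic volumes to well below 1%.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .constants import (
    NEMA_SPHERE_VOLUMES_ML,
    fwhm_to_sigma,
)
from .images import LabelMask, VoxelImage

__all__ = ["PhantomSpec", "make_sphere_phantom", "blur_and_noise", "nema_phantom_spec"]


@dataclass
class PhantomSpec:
    """Geometry, activity and acquisition parameters of a sphere phantom.

    ``noise_scale`` is the expected number of counts per voxel for a voxel at
    ``sphere_concentration``; 0 disables counting noise.
    """

    sphere_volumes_ml: tuple[float, ...]
    sphere_concentration: float = 1.0e5
    background_ratio: float = 0.0
    voxel_size_mm: float = 3.65
    grid_shape: tuple[int, int, int] | None = None
    psf_fwhm_mm: float = 6.4
    noise_scale: float = 0.0
    seed: int = 0
    supersample: int = 7

    def __post_init__(self):
        self.sphere_volumes_ml = tuple(float(v) for v in self.sphere_volumes_ml)
        if any(v <= 0 for v in self.sphere_volumes_ml):
            raise ValueError("all sphere volumes must be positive")
        if not 0.0 <= self.background_ratio < 1.0:
            raise ValueError("background_ratio must lie in [0, 1)")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be non-negative")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.supersample < 5:
            raise ValueError("supersample must be at least 5 per axis")

    @property
    def sphere_radii_mm(self) -> np.ndarray:
        v_mm3 = np.asarray(self.sphere_volumes_ml) * 1000.0
        return (3.0 * v_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def nema_phantom_spec(background_ratio: float = 0.0, **kwargs) -> PhantomSpec:
    """Spec for the standard six-sphere (0.52-26.5 mL) calibration phantom."""
    kwargs.setdefault("sphere_volumes_ml", NEMA_SPHERE_VOLUMES_ML)
    return PhantomSpec(background_ratio=background_ratio, **kwargs)


def _sphere_layout(spec: PhantomSpec) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Deterministic sphere centres (mm) and a grid shape that fits them.

    Spheres are laid out along x with a per-sphere margin of the radius plus
    three PSF FWHMs plus a fixed background collar, which also leaves room
    for local-background shells used downstream.
    """
    radii = spec.sphere_radii_mm
    margin = 3.0 * max(spec.psf_fwhm_mm, spec.voxel_size_mm) + 4.0 * spec.voxel_size_mm
    half_widths = radii + margin
    centres_x = np.cumsum(2 * half_widths) - half_widths
    half_yz = float(half_widths.max())
    centres = np.column_stack(
        [centres_x, np.full_like(centres_x, half_yz), np.full_like(centres_x, half_yz)]
    )
    if spec.grid_shape is None:
        nx = int(np.ceil(centres_x[-1] + half_widths[-1]) / spec.voxel_size_mm) + 1
        nyz = int(np.ceil(2 * half_yz / spec.voxel_size_mm)) + 1
        shape = (nx, nyz, nyz)
    else:
        shape = tuple(int(n) for n in spec.grid_shape)
    return centres, shape


def make_sphere_phantom(spec: PhantomSpec) -> tuple[VoxelImage, LabelMask]:
    """Rasterize the noise-free ground-truth phantom and its sphere mask.

    Returns the true activity-concentration image (before any blurring) and
    a label mask whose legend records each sphere's analytic volume. Voxels
    straddling a sphere surface carry the exact occupied-volume fraction of
    sphere over background concentration, estimated by ``supersample**3``
    sub-voxel samples.
    """
    centres, shape = _sphere_layout(spec)
    radii = spec.sphere_radii_mm
    vs = spec.voxel_size_mm
    extent = np.asarray(shape) * vs

    margin_req = 3.0 * spec.psf_fwhm_mm
    for i, (c, r) in enumerate(zip(centres, radii)):
        if np.any(c - r - margin_req < 0) or np.any(c + r + margin_req > extent):
            raise ValueError(
                f"sphere {i} (r={r:.1f} mm) does not fit in the grid with a "
                f"3 x FWHM margin; enlarge grid_shape"
            )
    for i, j in itertools.combinations(range(len(centres)), 2):
        if np.linalg.norm(centres[i] - centres[j]) < radii[i] + radii[j]:
            raise ValueError(f"spheres {i} and {j} overlap")

    bg = spec.background_ratio * spec.sphere_concentration
    values = np.full(shape, bg, dtype=float)
    labels = np.zeros(shape, dtype=np.int16)
    legend: dict[int, str] = {}
    volumes: dict[int, float] = {}

    n = spec.supersample
    # sub-voxel sample offsets in voxel units, centred on the voxel centre
    off = (np.arange(n) + 0.5) / n - 0.5
    ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])  # (n^3, 3)

    for idx, (centre, r) in enumerate(zip(centres, radii)):
        label = idx + 1
        lo = np.maximum(np.floor((centre - r) / vs - 1).astype(int), 0)
        hi = np.minimum(np.ceil((centre + r) / vs + 1).astype(int), shape)
        ii, jj, kk = np.meshgrid(
            *[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij"
        )
        vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        vox_centres = (vox + 0.5) * vs  # mm
        d2 = ((vox_centres - centre) ** 2).sum(axis=1)
        half_diag = vs * np.sqrt(3) / 2
        inside = d2 <= (r - half_diag) ** 2 if r > half_diag else np.zeros(len(vox), bool)
        boundary = (~inside) & (d2 <= (r + half_diag) ** 2)

        frac = np.zeros(len(vox))
        frac[inside] = 1.0
        if boundary.any():
            pts = vox_centres[boundary, None, :] + offsets[None, :, :] * vs
            sub_d2 = ((pts - centre) ** 2).sum(axis=2)
            frac[boundary] = (sub_d2 <= r * r).mean(axis=1)

        sel = frac > 0
        vi = tuple(vox[sel].T)
        values[vi] = bg + frac[sel] * (spec.sphere_concentration - bg)
        # label the full support so the VOI captures all sphere activity;
        # the analytic volume lives in the legend, not in the voxel count
        labels[vi] = label
        vol_ml = spec.sphere_volumes_ml[idx]
        legend[label] = f"sphere_{vol_ml:.2f}mL"
        volumes[label] = vol_ml

    truth = VoxelImage(values, (vs, vs, vs))
    mask = LabelMask(labels, legend=legend, volumes_ml=volumes)
    return truth, mask


def blur_and_noise(
    truth: VoxelImage,
    psf_fwhm_mm: float,
    noise_scale: float = 0.0,
    seed: int = 0,
    reference_concentration: float | None = None,
) -> VoxelImage:
    """Simulate the imaging system: Gaussian PSF plus counting noise.

    The blur is an isotropic Gaussian of the stated FWHM; boundary handling
    (nearest-neighbour extension) conserves total activity for objects away
    from the grid edge. If ``noise_scale > 0`` the image is scaled so that a
    voxel at ``reference_concentration`` (default: image maximum) has
    ``noise_scale`` expected counts, Poisson counts are drawn, and the image
    is scaled back.
    """
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be non-negative")
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    values = truth.values
    if psf_fwhm_mm > 0:
        sigma_vox = [fwhm_to_sigma(psf_fwhm_mm) / s for s in truth.voxel_size]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="nearest")
    if noise_scale > 0:
        ref = reference_concentration
        if ref is None:
            ref = float(values.max())
        if ref <= 0:
            raise ValueError("reference concentration must be positive for noise")
        gain = noise_scale / ref
        rng = np.random.default_rng(seed)
        values = rng.poisson(np.clip(values, 0, None) * gain) / gain
    return VoxelImage(values.astype(float), truth.voxel_size, truth.origin)
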
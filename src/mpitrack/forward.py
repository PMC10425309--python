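"""Image-formation model: PSF convolution, baseline loss, shadowing noise.

The scanner's tomographic internals are abstracted away: acquisition is modeled
directly in reconstruction space as two orthogonal line-scan channels.  Each
channel measures the ideal (PSF-blurred, iron-linear) signal volume but loses
the constant (DC) offset of every line along its transmit axis — the physical
origin of the partial-field-of-view baseline problem.  The noise floor is
coupled to the brightest in-FOV voxel, which is how a large field of view
containing the injection site "shadows" the weak lymph-node signal.

Array convention: 3-D grids are indexed ``[iz, ix, iy]``; Z is the bore axis.
Voxel ``(0, 0, 0)`` has its center at ``origin_mm + 0.5 * voxel_mm``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve

from .phantoms import IronSource, PhantomScene

__all__ = [
    "ScanConfig",
    "RawScan",
    "ReconImage",
    "psf_kernel",
    "ideal_image",
    "acquire_scan",
    "FOCUSED_FOV_CENTER_Z_MM",
]

# Shape constant making the kernel's half-maximum radius exactly FWHM/2.
_PSF_SHAPE = 2.0 ** (2.0 / 3.0) - 1.0
# Kernel support: truncated at a radius of 3 x FWHM.
_PSF_TRUNC_FWHM = 3.0

#: Default center of the focused 2-cm window along Z.  Chosen just caudal of
#: the pLN (z = 35 mm) so both nodes sit well inside the window while the
#: injection site (z = 45 mm) stays beyond the PSF support of every in-FOV
#: voxel's neighbourhood edge.
FOCUSED_FOV_CENTER_Z_MM = 32.0


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition geometry, PSF width, gain and noise model.

    Field strengths, gradient and projection count are carried as metadata
    describing the emulated sequence (3.0 T/m selection gradient, 20/23 mT
    drive fields, 35 projections over 0-180 degrees); they do not enter the
    simplified image-formation math.  ``noise_rel_coeff`` couples the noise
    floor to the brightest ideal in-FOV value (dynamic-range shadowing);
    ``noise_abs_sd`` is the scanner's absolute noise floor.
    """

    gradient_Tpm: float = 3.0
    drive_x_mT: float = 20.0
    drive_z_mT: float = 23.0
    n_projections: int = 35
    fov_z_mm: float = 120.0
    fov_x_mm: float = 60.0
    fov_y_mm: float = 60.0
    fov_center_z_mm: float = 0.0
    voxel_mm: float = 0.5
    psf_fwhm_mm: float = 2.5
    gain_au_per_ng: float = 100.0
    noise_abs_sd: float = 0.02
    noise_rel_coeff: float = 0.0072
    rng_seed: int = 0
    name: str = "full12"

    def __post_init__(self) -> None:
        for attr in ("fov_z_mm", "fov_x_mm", "fov_y_mm", "voxel_mm", "psf_fwhm_mm",
                     "gain_au_per_ng"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0, got {getattr(self, attr)}")
        if self.psf_fwhm_mm < self.voxel_mm:
            raise ValueError(
                f"psf_fwhm_mm ({self.psf_fwhm_mm}) must be >= voxel_mm ({self.voxel_mm})"
            )
        if self.noise_abs_sd < 0 or self.noise_rel_coeff < 0:
            raise ValueError("noise coefficients must be >= 0")

    # -- geometry -------------------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return (
            int(round(self.fov_z_mm / self.voxel_mm)),
            int(round(self.fov_x_mm / self.voxel_mm)),
            int(round(self.fov_y_mm / self.voxel_mm)),
        )

    @property
    def origin_mm(self) -> np.ndarray:
        """World coordinate (z, x, y) of the low corner of the FOV."""
        return np.array(
            [
                self.fov_center_z_mm - self.fov_z_mm / 2.0,
                -self.fov_x_mm / 2.0,
                -self.fov_y_mm / 2.0,
            ]
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_mm ** 3

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one array axis."""
        n = self.grid_shape[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * self.voxel_mm

    def world_to_index(self, position) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest to a world position."""
        pos = np.asarray(position, dtype=float)
        idx = np.floor((pos - self.origin_mm) / self.voxel_mm).astype(int)
        idx = np.clip(idx, 0, np.array(self.grid_shape) - 1)
        return tuple(int(i) for i in idx)

    @property
    def config_id(self) -> str:
        """Stable identifier of the imaging sequence (geometry + PSF + gain +
        noise model).  Calibration lines are only valid for images acquired
        under the same id."""
        key = "|".join(
            f"{v:.6g}"
            for v in (
                self.gradient_Tpm, self.drive_x_mT, self.drive_z_mT,
                self.n_projections, self.fov_z_mm, self.fov_x_mm, self.fov_y_mm,
                self.fov_center_z_mm, self.voxel_mm, self.psf_fwhm_mm,
                self.gain_au_per_ng, self.noise_abs_sd, self.noise_rel_coeff,
            )
        )
        digest = hashlib.sha1(key.encode()).hexdigest()[:10]
        return f"{self.name}-{digest}"

    # -- stock sequences ------------------------------------------------------
    @classmethod
    def full_fov(cls, **overrides) -> "ScanConfig":
        """Whole-animal 12 cm (Z) x 6 cm (X) sequence."""
        defaults = dict(name="full12")
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def focused_fov(cls, **overrides) -> "ScanConfig":
        """pLN-focused 2 cm (Z) x 6 cm (X) sequence."""
        defaults = dict(
            fov_z_mm=20.0,
            fov_center_z_mm=FOCUSED_FOV_CENTER_Z_MM,
            name="focused2",
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def fov_center(self) -> tuple[float, float, float]:
        return (self.fov_center_z_mm, 0.0, 0.0)


@dataclass
class ReconImage:
    """A 3-D scalar signal grid with its world placement and provenance."""

    values: np.ndarray
    voxel_mm: float
    origin_mm: np.ndarray
    method: str  # ideal | native | joint
    config_id: str = ""
    converged: bool = True
    objective_trace: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ReconImage values must be a 3-D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ReconImage values must be finite")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_mm ** 3

    def integral(self) -> float:
        """Total signal, a.u. * mm^3."""
        return float(self.values.sum() * self.voxel_volume_mm3)

    def world_to_index(self, position) -> tuple[int, int, int]:
        pos = np.asarray(position, dtype=float)
        idx = np.floor((pos - self.origin_mm) / self.voxel_mm).astype(int)
        idx = np.clip(idx, 0, np.array(self.values.shape) - 1)
        return tuple(int(i) for i in idx)


@dataclass
class RawScan:
    """Two orthogonal line-scan channels with per-line baselines removed.

    ``channel_z`` lines run along array axis 0 (the Z transmit axis) and each
    has had its own mean subtracted; ``channel_x`` lines run along axis 1.
    The subtracted (true) offsets are retained for testing only — a
    reconstruction method must not look at them.
    """

    channel_z: np.ndarray
    channel_x: np.ndarray
    true_offsets_z: np.ndarray  # shape (nx, ny): lost mean of each Z-line
    true_offsets_x: np.ndarray  # shape (nz, ny): lost mean of each X-line
    config: ScanConfig
    rng_seed: int = 0
    noise_sd: float = 0.0


def psf_kernel(config: ScanConfig) -> np.ndarray:
    """Isotropic point-spread kernel sampled on the voxel lattice.

    Radially decreasing profile ``(1 + s*(2r/w)^2)^(-3/2)`` with shape factor
    ``s`` chosen so the half-maximum radius is exactly ``w/2`` (w = FWHM),
    truncated at r = 3*FWHM, and normalized so that sum * voxel volume = 1.
    """
    w = config.psf_fwhm_mm
    vox = config.voxel_mm
    r_max = _PSF_TRUNC_FWHM * w
    n = int(np.ceil(r_max / vox))
    coords = (np.arange(-n, n + 1)) * vox
    zz, xx, yy = np.meshgrid(coords, coords, coords, indexing="ij")
    r2 = zz ** 2 + xx ** 2 + yy ** 2
    h = (1.0 + _PSF_SHAPE * (2.0 * np.sqrt(r2) / w) ** 2) ** -1.5
    h[r2 > r_max ** 2] = 0.0
    h /= h.sum() * config.voxel_volume_mm3
    return h


def _render_source(
    src: IronSource, config: ScanConfig, out: np.ndarray, gain_scale: float = 1.0
) -> None:
    """Add one source's PSF-blurred footprint into the FOV grid ``out``.

    The stamp is computed on a local lattice aligned with the global grid
    (so off-lattice source positions are handled exactly) and normalized to
    unit integral on its truncated support, then scaled by gain x mass.
    Sources outside the FOV still deposit their in-FOV tails.
    """
    if src.iron_ng == 0:
        return
    vox = config.voxel_mm
    w = config.psf_fwhm_mm
    sigma = src.extent_sigma_mm
    r_psf = _PSF_TRUNC_FWHM * w
    r_stamp = r_psf + 4.0 * sigma
    pos = np.asarray(src.position, dtype=float)
    origin = config.origin_mm
    shape = np.array(config.grid_shape)

    # Global index bounds of the stamp box (may extend beyond the FOV).
    lo = np.floor((pos - r_stamp - origin) / vox - 0.5).astype(int)
    hi = np.ceil((pos + r_stamp - origin) / vox - 0.5).astype(int) + 1

    axes = [origin[a] + (np.arange(lo[a], hi[a]) + 0.5) * vox - pos[a] for a in range(3)]
    zz, xx, yy = np.meshgrid(*axes, indexing="ij", sparse=True)

    if sigma == 0.0:
        r2 = zz ** 2 + xx ** 2 + yy ** 2
        stamp = (1.0 + _PSF_SHAPE * 4.0 * r2 / w ** 2) ** -1.5
        stamp[r2 > r_psf ** 2] = 0.0
    else:
        # Blob density sampled on the (shifted) lattice, convolved with the
        # PSF sampled on a centered lattice.
        dens = np.exp(-(zz ** 2 + xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
        n = int(np.ceil(r_psf / vox))
        c = np.arange(-n, n + 1) * vox
        kz, kx, ky = np.meshgrid(c, c, c, indexing="ij", sparse=True)
        kr2 = kz ** 2 + kx ** 2 + ky ** 2
        kern = (1.0 + _PSF_SHAPE * 4.0 * kr2 / w ** 2) ** -1.5
        kern[kr2 > r_psf ** 2] = 0.0
        stamp = fftconvolve(dens, kern, mode="same")
        np.maximum(stamp, 0.0, out=stamp)  # clip FFT ringing at the support edge

    total = stamp.sum() * config.voxel_volume_mm3
    if total <= 0:
        return
    stamp *= gain_scale * src.iron_ng / total

    # Crop stamp to the FOV and accumulate.
    glo = np.maximum(lo, 0)
    ghi = np.minimum(hi, shape)
    if np.any(glo >= ghi):
        return
    slo = glo - lo
    shi = ghi - lo
    out[glo[0]:ghi[0], glo[1]:ghi[1], glo[2]:ghi[2]] += stamp[
        slo[0]:shi[0], slo[1]:shi[1], slo[2]:shi[2]
    ]


def ideal_image(scene: PhantomScene, config: ScanConfig) -> ReconImage:
    """Noise-free signal volume: gain x sum of PSF-blurred sources.

    Linear in every source mass; the whole-image integral of a source well
    inside the FOV is ``gain_au_per_ng x iron_ng`` (a.u. mm^3).
    """
    out = np.zeros(config.grid_shape, dtype=float)
    for src in scene.sources:
        _render_source(src, config, out, gain_scale=config.gain_au_per_ng)
    return ReconImage(out, config.voxel_mm, config.origin_mm, "ideal", config.config_id)


def acquire_scan(
    scene: PhantomScene, config: ScanConfig, seed: Optional[int] = None
) -> RawScan:
    """Simulate a two-channel acquisition of a scene.

    Computes the ideal image (including in-FOV tails of out-of-FOV sources),
    then for each channel removes every line's own mean along its transmit
    axis — the lost DC baseline — and adds i.i.d. Gaussian noise with
    ``sd = noise_abs_sd + noise_rel_coeff * (peak ideal in-FOV value)``.
    The coupling of the noise floor to the in-FOV peak is the dynamic-range
    shadowing mechanism: a FOV containing the bright injection site raises
    the floor under the faint pLN signal.
    """
    ideal = ideal_image(scene, config).values
    peak = float(ideal.max(initial=0.0))
    sd = config.noise_abs_sd + config.noise_rel_coeff * max(peak, 0.0)

    if seed is None:
        seed = int(np.random.SeedSequence([scene.rng_seed, config.rng_seed]).generate_state(1)[0] % (2 ** 31))
    stream_z, stream_x = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)]

    meas_z = ideal if sd == 0 else ideal + stream_z.normal(0.0, sd, size=ideal.shape)
    meas_x = ideal if sd == 0 else ideal + stream_x.normal(0.0, sd, size=ideal.shape)
    # The DC offset is lost from the *measured* line, so every stored line has
    # exactly zero mean by construction.
    offs_z = meas_z.mean(axis=0)  # (nx, ny)
    offs_x = meas_x.mean(axis=1)  # (nz, ny)
    channel_z = meas_z - offs_z[None, :, :]
    channel_x = meas_x - offs_x[:, None, :]
    return RawScan(channel_z, channel_x, offs_z, offs_x, config, seed, sd)
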
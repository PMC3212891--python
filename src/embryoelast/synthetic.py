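"""Synthetic measurement generator for end-to-end testing of the pipeline.

Real inputs to the method are brightfield image pairs of a loaded embryo
(or the PIV lattices derived from them).  This module fabricates both from
the forward model, with the noise structure the study conditions specify:

* individual displacement measurements with a signal-to-noise ratio near 1
  (image pixel scale ~1.5 um against displacements of a few um);
* force-normalised ensemble averages whose residual relative variance near
  the load is ~0.10;
* applied force magnitudes drawn uniformly from the experimental
  100-430 nN range;
* speckle-textured images (a stand-in for the embryo's intrinsic optical
  texture) warped by the forward model's displacement field so the PIV
  stage can be exercised without any recorded data.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .fields import (
    DEFAULT_IMAGE_SHAPE,
    DEFAULT_PIXEL_SCALE_UM,
    DisplacementGrid,
    Lattice,
    default_lattice,
)
from .forward import (
    MaterialParams,
    Mesh,
    PlaneStressOperator,
    PointLoad,
    RegionGeometry,
    generate_mesh,
)

__all__ = [
    "NoiseSpec",
    "SyntheticCase",
    "SyntheticExperiment",
    "make_speckle_image",
    "warp_image",
    "synth_measurement_set",
    "field_sampler_from_grid",
    "render_image_pair",
]

#: experimental applied-force magnitude range, N
FORCE_RANGE_N = (100e-9, 430e-9)

#: autocorrelation HWHM of filtered white noise equals 2*sqrt(ln 2)*sigma
_GRAIN_TO_SIGMA = 1.0 / (2.0 * np.sqrt(np.log(2.0)))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise structure of the emulated measurements.

    ``per_measurement_snr`` is RMS(signal)/RMS(noise) over the lattice for
    one measurement.  ``ensemble_relative_variance`` is the target ratio of
    the averaged field's residual noise RMS to the mean displacement
    magnitude near the load; when ``n_embryos`` is None the replicate count
    is calibrated so the ensemble reaches that target.
    """

    per_measurement_snr: float = 1.0
    ensemble_relative_variance: float = 0.10
    replicates_per_load: int = 4
    n_embryos: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if not self.per_measurement_snr > 0:
            raise ValueError("per_measurement_snr must be positive")
        if not 0.0 <= self.ensemble_relative_variance < 1.0:
            raise ValueError("ensemble_relative_variance must lie in [0, 1)")
        if self.replicates_per_load < 1:
            raise ValueError("replicates_per_load must be at least 1")
        if self.n_embryos is not None and self.n_embryos < 1:
            raise ValueError("n_embryos must be at least 1")


@dataclass
class SyntheticCase:
    """One load case: noiseless truth plus noisy replicate lattices."""

    load: PointLoad
    mesh: Mesh
    truth_grid: DisplacementGrid        # noiseless field at the nominal force, um
    replicates: List[DisplacementGrid]  # noisy fields at the drawn forces, um
    forces_n: List[float]               # |F| per replicate, N
    noise_sd_um: List[float]            # per-component noise sd per replicate


@dataclass
class SyntheticExperiment:
    """A full synthetic study: ground truth plus per-load measurement sets."""

    geometry: RegionGeometry
    materials: MaterialParams
    cases: List[SyntheticCase]
    noise: NoiseSpec


# ---------------------------------------------------------------------------
# speckle images
# ---------------------------------------------------------------------------

def make_speckle_image(
    shape: Tuple[int, int] = (DEFAULT_IMAGE_SHAPE[1], DEFAULT_IMAGE_SHAPE[0]),
    grain_px: float = 3.0,
    seed: int = 0,
) -> np.ndarray:
    """Band-limited random texture emulating tissue optical contrast.

    ``shape`` is (rows, cols); the default (512, 640) is a 640 x 512 px
    image.  ``grain_px`` sets the correlation length: it is the half-width
    at half-maximum of the image autocorrelation.  Deterministic per seed;
    values lie in [0, 1].
    """
    if min(shape) < 64:
        raise ValueError("image must be at least 64 x 64 px")
    if grain_px >= min(shape):
        raise ValueError("grain_px larger than the image")
    if not grain_px > 0:
        raise ValueError("grain_px must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(shape)
    z = gaussian_filter(z, sigma=grain_px * _GRAIN_TO_SIGMA, mode="wrap")
    z = (z - z.mean()) / z.std()
    return np.clip(0.5 + 0.15 * z, 0.0, 1.0)


FieldSampler = Callable[[np.ndarray], np.ndarray]


def warp_image(
    image: np.ndarray,
    displacement: Union[DisplacementGrid, FieldSampler],
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    mode: str = "wrap",
    max_fraction: float = 0.25,
) -> np.ndarray:
    """Deform an image so PIV on (image, warped) recovers +displacement.

    Inverse-mapped bilinear resampling: the deformed image at pixel x takes
    the reference value at x - u(x).  ``displacement`` is either a
    :class:`DisplacementGrid` in the image frame (um, y down) or a callable
    mapping (N, 2) pixel coordinates (x_px, y_px) to (N, 2) displacements
    in um.  ``mode`` handles edges ('wrap' = periodic, 'nearest' = cropped
    extension).
    """
    img = np.asarray(image, dtype=float)
    H, W = img.shape
    X, Y = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    pts = np.column_stack([X.ravel(), Y.ravel()])
    if isinstance(displacement, DisplacementGrid):
        if displacement.frame != "image":
            raise ValueError("DisplacementGrid must be in the image frame")
        u_um = _grid_sampler(displacement)(pts * pixel_scale_um / 1000.0)
    else:
        u_um = np.asarray(displacement(pts))
    u_px = u_um / pixel_scale_um
    bound = max_fraction * min(H, W)
    if np.nanmax(np.abs(u_px)) > bound:
        raise ValueError(
            f"displacement exceeds {max_fraction:.0%} of the image size"
        )
    u_px = np.nan_to_num(u_px)
    src_x = (X.ravel() - u_px[:, 0]).reshape(H, W)
    src_y = (Y.ravel() - u_px[:, 1]).reshape(H, W)
    # scipy's 'wrap' is not truly periodic; 'grid-wrap' is
    nd_mode = {"wrap": "grid-wrap"}.get(mode, mode)
    return map_coordinates(img, [src_y, src_x], order=1, mode=nd_mode)


def _grid_sampler(grid: DisplacementGrid) -> Callable[[np.ndarray], np.ndarray]:
    """Bilinear sampler of a DisplacementGrid; input points in mm, output um."""
    from scipy.interpolate import RegularGridInterpolator

    u = np.where(grid.valid[..., None], grid.u, 0.0)
    itp = RegularGridInterpolator(
        (grid.y, grid.x), u, bounds_error=False, fill_value=None
    )

    def sample(points_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_mm)
        return itp(np.column_stack([p[:, 1], p[:, 0]]))

    return sample


def field_sampler_from_grid(
    grid_model: DisplacementGrid,
    center_mm: Tuple[float, float],
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    image_shape: Tuple[int, int] = (DEFAULT_IMAGE_SHAPE[1], DEFAULT_IMAGE_SHAPE[0]),
) -> FieldSampler:
    """Pixel-coordinate sampler of a model-frame field, for :func:`warp_image`.

    The image is taken to be centred on ``center_mm`` in the model frame
    with y increasing downward; u_y changes sign accordingly.
    """
    sampler = _grid_sampler(grid_model)
    H, W = image_shape
    s = pixel_scale_um / 1000.0

    def sample(points_px: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_px)
        mx = (p[:, 0] - (W - 1) / 2.0) * s + center_mm[0]
        my = -(p[:, 1] - (H - 1) / 2.0) * s + center_mm[1]
        u = sampler(np.column_stack([mx, my])).copy()
        u[:, 1] *= -1.0
        return u

    return sample


def render_image_pair(
    grid_model: DisplacementGrid,
    center_mm: Tuple[float, float] = (0.0, 0.0),
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    image_shape: Tuple[int, int] = (DEFAULT_IMAGE_SHAPE[1], DEFAULT_IMAGE_SHAPE[0]),
    grain_px: float = 3.0,
    seed: int = 0,
):
    """Speckle reference plus the same image warped by a model-frame field.

    Returns an :class:`~embryoelast.piv.ImagePair`.
    """
    from .piv import ImagePair

    ref = make_speckle_image(image_shape, grain_px=grain_px, seed=seed)
    sampler = field_sampler_from_grid(grid_model, center_mm, pixel_scale_um, image_shape)
    deformed = warp_image(ref, sampler, pixel_scale_um)
    return ImagePair(reference=ref, deformed=deformed, pixel_scale_um=pixel_scale_um)


# ---------------------------------------------------------------------------
# lattice-level measurement synthesis
# ---------------------------------------------------------------------------

def _near_load_mask(lattice: Lattice, position, radius_mm: float) -> np.ndarray:
    pts = lattice.points()
    d = np.hypot(pts[:, 0] - position[0], pts[:, 1] - position[1])
    return (d <= radius_mm).reshape(lattice.shape)


def synth_measurement_set(
    materials: MaterialParams,
    geometry: RegionGeometry,
    loads: Sequence[PointLoad],
    noise: NoiseSpec = NoiseSpec(),
    target_nodes: int = 3000,
    lattice_for: Optional[Callable[[PointLoad], Lattice]] = None,
) -> SyntheticExperiment:
    """Generate noisy replicate displacement lattices for each load case.

    Per case: the forward model is solved at the true moduli on a mesh
    refined at the load position and interpolated to the measurement
    lattice (by default the standard 40 x 32 lattice centred on the load).
    Each replicate scales the field to a force drawn uniformly from the
    experimental 100-430 nN range and adds i.i.d. Gaussian noise per vector
    component sized so RMS(signal)/RMS(noise) equals the per-measurement
    SNR.  When ``noise.n_embryos`` is None, the total replicate count is
    calibrated so the force-normalised ensemble mean reaches the target
    relative variance near the load.
    """
    if not loads:
        raise ValueError("at least one load case is required")
    rng = np.random.default_rng(noise.seed)
    cases = []
    for load in loads:
        lattice = (
            lattice_for(load) if lattice_for is not None
            else default_lattice(center=load.position)
        )
        mesh = generate_mesh(geometry, target_nodes=target_nodes,
                             refine_points=[load.position])
        op = PlaneStressOperator(mesh, geometry, materials.poisson_ratio,
                                 load, lattice=lattice)
        truth = op.solve_grid(materials.youngs_moduli)
        f0 = load.magnitude
        snr = noise.per_measurement_snr
        sig_rms = truth.rms()
        sd0 = sig_rms / (snr * np.sqrt(2.0))  # per component at nominal force

        if noise.n_embryos is None:
            near = _near_load_mask(lattice, load.position, radius_mm=0.024)
            if not np.any(near & truth.valid):
                near = truth.valid
            m_near = float(np.nanmean(truth.magnitude()[near & truth.valid]))
            erv = noise.ensemble_relative_variance
            if erv > 0:
                n_total = int(np.ceil(2.0 * sd0**2 / (erv * m_near) ** 2))
            else:
                n_total = noise.replicates_per_load
            n_total = max(noise.replicates_per_load, n_total)
        else:
            n_total = noise.n_embryos * noise.replicates_per_load

        reps, forces, sds = [], [], []
        for _ in range(n_total):
            f = rng.uniform(*FORCE_RANGE_N)
            scale = f / f0
            sd = sd0 * scale if np.isfinite(sd0) else 0.0
            noise_arr = (
                rng.normal(0.0, sd, truth.u.shape) if sd > 0
                else np.zeros_like(truth.u)
            )
            rep = replace(
                truth,
                u=truth.u * scale + noise_arr,
                sd=None,
                valid=truth.valid.copy(),
                meta={"force_n": f, "noise_sd_um": sd},
            )
            reps.append(rep)
            forces.append(float(f))
            sds.append(float(sd))
        cases.append(SyntheticCase(
            load=load, mesh=mesh, truth_grid=truth,
            replicates=reps, forces_n=forces, noise_sd_um=sds,
        ))
    return SyntheticExperiment(
        geometry=geometry, materials=materials, cases=cases, noise=noise
    )
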
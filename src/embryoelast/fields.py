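"""Rectilinear displacement lattices shared by the forward model, PIV and inference.

The canonical measurement lattice is 40 x 32 vectors: one vector per 16 px
interrogation window of a 640 x 512 px image at 1.5 um/px, i.e. a 24 um
spacing covering a 960 x 768 um field of view.

Conventions
-----------
* Lattice coordinates are stored in mm.
* Displacements (and their standard deviations) are stored in um.
* The *model* frame has x = mediolateral, y = anterior-posterior (up),
  origin at the common ellipse centre; caudal is -y.
* The *image* frame has the origin at the top-left pixel with y increasing
  downward.  :meth:`DisplacementGrid.to_model_frame` performs the (single,
  documented) conversion: y is flipped about the image centre, the image
  centre is moved onto a chosen model point, and u_y changes sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

#: default interrogation-window size in pixels
DEFAULT_WINDOW_PX = 16
#: default pixel scale in um per pixel
DEFAULT_PIXEL_SCALE_UM = 1.5
#: default image shape (width, height) in pixels
DEFAULT_IMAGE_SHAPE = (640, 512)


@dataclass(frozen=True)
class Lattice:
    """Rectilinear lattice of sample points, coordinates in mm.

    ``x`` has length nx, ``y`` length ny; the lattice sites are the outer
    product with shape (ny, nx).
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.y.size, self.x.size)

    @property
    def n_sites(self) -> int:
        return self.x.size * self.y.size

    def points(self) -> np.ndarray:
        """All lattice sites as an (n_sites, 2) array in mm, row-major in (y, x)."""
        X, Y = np.meshgrid(self.x, self.y)
        return np.column_stack([X.ravel(), Y.ravel()])


def default_lattice(
    center: Tuple[float, float] = (0.0, 0.0),
    n: Tuple[int, int] = (40, 32),
    spacing_um: float = DEFAULT_WINDOW_PX * DEFAULT_PIXEL_SCALE_UM,
) -> Lattice:
    """The standard measurement lattice: ``n = (nx, ny)`` window centres.

    Sites are placed at window centres of an image whose centre sits at
    ``center`` (mm, model frame), so with the defaults the lattice spans
    960 x 768 um and no site coincides with the centre itself.
    """
    nx, ny = n
    s = spacing_um / 1000.0  # mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * s + center[0]
    y = (np.arange(ny) - (ny - 1) / 2.0) * s + center[1]
    return Lattice(x=x, y=y)


@dataclass
class DisplacementGrid:
    """A lattice of 2D displacement vectors with optional per-site spread.

    Attributes
    ----------
    x, y : 1D arrays, mm — lattice coordinates (see :class:`Lattice`).
    u : (ny, nx, 2) array, um — displacement vectors (u_x, u_y).
    sd : optional (ny, nx, 2) array, um — per-component standard deviation.
    valid : (ny, nx) boolean mask of trustworthy vectors.
    frame : 'model' or 'image'.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    sd: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None
    frame: str = "model"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        ny, nx = self.y.size, self.x.size
        if self.u.shape != (ny, nx, 2):
            raise ValueError(
                f"u has shape {self.u.shape}, expected {(ny, nx, 2)}"
            )
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.u.shape:
                raise ValueError("sd shape must match u")
        if self.valid is None:
            self.valid = np.all(np.isfinite(self.u), axis=-1)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.frame not in ("model", "image"):
            raise ValueError("frame must be 'model' or 'image'")

    # -- basic queries -------------------------------------------------

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.y.size, self.x.size)

    @property
    def lattice(self) -> Lattice:
        return Lattice(x=self.x, y=self.y)

    def points(self) -> np.ndarray:
        return self.lattice.points()

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    def rms(self) -> float:
        """Root-mean-square vector magnitude over valid sites, um."""
        uu = self.u[self.valid]
        if uu.size == 0:
            return float("nan")
        return float(np.sqrt(np.mean(np.sum(uu**2, axis=-1))))

    def magnitude(self) -> np.ndarray:
        """Per-site vector magnitude |u| in um (NaN where invalid)."""
        mag = np.sqrt(np.sum(self.u**2, axis=-1))
        return np.where(self.valid, mag, np.nan)

    # -- arithmetic ----------------------------------------------------

    def scaled(self, factor: float) -> "DisplacementGrid":
        """Rescale displacements (and sd) by ``factor``."""
        return replace(
            self,
            u=self.u * factor,
            sd=None if self.sd is None else self.sd * abs(factor),
            valid=self.valid.copy(),
            meta=dict(self.meta),
        )

    def same_lattice(self, other: "DisplacementGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.x, other.x, atol=tol)
            and np.allclose(self.y, other.y, atol=tol)
        )

    # -- frame conversion ----------------------------------------------

    def to_model_frame(
        self, center: Tuple[float, float] = (0.0, 0.0)
    ) -> "DisplacementGrid":
        """Convert an image-frame grid (y down) to the model frame (y up).

        The image centre is mapped onto ``center`` (mm, model frame); the y
        axis and u_y are negated.  A grid already in the model frame is
        returned unchanged.
        """
        if self.frame == "model":
            return self
        x0 = 0.5 * (self.x[0] + self.x[-1])
        y0 = 0.5 * (self.y[0] + self.y[-1])
        new_x = self.x - x0 + center[0]
        # flip so y increases upward; reverse row order to keep y ascending
        new_y = (-(self.y - y0) + center[1])[::-1]
        new_u = self.u[::-1].copy()
        new_u[..., 1] *= -1.0
        new_sd = None if self.sd is None else self.sd[::-1].copy()
        new_valid = self.valid[::-1].copy()
        return DisplacementGrid(
            x=new_x, y=new_y, u=new_u, sd=new_sd, valid=new_valid,
            frame="model", meta=dict(self.meta),
        )
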
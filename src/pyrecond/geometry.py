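"""Simulation domains and discrete differential operators.

Two domain kinds are supported:

* ``periodic_square`` — a uniform cell-centered grid with periodic wrap in
  both directions (spectral-friendly).
* ``chloroplast_mask`` — a cup-shaped masked domain: the interior of an
  ellipse (semiaxes ``a`` along x, ``b`` along y) minus a circle of radius
  ``r_in`` whose center may be offset along the minor axis.  Fluxes obey a
  no-flux closure on the mask boundary and the order-parameter normal
  derivative carries contact-angle (wetting) Neumann data.

All operators are finite-volume: fluxes live on cell faces, so the discrete
divergence theorem (and hence mass conservation) holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy import ndimage


@dataclass
class Geometry:
    """A discretized simulation domain.

    Fields follow the cell-centered convention: cell (i, j) is centered at
    ``(x[j], y[i])`` with the origin at the domain center and x along the
    major axis.  ``mask`` is True inside the domain (all-True for the
    periodic kind).
    """

    kind: str                      # "periodic_square" | "chloroplast_mask"
    Nx: int
    Ny: int
    h: float                       # uniform grid spacing (dimensionless)
    mask: np.ndarray               # bool, shape (Ny, Nx)
    contact_angle_s: float = 5 * np.pi / 6
    contact_angle_ns: float = 5 * np.pi / 6
    # chloroplast shape constants (dimensionless); unused for periodic kind
    a: float = 0.0
    b: float = 0.0
    r_in: float = 0.0
    offset: float = 0.0
    _cache: dict = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------------ #
    @property
    def periodic(self) -> bool:
        return self.kind == "periodic_square"

    @property
    def Lx(self) -> float:
        return self.Nx * self.h

    @property
    def Ly(self) -> float:
        return self.Ny * self.h

    @property
    def n_inside(self) -> int:
        return int(self.mask.sum())

    def cell_centers(self):
        """Return (x, y) 1-D coordinate arrays of cell centers."""
        x = (np.arange(self.Nx) + 0.5) * self.h - self.Lx / 2
        y = (np.arange(self.Ny) + 0.5) * self.h - self.Ly / 2
        return x, y

    # ---------------------------- face masks -------------------------- #
    # Face convention: fx[i, j] is the face between cell (i, j) and its +x
    # neighbour (i, j+1) (periodic wrap); fy[i, j] likewise in +y.
    def _faces(self):
        if "fx" in self._cache:
            return self._cache["fx"], self._cache["fy"]
        m = self.mask
        if self.periodic:
            fx = np.ones_like(m, dtype=bool)
            fy = np.ones_like(m, dtype=bool)
        else:
            fx = m & np.roll(m, -1, axis=1)
            fx[:, -1] = False
            fy = m & np.roll(m, -1, axis=0)
            fy[-1, :] = False
        self._cache["fx"], self._cache["fy"] = fx, fy
        return fx, fy

    def _boundary_face_count(self) -> np.ndarray:
        """Per-cell number of boundary faces (0 for periodic)."""
        if "bcount" in self._cache:
            return self._cache["bcount"]
        if self.periodic:
            bc = np.zeros_like(self.mask, dtype=np.int64)
        else:
            fx, fy = self._faces()
            nb = (
                fx.astype(np.int64)
                + np.roll(fx, 1, axis=1)
                + fy
                + np.roll(fy, 1, axis=0)
            )
            bc = np.where(self.mask, 4 - nb, 0)
        self._cache["bcount"] = bc
        return bc

    # --------------------------- operators ---------------------------- #
    def laplacian(
        self,
        f: np.ndarray,
        kappa_tilde: Optional[float] = None,
        theta: Optional[float] = None,
    ) -> np.ndarray:
        """Five-point Laplacian with the domain's boundary rule.

        For the masked kind, boundary faces default to homogeneous Neumann
        (zero normal derivative); passing ``kappa_tilde`` and ``theta``
        instead imposes the wetting condition
        ``grad(f)·n = (sqrt(2)/2) sqrt(kappa_tilde) cos(theta) (1-f)^2``
        as ghost-cell Neumann data.
        """
        f = np.asarray(f, dtype=float)
        if f.shape != self.mask.shape:
            raise ValueError(f"field shape {f.shape} != grid {self.mask.shape}")
        h2 = self.h * self.h
        if self.periodic:
            return (
                np.roll(f, -1, 1) + np.roll(f, 1, 1)
                + np.roll(f, -1, 0) + np.roll(f, 1, 0)
                - 4 * f
            ) / h2
        fx, fy = self._faces()
        out = np.zeros_like(f)
        # interior faces only: sum of (f_nb - f_c) over inside neighbours
        dxp = np.where(fx, np.roll(f, -1, 1) - f, 0.0)
        dyp = np.where(fy, np.roll(f, -1, 0) - f, 0.0)
        out += dxp - np.roll(dxp, 1, 1)
        out += dyp - np.roll(dyp, 1, 0)
        out /= h2
        if kappa_tilde is not None and theta is not None:
            g = contact_angle_gradient(f, kappa_tilde, theta)
            # ghost value f + h*g must stay within [0, 1]: soft-limit the
            # Neumann data so the wetting condition never demands unphysical
            # ghost concentrations on a coarse grid; the limiter is smooth
            # in f (a hard clip makes near-empty boundary cells stiffly
            # nonsmooth and stalls adaptive stepping)
            cap_lo = 0.5 * f / self.h
            cap_hi = 0.5 * (1.0 - f) / self.h
            mag = np.abs(g)
            cap = np.where(g < 0, cap_lo, cap_hi)
            g = g * cap / (cap + mag + 1e-30)
            out += self._boundary_face_count() * g / self.h
        return np.where(self.mask, out, 0.0)

    def face_gradient(self, f: np.ndarray):
        """Gradient on +x / +y faces; zero across boundary faces."""
        gx = (np.roll(f, -1, 1) - f) / self.h
        gy = (np.roll(f, -1, 0) - f) / self.h
        if not self.periodic:
            fx, fy = self._faces()
            gx *= fx
            gy *= fy
        return gx, gy

    def face_average(self, f: np.ndarray):
        """Arithmetic mean of adjacent cells on +x / +y faces."""
        ax = 0.5 * (np.roll(f, -1, 1) + f)
        ay = 0.5 * (np.roll(f, -1, 0) + f)
        if not self.periodic:
            fx, fy = self._faces()
            ax *= fx
            ay *= fy
        return ax, ay

    def divergence_of_flux(self, flux_x: np.ndarray, flux_y: np.ndarray) -> np.ndarray:
        """Discrete divergence of face fluxes (no-flux closure on boundary).

        ``flux_x[i, j]`` is the flux through the +x face of cell (i, j);
        boundary faces are forced to zero so the domain total of the result
        vanishes identically (discrete divergence theorem).
        """
        if flux_x.shape != self.mask.shape or flux_y.shape != self.mask.shape:
            raise ValueError("flux shape mismatch")
        if self.periodic:
            qx, qy = flux_x, flux_y
        else:
            fx, fy = self._faces()
            qx = flux_x * fx
            qy = flux_y * fy
        div = (qx - np.roll(qx, 1, 1) + qy - np.roll(qy, 1, 0)) / self.h
        if self.periodic:
            return div
        return np.where(self.mask, div, 0.0)

    # ------------------- sparse operators (masked solver) ------------- #
    def sparse_laplacian(self) -> sp.csr_matrix:
        """Sparse homogeneous-Neumann Laplacian over inside cells."""
        if "L" in self._cache:
            return self._cache["L"]
        m = self.mask
        idx = -np.ones(m.shape, dtype=np.int64)
        idx[m] = np.arange(m.sum())
        rows, cols, vals = [], [], []
        fx, fy = self._faces()
        for fmask, ax in ((fx, 1), (fy, 0)):
            ii, jj = np.nonzero(fmask)
            if ax == 1:
                nb_i, nb_j = ii, (jj + 1) % self.Nx
            else:
                nb_i, nb_j = (ii + 1) % self.Ny, jj
            c1 = idx[ii, jj]
            c2 = idx[nb_i, nb_j]
            rows += [c1, c2, c1, c2]
            cols += [c2, c1, c1, c2]
            vals += [np.ones_like(c1, float), np.ones_like(c1, float),
                     -np.ones_like(c1, float), -np.ones_like(c1, float)]
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals) / (self.h * self.h)
        L = sp.coo_matrix((vals, (rows, cols)), shape=(m.sum(), m.sum())).tocsr()
        self._cache["L"] = L
        self._cache["idx"] = idx
        return L

    def inside_index(self) -> np.ndarray:
        self.sparse_laplacian()
        return self._cache["idx"]

    def to_tiff(self, path) -> None:
        """Export the mask as a single-channel TIFF for inspection."""
        import tifffile

        tifffile.imwrite(path, self.mask.astype(np.uint8) * 255)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "Nx": self.Nx,
            "Ny": self.Ny,
            "h": self.h,
            "contact_angle_s": self.contact_angle_s,
            "contact_angle_ns": self.contact_angle_ns,
            "a": self.a,
            "b": self.b,
            "r_in": self.r_in,
            "offset": self.offset,
        }


def contact_angle_gradient(f: np.ndarray, kappa_tilde: float, theta: float) -> np.ndarray:
    """Wetting Neumann data: (sqrt(2)/(2 sqrt(kappa))) cos(theta) (1-f)^2.

    Interface gradients scale as 1/sqrt(kappa) (wider interfaces are
    shallower), so the imposed wall slope carries the same scaling; theta >
    pi/2 (the default 5*pi/6) makes the slope negative, i.e. dewetting.
    """
    return (np.sqrt(2.0) / (2.0 * np.sqrt(kappa_tilde))) * np.cos(theta) * (1.0 - f) ** 2


def geometry_from_dict(d: dict) -> Geometry:
    if d["kind"] == "periodic_square":
        return make_periodic_square(d["h"] * d["Nx"], d["Nx"])
    return make_chloroplast(
        N=d["Nx"],
        a=d["a"],
        b=d["b"],
        r_in=d["r_in"],
        offset=d["offset"],
        contact_angle_s=d.get("contact_angle_s", 5 * np.pi / 6),
        contact_angle_ns=d.get("contact_angle_ns", 5 * np.pi / 6),
    )


def make_periodic_square(L_tilde: float, N: int) -> Geometry:
    """Periodic square domain of dimensionless side ``L_tilde``, N x N cells."""
    if N < 8:
        raise ValueError("N must be >= 8")
    if L_tilde <= 0:
        raise ValueError("L_tilde must be positive")
    mask = np.ones((N, N), dtype=bool)
    return Geometry(kind="periodic_square", Nx=N, Ny=N, h=L_tilde / N, mask=mask)


def make_chloroplast(
    N: int = 112,
    a: float = 35.0,
    b: float = 29.17,
    r_in: float = 16.67,
    offset: Optional[float] = None,
    pad: float = 1.5,
    contact_angle_s: float = 5 * np.pi / 6,
    contact_angle_ns: float = 5 * np.pi / 6,
) -> Geometry:
    """Cup-shaped chloroplast domain: ellipse minus an offset inner circle.

    The inner circle's center sits on the minor (y) axis, displaced by
    ``offset`` toward +y.  The default ``offset = b - r_in - 2`` keeps the
    circle strictly inside the ellipse and leaves the largest clearance on
    the -y side, where the condensate canonically sits; this placement is a
    reconstruction (the published shape constants fix only a, b, r_in).
    ``offset=0`` gives an annular-elliptic domain.

    ``N`` is the number of grid cells along the major (x) axis.
    """
    if not (a > b > r_in >= 0):
        raise ValueError("require a > b > r_in >= 0")
    if offset is None:
        offset = b - r_in - 2.0
    if r_in > 0 and abs(offset) + r_in >= _ellipse_extent_y(a, b):
        raise ValueError("inner circle extends beyond the ellipse")
    h = 2 * (a + pad) / N
    Ny = int(np.ceil(2 * (b + pad) / h))
    geo = Geometry(
        kind="chloroplast_mask",
        Nx=N,
        Ny=Ny,
        h=h,
        mask=np.ones((Ny, N), dtype=bool),
        contact_angle_s=contact_angle_s,
        contact_angle_ns=contact_angle_ns,
        a=a,
        b=b,
        r_in=r_in,
        offset=offset,
    )
    x, y = geo.cell_centers()
    X, Y = np.meshgrid(x, y)
    inside_ellipse = (X / a) ** 2 + (Y / b) ** 2 < 1.0
    if r_in > 0:
        outside_circle = X**2 + (Y - offset) ** 2 > r_in**2
        mask = inside_ellipse & outside_circle
    else:
        mask = inside_ellipse
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty domain")
    if n > 1:
        raise ValueError(f"domain is disconnected ({n} components)")
    geo.mask = mask
    return geo


def _ellipse_extent_y(a: float, b: float) -> float:
    return b


def boundary_normals(geo: Geometry) -> np.ndarray:
    """Outward unit normals on boundary cells, from the analytic shape.

    Returns an (Ny, Nx, 2) array; zero away from the boundary.  Normals are
    the gradient of the signed distance of the analytic ellipse-minus-circle
    shape, evaluated at boundary cell centers.
    """
    if geo.periodic:
        return np.zeros(geo.mask.shape + (2,))
    bmask = geo._boundary_face_count() > 0
    x, y = geo.cell_centers()
    X, Y = np.meshgrid(x, y)
    # which analytic surface is closer: ellipse or inner circle
    d_circ = np.sqrt(X**2 + (Y - geo.offset) ** 2) - geo.r_in
    # approximate ellipse signed distance via level-set normalization
    e = (X / geo.a) ** 2 + (Y / geo.b) ** 2 - 1.0
    grad_e = np.stack([2 * X / geo.a**2, 2 * Y / geo.b**2], axis=-1)
    norm_e = np.linalg.norm(grad_e, axis=-1)
    d_ell = -e / np.maximum(norm_e, 1e-12)  # >0 inside
    n_ell = grad_e / np.maximum(norm_e, 1e-12)[..., None]
    r = np.sqrt(X**2 + (Y - geo.offset) ** 2)
    n_circ = -np.stack([X, Y - geo.offset], axis=-1) / np.maximum(r, 1e-12)[..., None]
    use_circ = np.abs(d_circ) < np.abs(d_ell)
    normals = np.where(use_circ[..., None], n_circ, n_ell)
    return np.where(bmask[..., None], normals, 0.0)
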
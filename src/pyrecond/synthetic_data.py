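"""Generators for every input the pipeline consumes.

Two families:

* simulator initial conditions — noise-seeded uniform states and placed
  droplets (tanh interfaces between the dilute and dense phase levels);
* synthetic confocal-like z-stacks — Venus-channel-style intensity
  proportional to concentration, with scaled-Poisson shot noise, Gaussian
  read noise and exponential photobleaching, plus the exact ground truth for
  recovery tests.

Every generator is a pure function of its spec and seed: identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import Geometry
from .model_core import FieldState, ModelParams, uniform_steady_state


@dataclass
class DropletSpec:
    """Placed-droplet initial condition.

    droplets        list of ((x, y) center in dimensionless units, radius)
    interface_width tanh interface width w (dimensionless)
    phi_plus/minus  dense and dilute levels of total protein
    sticky_fraction fraction of placed dense material assigned to the sticky
                    species (default 1: the dense phase is unphosphorylated)
    allow_overlap   permit overlapping droplets (default False)
    """

    droplets: List[Tuple[Tuple[float, float], float]]
    interface_width: float = 1.0
    phi_plus: float = 0.9
    phi_minus: float = 0.0
    sticky_fraction: float = 1.0
    allow_overlap: bool = False

    def __post_init__(self):
        if self.interface_width <= 0:
            raise ValueError("interface width must be > 0")
        for (_, r) in self.droplets:
            if r <= 0:
                raise ValueError("droplet radii must be > 0")
        if not self.allow_overlap:
            for i in range(len(self.droplets)):
                for j in range(i + 1, len(self.droplets)):
                    (c1, r1), (c2, r2) = self.droplets[i], self.droplets[j]
                    d = np.hypot(c1[0] - c2[0], c1[1] - c2[1])
                    if d < r1 + r2:
                        raise ValueError("droplets overlap (set allow_overlap)")


def seeded_uniform(params: ModelParams, geometry: Geometry,
                   amplitude: Optional[float] = None,
                   seed: int = 0) -> FieldState:
    """Uniform steady state plus i.i.d. zero-mean perturbations.

    Default amplitude is 1e-3 * phi_tot.  Each species' noise is scaled by
    its share of the steady state (a species at zero baseline stays exactly
    zero: perturbing an empty concentration field would produce an
    unphysical half-rectified field).  Fields are clipped to physical
    bounds and the total mass renormalized to exactly phi_tot * domain area.
    """
    if amplitude is None:
        amplitude = 1e-3 * params.phi_tot
    if amplitude > params.phi_tot / 10:
        raise ValueError("noise amplitude too large (> phi_tot/10)")
    rng = np.random.default_rng(seed)
    phi_s0, phi_ns0 = uniform_steady_state(params.phi_tot, params.k_tilde)
    shape = geometry.mask.shape
    w_s = phi_s0 / params.phi_tot
    w_ns = phi_ns0 / params.phi_tot
    phi_s = phi_s0 + amplitude * w_s * rng.standard_normal(shape)
    phi_ns = phi_ns0 + amplitude * w_ns * rng.standard_normal(shape)
    np.clip(phi_s, 0.0, 1.0, out=phi_s)
    np.clip(phi_ns, 0.0, 1.0, out=phi_ns)
    mask = geometry.mask
    phi_s[~mask] = 0.0
    phi_ns[~mask] = 0.0
    if amplitude > 0:
        target_s = phi_s0 * mask.sum()
        target_ns = phi_ns0 * mask.sum()
        if phi_s[mask].sum() > 0:
            phi_s[mask] *= target_s / phi_s[mask].sum()
        if phi_ns0 > 0 and phi_ns[mask].sum() > 0:
            phi_ns[mask] *= target_ns / phi_ns[mask].sum()
    return FieldState(phi_s, phi_ns, 0.0, geometry.h)


def _radial_distance(geometry: Geometry, center: Tuple[float, float]) -> np.ndarray:
    """Distance of every cell center from a point; minimum-image on periodic
    domains so droplets may straddle the wrap."""
    x, y = geometry.cell_centers()
    X, Y = np.meshgrid(x, y)
    dx = X - center[0]
    dy = Y - center[1]
    if geometry.periodic:
        dx = (dx + geometry.Lx / 2) % geometry.Lx - geometry.Lx / 2
        dy = (dy + geometry.Ly / 2) % geometry.Ly - geometry.Ly / 2
    return np.hypot(dx, dy)


def droplet_profile(geometry: Geometry, spec: DropletSpec) -> np.ndarray:
    """Total-protein field: background phi_minus with tanh bumps to phi_plus."""
    total = np.full(geometry.mask.shape, float(spec.phi_minus))
    for (center, radius) in spec.droplets:
        r = _radial_distance(geometry, center)
        bump = 0.5 * (1.0 - np.tanh((r - radius) / spec.interface_width))
        total += (spec.phi_plus - spec.phi_minus) * bump
    return np.clip(total, 0.0, 1.0)


def place_droplets(spec: DropletSpec, geometry: Geometry,
                   params: Optional[ModelParams] = None) -> FieldState:
    """Initial condition with placed condensates.

    The dense material follows ``spec.sticky_fraction`` (default fully
    sticky); when model parameters are given, the *background* dilute level
    is the uniform switching balance of phi_minus (or of phi_tot when
    phi_minus is 0 the background stays empty).  Droplet centers must lie
    inside the domain mask.
    """
    for (center, _) in spec.droplets:
        x, y = geometry.cell_centers()
        j = int(np.clip(np.searchsorted(x, center[0]), 0, geometry.Nx - 1))
        i = int(np.clip(np.searchsorted(y, center[1]), 0, geometry.Ny - 1))
        if not geometry.mask[i, j]:
            raise ValueError(f"droplet center {center} lies outside the mask")
    total = droplet_profile(geometry, spec)
    k = params.k_tilde if params is not None else 0.0
    # split: placed dense material mostly sticky; background at switching balance
    bg = spec.phi_minus
    dense_part = np.clip(total - bg, 0.0, None)
    phi_s = spec.sticky_fraction * dense_part + bg / (1.0 + k)
    phi_ns = (1.0 - spec.sticky_fraction) * dense_part + bg * k / (1.0 + k)
    phi_s[~geometry.mask] = 0.0
    phi_ns[~geometry.mask] = 0.0
    return FieldState(phi_s, phi_ns, 0.0, geometry.h)


# --------------------------------------------------------------------- #
# synthetic confocal-like stacks
# --------------------------------------------------------------------- #
@dataclass
class SyntheticStackSpec:
    """Synthetic fluorescence timelapse of 3-D droplets.

    shape        (nz, ny, nx) voxel grid
    droplets     list of ((z, y, x) center in voxels, radius in voxels)
    gain         photons per unit concentration
    phi_plus     droplet concentration (dilute background ``phi_minus``)
    phi_minus    background concentration
    poisson_scale  photons per intensity unit for shot noise (0 disables)
    read_noise_sd  additive Gaussian sd (0 disables)
    bleach_rate  exponential intensity decay rate beta per frame
    n_frames     frames in the timelapse
    seed         RNG seed (recorded in the output)
    """

    shape: Tuple[int, int, int] = (16, 64, 64)
    droplets: Sequence[Tuple[Tuple[float, float, float], float]] = ()
    gain: float = 100.0
    phi_plus: float = 1.0
    phi_minus: float = 0.02
    interface_width: float = 1.0
    poisson_scale: float = 1.0
    read_noise_sd: float = 1.0
    bleach_rate: float = 0.0
    n_frames: int = 1
    seed: int = 0


def render_stack(spec: SyntheticStackSpec) -> Tuple[np.ndarray, pd.DataFrame, dict]:
    """Render a (frames, z, y, x) stack plus its ground truth.

    Intensity = gain * concentration * exp(-beta t) + noise, clipped
    non-negative.  Returns (stack, truth table, meta); the truth table has
    the true centroid, radius and volume of each droplet, and meta records
    the bleach rate, seed and noiseless frame-0 total.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    conc = np.full(spec.shape, float(spec.phi_minus))
    rows = []
    for idx, (center, radius) in enumerate(spec.droplets):
        r = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                    + (xx - center[2]) ** 2)
        bump = 0.5 * (1.0 - np.tanh((r - radius) / spec.interface_width))
        conc += (spec.phi_plus - spec.phi_minus) * bump
        rows.append({"droplet": idx, "z": center[0], "y": center[1],
                     "x": center[2], "radius": radius,
                     "volume": 4.0 / 3.0 * np.pi * radius**3})
    conc = np.clip(conc, 0.0, spec.phi_plus)
    frames = np.empty((spec.n_frames,) + spec.shape)
    for t in range(spec.n_frames):
        signal = spec.gain * conc * np.exp(-spec.bleach_rate * t)
        noisy = signal
        if spec.poisson_scale > 0:
            noisy = rng.poisson(signal * spec.poisson_scale) / spec.poisson_scale
        if spec.read_noise_sd > 0:
            noisy = noisy + spec.read_noise_sd * rng.standard_normal(spec.shape)
        frames[t] = np.clip(noisy, 0.0, None)
    truth = pd.DataFrame(rows)
    meta = {"bleach_rate": spec.bleach_rate, "seed": spec.seed,
            "gain": spec.gain, "noiseless_total0": float((spec.gain * conc).sum())}
    return frames, truth, meta


def write_stack_tiff(path, frames: np.ndarray, meta: dict) -> None:
    """Write a rendered timelapse as a multi-page TIFF with metadata."""
    import json

    import tifffile

    tifffile.imwrite(path, frames.astype(np.float32),
                     metadata={"pyrecond": json.dumps(meta)})
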
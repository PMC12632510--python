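"""Thermodynamic core of the two-state condensate model.

An intrinsically disordered linker protein (EPYC1) is described by two
interconverting species on a grid: unphosphorylated "sticky" molecules with
volume fraction ``phi_s`` that self-attract and phase separate, and
phosphorylated "non-sticky" molecules ``phi_ns`` that behave like solvent.
The mixture free energy is of Flory-Huggins form with square-gradient
interfacial terms,

    f/kBT = sum_i phi_i ln phi_i - chi phi_s^2
            + (kappa_s/2)|grad phi_s|^2 + (kappa_ns/2)|grad phi_ns|^2
            + grad phi_s . grad phi_ns,

in units where the cross interfacial coefficient kappa'_{s-ns} = 1 (it sets
the length scale) and energies are measured in kBT.  The public parameter
``chi`` is the attraction magnitude (> 0 favors demixing); the exchange
chemical potentials are the exact functional derivatives of f:

    mu_s - mu_sol  = ln(phi_s/phi_sol) - 2 chi phi_s
                     - kappa_s lap(phi_s) - lap(phi_ns)
    mu_ns - mu_sol = ln(phi_ns/phi_sol) - lap(phi_s) - kappa_ns lap(phi_ns)

with phi_sol = 1 - phi_s - phi_ns (incompressibility, equal molecular
volumes).  The spinodal of the uniform state requires 2*chi > 1/phi_s +
1/phi_sol, so chi must exceed 2 at phi_s = 1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .geometry import Geometry

logger = logging.getLogger(__name__)

#: fields are clipped into [EPS_CLIP, 1 - EPS_CLIP] before logarithms;
#: clipping is logged by the simulator (it signals an over-long timestep).
EPS_CLIP = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameters of the full phase-field model.

    chi            self-attraction magnitude of sticky molecules (>0 attracts)
    D_tilde        diffusivity in units of kappa'_{s-ns} * k_{ns->s}
    k_tilde        switching-rate ratio k_{s->ns} / k_{ns->s} (kinase/phosphatase)
    kappa_s_tilde  kappa'_s / kappa'_{s-ns}
    kappa_ns_tilde kappa'_ns / kappa'_{s-ns}
    phi_tot        total (sticky + non-sticky) protein volume fraction
    """

    chi: float = 7.0
    D_tilde: float = 10.0
    k_tilde: float = 0.14
    kappa_s_tilde: float = 5.0
    kappa_ns_tilde: float = 1.0
    phi_tot: float = 0.1

    def __post_init__(self):
        if self.D_tilde <= 0:
            raise ValueError("D_tilde must be > 0")
        if self.k_tilde < 0:
            raise ValueError("k_tilde must be >= 0")
        if self.kappa_s_tilde <= 0 or self.kappa_ns_tilde <= 0:
            raise ValueError("kappa coefficients must be > 0")
        if not (0 < self.phi_tot < 1):
            raise ValueError("phi_tot must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "chi": self.chi,
            "D_tilde": self.D_tilde,
            "k_tilde": self.k_tilde,
            "kappa_s_tilde": self.kappa_s_tilde,
            "kappa_ns_tilde": self.kappa_ns_tilde,
            "phi_tot": self.phi_tot,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def with_k(self, k_tilde: float) -> "ModelParams":
        return replace(self, k_tilde=k_tilde)


#: Named parameter presets.  "default" is the published simulation set for
#: the wild-type scenarios; the ectopic presets model low / absent kinase
#: activity (the latter with stronger self-attraction, since unphosphorylated
#: protein is stickier).
PRESETS = {
    "default": ModelParams(chi=7.0, D_tilde=10.0, k_tilde=0.14,
                           kappa_s_tilde=5.0, kappa_ns_tilde=1.0, phi_tot=0.1),
    "low_kinase": ModelParams(chi=7.0, D_tilde=10.0, k_tilde=0.01,
                              kappa_s_tilde=5.0, kappa_ns_tilde=1.0, phi_tot=0.1),
    "ectopic_low_key1": ModelParams(chi=5.5, D_tilde=10.0, k_tilde=1e-3,
                                    kappa_s_tilde=5.0, kappa_ns_tilde=1.0, phi_tot=0.1),
    "ectopic_no_key1": ModelParams(chi=8.0, D_tilde=10.0, k_tilde=0.0,
                                   kappa_s_tilde=5.0, kappa_ns_tilde=1.0, phi_tot=0.1),
}


@dataclass(frozen=True)
class DimensionalScales:
    """Dimensional anchors of the model.

    D                diffusion coefficient (um^2/s)
    k_ns_to_s        dephosphorylation (phosphatase) rate (1/s)
    k_s_to_ns        phosphorylation (kinase) rate (1/s)
    kappa_s_ns_prime cross interfacial coefficient kappa'_{s-ns} (um^2)

    The characteristic length is sqrt(kappa'_{s-ns}) and the characteristic
    time is 1/k_{ns->s}; kB*T is absorbed into the energy unit and maximum
    molar concentration into the volume fractions.
    """

    D: float
    k_ns_to_s: float
    k_s_to_ns: float
    kappa_s_ns_prime: float

    def __post_init__(self):
        if self.D <= 0 or self.k_ns_to_s <= 0 or self.kappa_s_ns_prime <= 0:
            raise ValueError("D, k_ns_to_s and kappa_s_ns_prime must be > 0")
        if self.k_s_to_ns < 0:
            raise ValueError("k_s_to_ns must be >= 0")

    @property
    def length_scale(self) -> float:
        """Characteristic length sqrt(kappa'_{s-ns}) in um."""
        return float(np.sqrt(self.kappa_s_ns_prime))

    @property
    def time_scale(self) -> float:
        """Characteristic time 1/k_{ns->s} in s."""
        return 1.0 / self.k_ns_to_s


def nondimensionalize(scales: DimensionalScales) -> dict:
    """Map dimensional rates to the dimensionless (D_tilde, k_tilde) pair."""
    return {
        "D_tilde": scales.D / (scales.kappa_s_ns_prime * scales.k_ns_to_s),
        "k_tilde": scales.k_s_to_ns / scales.k_ns_to_s,
        "length_scale": scales.length_scale,
        "time_scale": scales.time_scale,
    }


def dimensionalize(D_tilde: float, k_tilde: float,
                   kappa_s_ns_prime: float, k_ns_to_s: float) -> DimensionalScales:
    """Exact inverse of :func:`nondimensionalize` given the two scales."""
    return DimensionalScales(
        D=D_tilde * kappa_s_ns_prime * k_ns_to_s,
        k_ns_to_s=k_ns_to_s,
        k_s_to_ns=k_tilde * k_ns_to_s,
        kappa_s_ns_prime=kappa_s_ns_prime,
    )


@dataclass
class FieldState:
    """The simulator state: both species' volume-fraction fields at a time."""

    phi_s: np.ndarray
    phi_ns: np.ndarray
    t_tilde: float = 0.0
    grid_spacing: float = 1.0

    def __post_init__(self):
        self.phi_s = np.asarray(self.phi_s, dtype=float)
        self.phi_ns = np.asarray(self.phi_ns, dtype=float)
        if self.phi_s.shape != self.phi_ns.shape:
            raise ValueError("phi_s and phi_ns must have identical shape")

    @property
    def phi_sol(self) -> np.ndarray:
        return 1.0 - self.phi_s - self.phi_ns

    def validate(self, atol: float = 0.0) -> None:
        if self.phi_s.min() < -atol or self.phi_ns.min() < -atol:
            raise ValueError("negative volume fraction")
        if (self.phi_s + self.phi_ns).max() > 1.0 + atol:
            raise ValueError("phi_s + phi_ns exceeds 1 (no solvent left)")

    def total_mass(self, mask: Optional[np.ndarray] = None) -> float:
        """Total protein content sum((phi_s+phi_ns)) * cell area."""
        tot = self.phi_s + self.phi_ns
        if mask is not None:
            tot = tot[mask]
        return float(tot.sum()) * self.grid_spacing**2

    def copy(self) -> "FieldState":
        return FieldState(self.phi_s.copy(), self.phi_ns.copy(),
                          self.t_tilde, self.grid_spacing)


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x*log(x) with the 0*log(0) = 0 convention."""
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def free_energy_density(state: FieldState, params: ModelParams,
                        geometry: Optional[Geometry] = None) -> np.ndarray:
    """Free-energy density field in kBT per lattice volume.

    Entropy of mixing of the three components plus the sticky-sticky
    attraction -chi*phi_s^2 and the square-gradient interfacial terms.
    Without a geometry, gradients are taken periodic with the state's grid
    spacing.
    """
    phi_s, phi_ns = state.phi_s, state.phi_ns
    phi_sol = state.phi_sol
    if phi_s.min() < 0 or phi_ns.min() < 0 or phi_sol.min() < -1e-12:
        raise ValueError("fields outside the physical domain")
    if geometry is None:
        from .geometry import make_periodic_square

        n = phi_s.shape[0]
        geometry = make_periodic_square(n * state.grid_spacing, n)
    f = (_xlogx(phi_s) + _xlogx(phi_ns) + _xlogx(np.clip(phi_sol, 0, None))
         - params.chi * phi_s**2)
    # gradient energy lives on faces; attribute half to each adjacent cell
    gsx, gsy = geometry.face_gradient(phi_s)
    gnx, gny = geometry.face_gradient(phi_ns)
    ex = (0.5 * params.kappa_s_tilde * gsx**2
          + 0.5 * params.kappa_ns_tilde * gnx**2 + gsx * gnx)
    ey = (0.5 * params.kappa_s_tilde * gsy**2
          + 0.5 * params.kappa_ns_tilde * gny**2 + gsy * gny)
    f = f + 0.5 * (ex + np.roll(ex, 1, 1)) + 0.5 * (ey + np.roll(ey, 1, 0))
    if not geometry.periodic:
        f = np.where(geometry.mask, f, 0.0)
    return f


def total_free_energy(state: FieldState, params: ModelParams,
                      geometry: Optional[Geometry] = None) -> float:
    """Domain-integrated free energy (kBT)."""
    if geometry is None:
        from .geometry import make_periodic_square

        n = state.phi_s.shape[0]
        geometry = make_periodic_square(n * state.grid_spacing, n)
    phi_s, phi_ns = state.phi_s, state.phi_ns
    phi_sol = np.clip(state.phi_sol, 0.0, None)
    bulk = (_xlogx(phi_s) + _xlogx(phi_ns) + _xlogx(phi_sol)
            - params.chi * phi_s**2)
    if not geometry.periodic:
        bulk = np.where(geometry.mask, bulk, 0.0)
    gsx, gsy = geometry.face_gradient(phi_s)
    gnx, gny = geometry.face_gradient(phi_ns)
    grad = (0.5 * params.kappa_s_tilde * (gsx**2 + gsy**2)
            + 0.5 * params.kappa_ns_tilde * (gnx**2 + gny**2)
            + (gsx * gnx + gsy * gny))
    return float((bulk.sum() + grad.sum()) * geometry.h**2)


def chemical_potentials(state: FieldState, params: ModelParams,
                        geometry: Optional[Geometry] = None,
                        clip: bool = False) -> Tuple[np.ndarray, np.ndarray]:
    """Exchange chemical potentials (mu_s - mu_sol, mu_ns - mu_sol) in kBT.

    Laplacians follow the geometry's boundary rule, including the
    contact-angle Neumann data on masked domains.  With ``clip=False`` a
    field that has escaped (0, 1) raises (the integrator should shrink its
    step); with ``clip=True`` log arguments are clipped to [1e-9, 1-1e-9].
    """
    phi_s, phi_ns = state.phi_s, state.phi_ns
    phi_sol = state.phi_sol
    if geometry is None:
        from .geometry import make_periodic_square

        n = phi_s.shape[0]
        geometry = make_periodic_square(n * state.grid_spacing, n)
    if clip:
        phi_s_l = np.clip(phi_s, EPS_CLIP, 1 - EPS_CLIP)
        phi_ns_l = np.clip(phi_ns, EPS_CLIP, 1 - EPS_CLIP)
        phi_sol_l = np.clip(phi_sol, EPS_CLIP, 1 - EPS_CLIP)
    else:
        if not geometry.periodic:
            ok = geometry.mask
        else:
            ok = np.ones_like(phi_s, dtype=bool)
        if (phi_s[ok].min() <= 0 or phi_ns[ok].min() <= 0
                or phi_sol[ok].min() <= 0):
            raise ValueError("log argument <= 0: field escaped (0,1)")
        phi_s_l, phi_ns_l, phi_sol_l = phi_s, phi_ns, phi_sol
    lap_s = geometry.laplacian(phi_s, params.kappa_s_tilde, geometry.contact_angle_s)
    lap_ns = geometry.laplacian(phi_ns, params.kappa_ns_tilde, geometry.contact_angle_ns)
    mu_s = (np.log(phi_s_l / phi_sol_l) - 2 * params.chi * phi_s
            - params.kappa_s_tilde * lap_s - lap_ns)
    mu_ns = np.log(phi_ns_l / phi_sol_l) - lap_s - params.kappa_ns_tilde * lap_ns
    if not geometry.periodic:
        mu_s = np.where(geometry.mask, mu_s, 0.0)
        mu_ns = np.where(geometry.mask, mu_ns, 0.0)
    return mu_s, mu_ns


def uniform_steady_state(phi_tot: float, k_tilde: float) -> Tuple[float, float]:
    """Uniform fixed point of the switching kinetics.

    phi_s0 = phi_tot/(1 + k), phi_ns0 = phi_tot*k/(1 + k): the kinase flux
    k*phi_s0 exactly balances the phosphatase flux phi_ns0.
    """
    if not (0 < phi_tot < 1):
        raise ValueError("phi_tot must lie in (0,1)")
    if k_tilde < 0:
        raise ValueError("k_tilde must be >= 0")
    phi_s0 = phi_tot / (1.0 + k_tilde)
    return phi_s0, phi_tot - phi_s0
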